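"""Force-balance bookkeeping for confined swimmers.

Under weak confinement the flagellar thrust balances the Stokes drag on
the cell body.  Under strong confinement the swimming speed collapses
while the thrust is unchanged (the flagella beat far from the walls and
thrust is viscosity-limited), so the balance must be closed by direct
contact friction with the walls.  This module exposes that arithmetic:
Stokes drag, the constant-thrust estimate, and the upper bound on the
contact-friction force obtained when the hydrodynamic drag takes its
minimal (unconfined Stokes) value.

The lubrication-film drag correction (logarithmic in the film thickness)
is deliberately not computed: the film thickness is unknown and the
correction cannot close the balance in any case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ForceLedger",
    "stokes_drag",
    "thrust_estimate",
    "contact_friction_bound",
    "build_ledger",
    "percent_speed_reduction",
]

#: 3*pi*eta*D*u with eta in mPa.s, D in um, u in um/s comes out in units of
#: 1e-3 pN (3*pi * 1e-3 Pa.s * 1e-6 m * 1e-6 m/s = 1e-18 N = 1e-6 pN per
#: unit of the product, times the 1e3 from mPa.s): the net factor is 1e-3.
_DRAG_TO_PN = 1.0e-3


@dataclass(frozen=True)
class ForceLedger:
    """Componentwise force balance, in pN, for a cell swimming along +x."""

    F_th: tuple[float, float]
    F_hd: tuple[float, float]
    F_cf: tuple[float, float]
    regime: str  # "weak" | "strong"

    def total(self) -> tuple[float, float]:
        return (
            self.F_th[0] + self.F_hd[0] + self.F_cf[0],
            self.F_th[1] + self.F_hd[1] + self.F_cf[1],
        )

    def to_dict(self) -> dict:
        return asdict(self)


def stokes_drag(D: float, u: float, eta: float = 1.0) -> float:
    """Stokes drag magnitude 3*pi*eta*D*u in pN.

    D in um, u in um/s, eta in mPa.s.  With eta = 1, D = 10, u = 120 this
    gives 11.31 pN.
    """
    if D < 0 or u < 0 or eta < 0:
        raise ValueError("Stokes drag inputs must be non-negative")
    return 3.0 * np.pi * eta * D * u * _DRAG_TO_PN


def thrust_estimate(D: float = 10.0, u_weak: float = 120.0, eta: float = 1.0) -> tuple[float, float]:
    """Flagellar thrust vector (pN) from the weak-confinement drag balance.

    The thrust balances the Stokes drag at the weak-confinement speed and
    points along -x in the convention where forces on the fluid are
    booked; it is carried over unchanged to the strong regime
    (constant-thrust assumption, u proportional to 1/eta).
    """
    return (-stokes_drag(D, u_weak, eta), 0.0)


def contact_friction_bound(
    F_th_mag: float, D: float = 10.0, u_strong: float = 4.0, eta: float = 1.0
) -> float:
    """Upper bound on |F_cf| in pN: thrust minus minimal Stokes drag.

    The hydrodynamic drag under strong confinement is at least the
    unconfined Stokes drag at the (slow) strong-confinement speed; the
    contact friction therefore at most makes up the remainder of the
    thrust.  A negative remainder is clamped to zero with a warning (the
    cell is then force-balanced hydrodynamically).
    """
    if u_strong < 0:
        raise ValueError("speed must be non-negative")
    bound = F_th_mag - stokes_drag(D, u_strong, eta)
    if bound < 0:
        warnings.warn(
            "Stokes drag exceeds the thrust estimate; the cell is "
            "hydrodynamically force-balanced and the contact bound is 0"
        )
        return 0.0
    return bound


def build_ledger(
    D: float = 10.0,
    u_weak: float = 120.0,
    u_strong: float = 4.0,
    eta: float = 1.0,
    regime: str = "strong",
) -> ForceLedger:
    """Assemble a closed force ledger for the requested regime.

    Weak regime: F_cf = 0 and F_th = -F_hd.  Strong regime: F_hd is the
    minimal Stokes drag at ``u_strong`` and F_cf closes the balance, so
    the three forces sum to zero by construction.
    """
    F_th = thrust_estimate(D, u_weak, eta)
    if regime == "weak":
        return ForceLedger(F_th, (-F_th[0], 0.0), (0.0, 0.0), "weak")
    if regime != "strong":
        raise ValueError(f"regime must be 'weak' or 'strong', got {regime!r}")
    hd = stokes_drag(D, u_strong, eta)
    cf = contact_friction_bound(-F_th[0], D, u_strong, eta)
    return ForceLedger(F_th, (hd, 0.0), (cf, 0.0), "strong")


def percent_speed_reduction(u_weak: float = 122.14, u_strong: float = 4.07) -> float:
    """Percent decrease of mean swimming speed, 100 * (1 - u_strong/u_weak)."""
    if u_weak <= 0:
        raise ValueError("weak-confinement speed must be positive")
    return 100.0 * (1.0 - u_strong / u_weak)
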