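"""Scalar and geometric observables of a gridded flow field.

Stagnation points, vortex centres with their circulation sense, radial
speed profiles, the normalized spatial velocity-velocity correlation and
its 1/e decay length, a Peclet number helper, and the viscous power
dissipated by the full quasi-2D field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .brinkman_core import FlowField, Medium

__all__ = [
    "CorrelationCurve",
    "VortexCentre",
    "CriticalPointSet",
    "find_stagnation_on_axis",
    "find_vortex_centres",
    "dominant_vortex_sense",
    "radial_speed_profiles",
    "velocity_correlation",
    "peclet_number",
    "solute_diffusivity_um2s",
    "dissipated_power",
]


@dataclass
class CorrelationCurve:
    """Radially binned, normalized velocity autocorrelation.

    ``R`` holds the lower edge of each radial bin (the convention under
    which the model curves reproduce the printed decay lengths);
    ``lam`` is the first 1/e crossing by linear interpolation, or None.
    """

    R: np.ndarray
    Cvv: np.ndarray
    lam: float | None = None

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"R_um": self.R, "Cvv": self.Cvv}).to_csv(path, index=False)


@dataclass(frozen=True)
class VortexCentre:
    x: float
    y: float
    sense: int  # sign of the local vorticity
    vorticity: float
    circulation: float  # integral of vorticity over a small disc around the core

    @property
    def dist_centre(self) -> float:
        return float(np.hypot(self.x, self.y))

    @property
    def dist_axis(self) -> float:
        return float(abs(self.y))


@dataclass
class CriticalPointSet:
    stagnation_points: list[tuple[float, float]] = dc_field(default_factory=list)
    vortices: list[VortexCentre] = dc_field(default_factory=list)


def find_stagnation_on_axis(
    field: FlowField,
    x_min: float = 0.0,
    x_max: float | None = None,
) -> float | None:
    """Distance of the first anterior on-axis zero of vx beyond ``x_min``.

    Scans vx along the +x ray at y = 0 (nearest grid line), refines the
    first sign change by linear interpolation, and returns its distance
    from the origin in um, or None when vx does not change sign.
    """
    iy = int(np.argmin(np.abs(field.y)))
    xs = field.x
    sel = xs >= x_min
    if x_max is not None:
        sel &= xs <= x_max
    valid_line = field.valid()[:, iy] & sel
    if not np.any(valid_line):
        raise ValueError("the requested ray is entirely masked")
    xr = xs[valid_line]
    vr = field.vx[valid_line, iy]
    if np.all(vr == 0):
        return float(abs(xr[0]))
    sgn = np.sign(vr)
    nz = sgn != 0
    crossings = np.where(np.diff(np.where(nz, sgn, np.nan)) != 0)[0]
    for c in crossings:
        v1, v2 = vr[c], vr[c + 1]
        if not np.isfinite(v1) or not np.isfinite(v2) or v1 == v2:
            continue
        xz = xr[c] - v1 * (xr[c + 1] - xr[c]) / (v2 - v1)
        return float(abs(xz))
    return None


def _refine_zero(field: FlowField, i: int, j: int) -> tuple[float, float]:
    """Newton refinement of a velocity zero inside plaquette (i, j).

    Uses the bilinear interpolant of the four plaquette corners; falls
    back to the plaquette centre when the iteration leaves the cell.
    """
    vx = field.vx[i : i + 2, j : j + 2]
    vy = field.vy[i : i + 2, j : j + 2]
    s, t = 0.5, 0.5
    for _ in range(30):
        bx = (
            vx[0, 0] * (1 - s) * (1 - t) + vx[1, 0] * s * (1 - t)
            + vx[0, 1] * (1 - s) * t + vx[1, 1] * s * t
        )
        by = (
            vy[0, 0] * (1 - s) * (1 - t) + vy[1, 0] * s * (1 - t)
            + vy[0, 1] * (1 - s) * t + vy[1, 1] * s * t
        )
        J = np.array(
            [
                [
                    (vx[1, 0] - vx[0, 0]) * (1 - t) + (vx[1, 1] - vx[0, 1]) * t,
                    (vx[0, 1] - vx[0, 0]) * (1 - s) + (vx[1, 1] - vx[1, 0]) * s,
                ],
                [
                    (vy[1, 0] - vy[0, 0]) * (1 - t) + (vy[1, 1] - vy[0, 1]) * t,
                    (vy[0, 1] - vy[0, 0]) * (1 - s) + (vy[1, 1] - vy[1, 0]) * s,
                ],
            ]
        )
        try:
            ds, dt = np.linalg.solve(J, [-bx, -by])
        except np.linalg.LinAlgError:
            break
        s, t = s + ds, t + dt
        if not (0.0 <= s <= 1.0 and 0.0 <= t <= 1.0):
            s, t = 0.5, 0.5
            break
        if abs(ds) + abs(dt) < 1e-10:
            break
    return (
        field.x[i] + s * field.spacing[0],
        field.y[j] + t * field.spacing[1],
    )


def find_vortex_centres(
    field: FlowField,
    circulation_radius: float = 3.0,
) -> CriticalPointSet:
    """Velocity zeros with winding number +1 on grid plaquettes.

    The winding number is the total change of the velocity angle summed
    around each plaquette; +1 marks a vortex core (saddles give -1).
    Cores are subpixel-refined on the bilinear interpolant and tagged
    with the sign of the local central-difference vorticity and the
    vorticity integral over a disc of ``circulation_radius``.
    """
    if min(field.shape) < 3:
        raise ValueError("vortex detection needs at least a 3x3 grid")
    ang = np.arctan2(field.vy, field.vx)

    def wrap(a):
        return (a + np.pi) % (2 * np.pi) - np.pi

    wind = (
        wrap(ang[1:, :-1] - ang[:-1, :-1])
        + wrap(ang[1:, 1:] - ang[1:, :-1])
        + wrap(ang[:-1, 1:] - ang[1:, 1:])
        + wrap(ang[:-1, :-1] - ang[:-1, 1:])
    ) / (2 * np.pi)

    valid = field.valid()
    plaq_ok = valid[1:, :-1] & valid[1:, 1:] & valid[:-1, 1:] & valid[:-1, :-1]

    # plaquettes touching an exactly-zero node have an undefined angle;
    # those zeros are picked up by the node-ring pass below
    speed = np.hypot(field.vx, field.vy)
    tiny = 1e-12 * max(speed.max(), 1.0)
    nz = speed > tiny
    plaq_ok &= nz[1:, :-1] & nz[1:, 1:] & nz[:-1, 1:] & nz[:-1, :-1]

    om = field.vorticity()
    xg, yg = field.meshgrid()
    out = CriticalPointSet()

    def add(xc, yc, i, j):
        disc = (np.hypot(xg - xc, yg - yc) <= circulation_radius) & valid
        circ = float(np.sum(om[disc]) * field.spacing[0] * field.spacing[1])
        om_core = float(om[i, j])
        out.vortices.append(
            VortexCentre(float(xc), float(yc), int(np.sign(om_core)), om_core, circ)
        )

    for i, j in zip(*np.where((wind > 0.5) & plaq_ok)):
        xc, yc = _refine_zero(field, i, j)
        add(xc, yc, i, j)

    ring = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
    for i, j in zip(*np.where(~nz & valid)):
        if not (0 < i < field.shape[0] - 1 and 0 < j < field.shape[1] - 1):
            continue
        angs = [ang[i + di, j + dj] for di, dj in ring]
        if not all(nz[i + di, j + dj] for di, dj in ring):
            continue
        w = sum(wrap(b - a) for a, b in zip(angs, angs[1:] + angs[:1])) / (2 * np.pi)
        if w > 0.5:
            add(field.x[i], field.y[j], i, j)
    return out


def dominant_vortex_sense(field: FlowField, y_min: float = 1.0) -> int:
    """Circulation sense of the dominant upper-half-plane vortex flow.

    Sign of the net vorticity integrated over the unmasked upper half
    plane (|y| > ``y_min`` strip excluded to avoid the symmetry axis).
    Positive for the bulk/weak-confinement puller pattern of the
    three-force presets; negative for the inverted two-force pattern.
    """
    om = field.vorticity()
    _, yg = field.meshgrid()
    sel = (yg > y_min) & field.valid()
    return int(np.sign(np.sum(om[sel])))


def radial_speed_profiles(
    field: FlowField, lateral_x0: float = 8.0
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """|v| along the anterior (+x) and posterior (-x) rays and along the
    vertical line through (lateral_x0, 0).

    Returns a dict of (distance-from-axis-origin, speed) pairs; masked
    cells are dropped.
    """
    xs, ys = field.x, field.y
    if not (xs[0] <= lateral_x0 <= xs[-1]):
        raise ValueError(f"lateral line x0={lateral_x0} outside the grid")
    iy0 = int(np.argmin(np.abs(ys)))
    speed = field.speed()
    valid = field.valid()

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    ant = (xs >= 0) & valid[:, iy0]
    out["anterior"] = (xs[ant], speed[ant, iy0])
    post = (xs <= 0) & valid[:, iy0]
    out["posterior"] = (np.abs(xs[post]), speed[post, iy0])
    ix0 = int(np.argmin(np.abs(xs - lateral_x0)))
    lat = valid[ix0, :]
    out["lateral"] = (ys[lat], speed[ix0, lat])
    return out


def _fft_autocorr_maps(field: FlowField):
    n0, n1 = field.shape
    W = field.valid().astype(float)
    num = np.zeros((2 * n0, 2 * n1))
    for comp in (field.vx, field.vy):
        A = comp * W
        P = np.fft.rfft2(A, s=(2 * n0, 2 * n1))
        num += np.fft.irfft2(P * np.conj(P), s=(2 * n0, 2 * n1))
    Pw = np.fft.rfft2(W, s=(2 * n0, 2 * n1))
    cnt = np.fft.irfft2(Pw * np.conj(Pw), s=(2 * n0, 2 * n1))
    sx = np.fft.fftfreq(2 * n0) * 2 * n0 * field.spacing[0]
    sy = np.fft.fftfreq(2 * n1) * 2 * n1 * field.spacing[1]
    R = np.hypot(sx[:, None], sy[None, :])
    return num, cnt, R


def velocity_correlation(
    field: FlowField,
    bin_width: float = 1.0,
    max_lag: float | None = None,
    method: str = "fft",
) -> CorrelationCurve:
    """Normalized spatial velocity-velocity correlation Cvv(R).

    ``Cvv(R) = <v(r) . v(r + R)> / <v . v>`` averaged over all unmasked
    point pairs whose separation falls in ``[R, R + bin_width)``.  The
    decay length ``lam`` is the first crossing of 1/e, linearly
    interpolated between bins.

    ``method='fft'`` uses zero-padded FFT autocorrelation with mask
    correction; ``method='direct'`` bins every pair explicitly (oracle
    path for small grids).
    """
    valid = field.valid()
    if valid.sum() < 2:
        raise ValueError("need at least two unmasked grid points")
    v2_mean = float(np.mean(field.vx[valid] ** 2 + field.vy[valid] ** 2))
    if v2_mean == 0:
        raise ValueError("cannot normalize the correlation of a zero field")

    if max_lag is None:
        max_lag = 0.6 * max(
            field.spacing[0] * field.shape[0], field.spacing[1] * field.shape[1]
        )
    edges = np.arange(0.0, max_lag + bin_width, bin_width)

    if method == "fft":
        num, cnt, R = _fft_autocorr_maps(field)
        num_b = np.histogram(R.ravel(), bins=edges, weights=num.ravel())[0]
        cnt_b = np.histogram(R.ravel(), bins=edges, weights=cnt.ravel())[0]
    elif method == "direct":
        xg, yg = field.meshgrid()
        pts = np.column_stack([xg[valid], yg[valid]])
        vel = np.column_stack([field.vx[valid], field.vy[valid]])
        n = len(pts)
        num_b = np.zeros(len(edges) - 1)
        cnt_b = np.zeros(len(edges) - 1)
        chunk = max(1, 10_000_000 // max(n, 1))
        for a in range(0, n, chunk):
            b = min(a + chunk, n)
            d = np.linalg.norm(pts[a:b, None, :] - pts[None, :, :], axis=-1)
            dots = vel[a:b] @ vel.T
            num_b += np.histogram(d.ravel(), bins=edges, weights=dots.ravel())[0]
            cnt_b += np.histogram(d.ravel(), bins=edges)[0]
    else:
        raise ValueError(f"unknown method {method!r}")

    ok = cnt_b > 0
    Cvv = np.full(len(edges) - 1, np.nan)
    Cvv[ok] = num_b[ok] / cnt_b[ok] / v2_mean
    Rb = edges[:-1]

    lam = None
    target = 1.0 / np.e
    for b in range(len(Cvv) - 1):
        c0, c1 = Cvv[b], Cvv[b + 1]
        if np.isfinite(c0) and np.isfinite(c1) and c0 >= target > c1:
            lam = float(Rb[b] + (c0 - target) / (c0 - c1) * (Rb[b + 1] - Rb[b]))
            break
    return CorrelationCurve(Rb, Cvv, lam)


def peclet_number(V: float, lV: float, DS: float) -> float:
    """Pe = V * lV / DS for flow speed V (um/s), vortex diameter lV (um)
    and solute diffusivity DS (um^2/s)."""
    if V <= 0 or lV <= 0 or DS <= 0:
        raise ValueError("Peclet inputs must be positive")
    return V * lV / DS


def solute_diffusivity_um2s(DS_m2s: float = 1.0e-9) -> float:
    """Convert a diffusivity in m^2/s to um^2/s (1e-9 m^2/s -> 1000)."""
    return DS_m2s * 1.0e12


def dissipated_power(field: FlowField, medium: Medium) -> float:
    """Viscous power dissipated by the full quasi-2D flow, in pN.um/s.

    With ``v = v0(x, y) cos(pi z / H)``, the z-integral of the dissipation
    density ``2 eta e_ij e_ij`` gives, per unit area,

        (H/2) * [ 2 eta (e_xx0^2 + e_yy0^2 + 2 e_xy0^2) + eta (pi/H)^2 |v0|^2 ]

    (weights H/2 from the cos^2 and sin^2 integrals; the z-shear enters as
    ``eta (pi/H)^2 |v0|^2`` since e_xz = -(pi/2H) v0x sin(pi z/H)).
    Masked cells are excluded from the area sum.
    """
    if medium.H <= 0:
        raise ValueError("dissipation needs a valid chamber height")
    eta = medium.eta_pn
    H = medium.H
    dx, dy = field.spacing
    exx = np.gradient(field.vx, dx, axis=0)
    eyy = np.gradient(field.vy, dy, axis=1)
    exy = 0.5 * (np.gradient(field.vx, dy, axis=1) + np.gradient(field.vy, dx, axis=0))
    density = 2.0 * eta * (exx**2 + eyy**2 + 2.0 * exy**2) + eta * (np.pi / H) ** 2 * (
        field.vx**2 + field.vy**2
    )
    valid = field.valid()
    return float((H / 2.0) * np.sum(density[valid]) * dx * dy)
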