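"""Quasi-2D Brinkman flow synthesis for confined microswimmers.

A swimmer confined between two no-slip plates a distance ``H`` apart drives
a flow whose z-profile is well approximated by the first Fourier mode,
``v(x, y, z) = v0(x, y) * cos(pi * z / H)``.  Substituting this ansatz into
the Stokes equations yields a 2D Brinkman equation for the mid-plane
profile ``v0`` with screening wavenumber ``kappa = pi / H``.  In Fourier
space the velocity response to a point force ``F`` is

    v_k = (1 - k_hat k_hat) . F / (eta * (k^2 + kappa^2))

optionally regularized by a Gaussian envelope ``exp(-k^2 sigma^2 / 2)`` for
spatially spread (flagellar) forces.  This module builds such spectra,
inverts them on padded FFT grids, and superposes them into swimmer models.

Units are fixed package wide: micrometres, seconds, piconewtons, and
millipascal-seconds for viscosity (1 mPa.s = 1e-3 pN.s/um^2).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.special import k0 as _K0, k1 as _K1

__all__ = [
    "MPAS_TO_PN",
    "Medium",
    "ForceElement",
    "Pose",
    "SwimmerModel",
    "SpectralField",
    "GridSpec",
    "FlowField",
    "PRESET_NAMES",
    "swimmer_preset",
    "spectral_green",
    "gaussian_spectral_green",
    "synthesize_flow",
    "point_stokeslet_closed_form",
    "liron_mochon_far_field",
    "multi_swimmer_flow",
    "read_flowfield_csv",
    "write_flowfield_csv",
    "read_flowfield_hdf5",
    "write_flowfield_hdf5",
]

#: 1 mPa.s expressed in pN.s/um^2.
MPAS_TO_PN = 1.0e-3


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Medium:
    """Chamber and fluid parameters.

    Parameters
    ----------
    H : float
        Chamber height in um.
    eta : float
        Dynamic viscosity in mPa.s.
    DS : float
        Solute diffusivity in um^2/s (default 1e3, i.e. 1e-9 m^2/s).
    """

    H: float
    eta: float = 1.0
    DS: float = 1.0e3

    def __post_init__(self) -> None:
        if not (self.H > 0 and np.isfinite(self.H)):
            raise ValueError(f"chamber height must be positive, got {self.H}")
        if not (self.eta > 0 and np.isfinite(self.eta)):
            raise ValueError(f"viscosity must be positive, got {self.eta}")

    @property
    def kappa(self) -> float:
        """Screening wavenumber pi/H in 1/um."""
        return np.pi / self.H

    @property
    def eta_pn(self) -> float:
        """Viscosity in pN.s/um^2."""
        return self.eta * MPAS_TO_PN


@dataclass(frozen=True)
class ForceElement:
    """A point (``spread == 0``) or Gaussian force monopole.

    ``position`` is in the cell frame (um), ``strength`` in pN and
    ``spread`` is the Gaussian standard deviation sigma in um.
    """

    position: tuple[float, float]
    strength: tuple[float, float]
    spread: float = 0.0

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ValueError(f"spread must be >= 0, got {self.spread}")
        vals = (*self.position, *self.strength, self.spread)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite force element: {self}")
        object.__setattr__(self, "position", tuple(float(v) for v in self.position))
        object.__setattr__(self, "strength", tuple(float(v) for v in self.strength))


@dataclass(frozen=True)
class Pose:
    """Swimmer centre position (um) and heading angle (rad, 0 == +x)."""

    x: float = 0.0
    y: float = 0.0
    theta: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.x == 0.0 and self.y == 0.0 and self.theta == 0.0

    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class SwimmerModel:
    """A collection of force elements in a medium, with a pose.

    The cell frame convention is: cell centre at the origin, swimming
    direction +x ("anterior"), right-handed axes.
    """

    elements: tuple[ForceElement, ...]
    medium: Medium
    pose: Pose = Pose()
    flagellum_length: float = 11.0
    beat_frequency: float = 50.0
    name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) == 0:
            raise ValueError("swimmer model needs at least one force element")

    def with_pose(self, x: float, y: float, theta: float) -> "SwimmerModel":
        return replace(self, pose=Pose(x, y, theta))

    def lab_elements(self) -> list[ForceElement]:
        """Elements translated/rotated into the lab frame by the pose."""
        R = self.pose.rotation()
        out = []
        for el in self.elements:
            p = R @ np.asarray(el.position) + np.array([self.pose.x, self.pose.y])
            f = R @ np.asarray(el.strength)
            out.append(ForceElement(tuple(p), tuple(f), el.spread))
        return out

    @property
    def min_spread(self) -> float:
        return min(el.spread for el in self.elements)

    def to_config(self) -> dict:
        return {
            "H_um": self.medium.H,
            "eta_mPas": self.medium.eta,
            "elements": [
                {
                    "x_um": el.position[0],
                    "y_um": el.position[1],
                    "Fx_pN": el.strength[0],
                    "Fy_pN": el.strength[1],
                    "sigma_um": el.spread,
                }
                for el in self.elements
            ],
            "pose": {"x_um": self.pose.x, "y_um": self.pose.y, "theta_rad": self.pose.theta},
            "name": self.name,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "SwimmerModel":
        med = Medium(H=cfg["H_um"], eta=cfg.get("eta_mPas", 1.0))
        els = tuple(
            ForceElement(
                (e["x_um"], e["y_um"]), (e["Fx_pN"], e.get("Fy_pN", 0.0)), e.get("sigma_um", 0.0)
            )
            for e in cfg["elements"]
        )
        pose_cfg = cfg.get("pose", {})
        pose = Pose(
            pose_cfg.get("x_um", 0.0), pose_cfg.get("y_um", 0.0), pose_cfg.get("theta_rad", 0.0)
        )
        return cls(els, med, pose, name=cfg.get("name", "custom"))


# Flagellar force positions and the default thrust scale of the swimmer
# presets.  The geometry of every derived observable is invariant to F0.
FLAGELLAR_POSITION = (6.0, 11.0)
DEFAULT_F0 = 11.31
DEFAULT_SIGMA = 5.0  # ~ half the flagellum length

PRESET_NAMES = ("two_stokeslet", "two_gaussian", "three_stokeslet", "three_gaussian")


def swimmer_preset(
    name: str,
    H: float = 10.0,
    eta: float = 1.0,
    F0: float = DEFAULT_F0,
    sigma: float = DEFAULT_SIGMA,
) -> SwimmerModel:
    """Build one of the named swimmer models.

    ``two_stokeslet``/``two_gaussian``: forces (-F0/2, 0) at (6, +-11) um,
    the force-monopole description of a strongly confined swimmer whose
    thrust is balanced by wall contact friction.  ``three_stokeslet``/
    ``three_gaussian`` add a balancing (+F0, 0) body drag force at the
    origin, the classic neutral puller.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    med = Medium(H=H, eta=eta)
    sig = sigma if name.endswith("gaussian") else 0.0
    xf, yf = FLAGELLAR_POSITION
    els = [
        ForceElement((xf, +yf), (-F0 / 2, 0.0), sig),
        ForceElement((xf, -yf), (-F0 / 2, 0.0), sig),
    ]
    if name.startswith("three"):
        els.append(ForceElement((0.0, 0.0), (F0, 0.0), sig))
    return SwimmerModel(tuple(els), med, name=name)


@dataclass(frozen=True)
class SpectralField:
    """Fourier-space velocity amplitudes on a wavevector grid.

    ``k`` has shape (..., 2) and ``vk`` the matching complex amplitudes.
    Transversality ``k . v_k == 0`` holds for every k != 0.
    """

    k: np.ndarray
    vk: np.ndarray

    def max_transversality_residual(self) -> float:
        dot = np.abs(np.sum(self.k * self.vk, axis=-1))
        scale = np.linalg.norm(self.k, axis=-1) * np.linalg.norm(self.vk, axis=-1)
        ok = scale > 0
        if not np.any(ok):
            return 0.0
        return float(np.max(dot[ok] / scale[ok]))


@dataclass(frozen=True)
class GridSpec:
    """A regular 2D grid: ``x = origin[0] + i*dx``, ``y = origin[1] + j*dy``."""

    origin: tuple[float, float]
    spacing: tuple[float, float]
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("grid spacing must be positive")

    @classmethod
    def centered(cls, window: float, spacing: float = 1.0) -> "GridSpec":
        """Square grid spanning [-window/2, window/2] in both axes."""
        n = int(round(window / spacing))
        half = n // 2
        n = 2 * half + 1
        return cls((-half * spacing, -half * spacing), (spacing, spacing), (n, n))

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.shape[0])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.shape[1])


@dataclass
class FlowField:
    """Gridded mid-plane velocity profile ``v0(x, y)``.

    Arrays are indexed ``[ix, iy]``.  ``mask`` follows the numpy masked
    array convention: True marks an invalid (masked) cell.  The full 3D
    field is ``v0(x, y) * cos(pi z / H)`` by construction.
    """

    origin: tuple[float, float]
    spacing: tuple[float, float]
    vx: np.ndarray
    vy: np.ndarray
    mask: np.ndarray | None = None
    frame: str = "cell"

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.shape != self.vy.shape:
            raise ValueError("vx and vy must have the same shape")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.vx.shape:
                raise ValueError("mask must match the velocity arrays")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("grid spacing must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.vx.shape

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.shape[0])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.shape[1])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y, indexing="ij")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.origin, self.spacing, self.shape)

    # -- derived fields -----------------------------------------------------
    def valid(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        return ~self.mask

    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def vorticity(self) -> np.ndarray:
        """omega = d(vy)/dx - d(vx)/dy by central differences."""
        dvy_dx = np.gradient(self.vy, self.spacing[0], axis=0)
        dvx_dy = np.gradient(self.vx, self.spacing[1], axis=1)
        return dvy_dx - dvx_dy

    def divergence(self) -> np.ndarray:
        return np.gradient(self.vx, self.spacing[0], axis=0) + np.gradient(
            self.vy, self.spacing[1], axis=1
        )

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Bilinear sample of (vx, vy) at ``points`` of shape (n, 2).

        Points outside the grid evaluate to zero.
        """
        from scipy.interpolate import RegularGridInterpolator

        pts = np.atleast_2d(points)
        out = np.empty((pts.shape[0], 2))
        for i, comp in enumerate((self.vx, self.vy)):
            itp = RegularGridInterpolator(
                (self.x, self.y), comp, bounds_error=False, fill_value=0.0
            )
            out[:, i] = itp(pts)
        return out


# ---------------------------------------------------------------------------
# spectral Green's functions
# ---------------------------------------------------------------------------

def spectral_green(k: np.ndarray, F: np.ndarray, medium: Medium) -> np.ndarray:
    """Fourier-space velocity amplitude of a point force.

    Implements ``v_k = (1 - k_hat k_hat) . F / (eta (k^2 + kappa^2))``.
    The k = 0 mode is set to zero (zero-mean-flow convention; the
    transverse projector has no limit there and a constant offset is
    unobservable in any correlation or RMSD analysis).

    Parameters
    ----------
    k : array, shape (..., 2)
        Wavevectors in 1/um.
    F : array, shape (2,) or broadcastable to k
        Force in pN.
    """
    k = np.asarray(k, dtype=float)
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(k)) or not np.all(np.isfinite(F)):
        raise ValueError("non-finite wavevector or force")
    k2 = np.sum(k * k, axis=-1)
    kdotF = np.sum(k * np.broadcast_to(F, k.shape), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        proj = np.broadcast_to(F, k.shape) - k * (kdotF / k2)[..., None]
    denom = medium.eta_pn * (k2 + medium.kappa**2)
    out = np.where((k2 == 0)[..., None], 0.0, proj / denom[..., None])
    return out


def gaussian_spectral_green(
    k: np.ndarray, F: np.ndarray, sigma: float, medium: Medium
) -> np.ndarray:
    """Spectral amplitude of a Gaussian-regularized force of spread sigma."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    base = spectral_green(k, F, medium)
    if sigma == 0:
        return base
    k2 = np.sum(np.asarray(k, dtype=float) ** 2, axis=-1)
    return base * np.exp(-k2 * sigma**2 / 2.0)[..., None]


# ---------------------------------------------------------------------------
# FFT synthesis
# ---------------------------------------------------------------------------

def _padded_axis(origin: float, spacing: float, n: int, h: float, L_min: float):
    """Node coordinates of a padded FFT axis containing the requested nodes.

    Returns (coords, index of the first requested node, stride).
    """
    stride = int(round(spacing / h))
    span = spacing * (n - 1)
    n_pad_total = int(np.ceil(max(L_min, span) / h))
    n_left = max((n_pad_total - (n - 1) * stride) // 2, 0)
    N = n_left + (n - 1) * stride + 1 + n_left
    if N % 2:
        N += 1
    coords = (origin - n_left * h) + h * np.arange(N)
    return coords, n_left, stride


def synthesize_flow(
    model: SwimmerModel,
    grid: GridSpec,
    *,
    pad_factor: float = 4.0,
    internal_spacing: float | None = None,
    mask_point_cores: bool = True,
    aliasing: str = "warn",
) -> FlowField:
    """Mid-plane (z = 0) flow of a swimmer model by inverse 2D FFT.

    The spectra of all elements are superposed (each translated to its
    element position by a phase factor) on a periodic grid padded to at
    least ``pad_factor`` times the requested window and ``16 / kappa``,
    then inverted and sampled on the requested grid.

    For point elements a disc of radius ``max(dx, 0.5) um`` around each
    element is masked (logarithmic near-field singularity).

    Parameters
    ----------
    internal_spacing : float, optional
        Spacing of the internal FFT grid; defaults to
        ``min(0.5, dx, sigma/4 if sigma > 0)``.  It is snapped so that it
        divides the requested spacing exactly.
    """
    dx, dy = grid.spacing
    medium = model.medium
    sig_min = model.min_spread
    if internal_spacing is None:
        h_target = min(0.5, dx, dy)
        if sig_min > 0:
            h_target = min(h_target, sig_min / 4.0) if sig_min / 4.0 < 0.5 else h_target
    else:
        h_target = internal_spacing
    # snap: h must divide both dx and dy
    h = dx / max(1, int(np.ceil(dx / h_target)))
    if abs(dy / h - round(dy / h)) > 1e-9:
        h = min(dx, dy) / max(1, int(np.ceil(min(dx, dy) / h_target)))
        if abs(dx / h - round(dx / h)) > 1e-9 or abs(dy / h - round(dy / h)) > 1e-9:
            raise ValueError("grid spacings must be commensurate for FFT synthesis")

    span = max(dx * (grid.shape[0] - 1), dy * (grid.shape[1] - 1))
    L_min = max(pad_factor * span, 16.0 / medium.kappa)

    lab_els = model.lab_elements()
    xs_pos = [el.position[0] for el in lab_els]
    ys_pos = [el.position[1] for el in lab_els]
    win_x = (grid.x[0], grid.x[-1])
    win_y = (grid.y[0], grid.y[-1])
    if (
        min(xs_pos) < win_x[0] - span or max(xs_pos) > win_x[1] + span
        or min(ys_pos) < win_y[0] - span or max(ys_pos) > win_y[1] + span
    ):
        msg = "force elements far outside the requested window; aliasing possible"
        if aliasing == "error":
            raise ValueError(msg)
        warnings.warn(msg)

    xc, ix0, sx = _padded_axis(grid.origin[0], dx, grid.shape[0], h, L_min)
    yc, iy0, sy = _padded_axis(grid.origin[1], dy, grid.shape[1], h, L_min)
    Nx, Ny = len(xc), len(yc)

    kx = 2 * np.pi * np.fft.fftfreq(Nx, d=h)[:, None]
    ky = 2 * np.pi * np.fft.rfftfreq(Ny, d=h)[None, :]
    k2 = kx * kx + ky * ky
    inv_denom = 1.0 / (medium.eta_pn * (k2 + medium.kappa**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_k2 = np.where(k2 > 0, 1.0 / k2, 0.0)

    vkx = np.zeros(k2.shape, dtype=complex)
    vky = np.zeros(k2.shape, dtype=complex)
    for el in lab_els:
        Fx, Fy = el.strength
        # transverse projection of F
        kdF = kx * Fx + ky * Fy
        px = Fx - kx * kdF * inv_k2
        py = Fy - ky * kdF * inv_k2
        amp = inv_denom.copy()
        if el.spread > 0:
            amp *= np.exp(-k2 * el.spread**2 / 2.0)
        phase = np.exp(-1j * (kx * (el.position[0] - xc[0]) + ky * (el.position[1] - yc[0])))
        vkx += px * amp * phase
        vky += py * amp * phase
    vkx[0, 0] = 0.0
    vky[0, 0] = 0.0

    vx_full = np.fft.irfft2(vkx, s=(Nx, Ny)) / (h * h)
    vy_full = np.fft.irfft2(vky, s=(Nx, Ny)) / (h * h)

    ix = ix0 + sx * np.arange(grid.shape[0])
    iy = iy0 + sy * np.arange(grid.shape[1])
    vx = vx_full[np.ix_(ix, iy)].copy()
    vy = vy_full[np.ix_(ix, iy)].copy()

    mask = None
    if mask_point_cores:
        eps = max(dx, dy, 0.5)
        xg, yg = np.meshgrid(grid.x, grid.y, indexing="ij")
        m = np.zeros(vx.shape, dtype=bool)
        for el in lab_els:
            if el.spread == 0:
                m |= np.hypot(xg - el.position[0], yg - el.position[1]) <= eps
        if np.any(m):
            mask = m

    frame = "cell" if model.pose.is_identity else "lab"
    return FlowField(grid.origin, grid.spacing, vx, vy, mask=mask, frame=frame)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def _brinkmanlet_AB(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # A(z) I + B(z) r_hat r_hat is the screened 2D Stokeslet kernel; the
    # modified-Bessel form follows from inverting the transverse projector
    # against 1/(k^2 + kappa^2).
    A = _K0(z) + _K1(z) / z - 1.0 / z**2
    B = -_K0(z) - 2.0 * _K1(z) / z + 2.0 / z**2
    return A, B


def point_stokeslet_closed_form(r: np.ndarray, F: np.ndarray, medium: Medium) -> np.ndarray:
    """Closed-form mid-plane flow of a point force at the origin.

    ``v(r) = [A(kr) I + B(kr) r_hat r_hat] . F / (2 pi eta)`` with
    ``A = K0 + K1/(kr) - 1/(kr)^2`` and ``B = -K0 - 2 K1/(kr) + 2/(kr)^2``.
    For ``kr >> 1`` this reduces to the potential-dipole far field
    ``(2 r_hat r_hat - I) . F / (2 pi eta kappa^2 r^2)``.
    """
    r = np.asarray(r, dtype=float)
    F = np.asarray(F, dtype=float)
    single = r.ndim == 1
    pts = np.atleast_2d(r)
    rad = np.linalg.norm(pts, axis=-1)
    if np.any(rad == 0):
        raise ValueError("point Stokeslet is singular at r = 0")
    z = medium.kappa * rad
    A, B = _brinkmanlet_AB(z)
    rhat = pts / rad[:, None]
    rdotF = rhat @ F
    pref = 1.0 / (2.0 * np.pi * medium.eta_pn)
    v = pref * (A[:, None] * F + (B * rdotF)[:, None] * rhat)
    return v[0] if single else v


def liron_mochon_far_field(r: np.ndarray, F: np.ndarray, medium: Medium) -> np.ndarray:
    """Mid-plane far field of a parallel Stokeslet between plates.

    The classic recursive-image solution decays exponentially to a 2D
    source-dipole form; at the mid-plane (force and observation both at
    z = H/2 from a wall) it reads

        v(r) = (3 H / (32 pi eta)) (2 r_hat r_hat - I) . F / r^2

    This is intended only for qualitative comparison with the Brinkman
    solution for ``r >~ H``; it shares the far-field angular structure but
    lacks the Bessel near field.
    """
    r = np.asarray(r, dtype=float)
    F = np.asarray(F, dtype=float)
    single = r.ndim == 1
    pts = np.atleast_2d(r)
    rad = np.linalg.norm(pts, axis=-1)
    if np.any(rad == 0):
        raise ValueError("far-field expression is singular at r = 0")
    rhat = pts / rad[:, None]
    rdotF = rhat @ F
    pref = 3.0 * medium.H / (32.0 * np.pi * medium.eta_pn)
    v = pref * (2.0 * (rdotF)[:, None] * rhat - F[None, :]) / (rad**2)[:, None]
    return v[0] if single else v


def multi_swimmer_flow(
    models: list[SwimmerModel],
    grid: GridSpec,
    *,
    exclusion_radius: float = 0.5,
    **synth_kwargs,
) -> FlowField:
    """Superposed flow of several posed swimmers on one grid.

    Equals :func:`synthesize_flow` for a single swimmer with identity
    pose.  Warns when force elements of different swimmers overlap within
    ``exclusion_radius``.
    """
    if len(models) == 0:
        raise ValueError("need at least one swimmer model")
    all_pos = []
    for m in models:
        all_pos.extend([el.position for el in m.lab_elements()])
    pos = np.asarray(all_pos)
    if len(pos) > 1:
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.min(d) < exclusion_radius:
            warnings.warn(
                f"force elements overlap within {exclusion_radius} um; "
                "superposed field may be inaccurate near them"
            )
    total = None
    for m in models:
        f = synthesize_flow(m, grid, **synth_kwargs)
        if total is None:
            total = f
        else:
            total.vx += f.vx
            total.vy += f.vy
            if f.mask is not None:
                total.mask = f.mask if total.mask is None else (total.mask | f.mask)
    total.frame = "lab"
    return total


# ---------------------------------------------------------------------------
# flow-field I/O
# ---------------------------------------------------------------------------

def write_flowfield_csv(ff: FlowField, path) -> None:
    """Long-format CSV with header x_um, y_um, vx, vy, mask."""
    import pandas as pd

    xg, yg = ff.meshgrid()
    m = ff.mask if ff.mask is not None else np.zeros(ff.shape, dtype=bool)
    df = pd.DataFrame(
        {
            "x_um": xg.ravel(),
            "y_um": yg.ravel(),
            "vx": ff.vx.ravel(),
            "vy": ff.vy.ravel(),
            "mask": m.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_flowfield_csv(path, frame: str = "cell") -> FlowField:
    import pandas as pd

    df = pd.read_csv(path)
    xs = np.unique(df["x_um"].to_numpy())
    ys = np.unique(df["y_um"].to_numpy())
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("flow-field table must span a 2D grid")
    dx = float(np.min(np.diff(xs)))
    dy = float(np.min(np.diff(ys)))
    nx, ny = len(xs), len(ys)
    ix = np.rint((df["x_um"].to_numpy() - xs[0]) / dx).astype(int)
    iy = np.rint((df["y_um"].to_numpy() - ys[0]) / dy).astype(int)
    vx = np.full((nx, ny), np.nan)
    vy = np.full((nx, ny), np.nan)
    mask = np.ones((nx, ny), dtype=bool)
    vx[ix, iy] = df["vx"].to_numpy()
    vy[ix, iy] = df["vy"].to_numpy()
    if "mask" in df.columns:
        mask[ix, iy] = df["mask"].to_numpy().astype(bool)
    else:
        mask[ix, iy] = False
    mask |= ~np.isfinite(vx) | ~np.isfinite(vy)
    vx[mask] = 0.0
    vy[mask] = 0.0
    return FlowField(
        (float(xs[0]), float(ys[0])), (dx, dy), vx, vy,
        mask=mask if mask.any() else None, frame=frame,
    )


def write_flowfield_hdf5(ff: FlowField, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("vx", data=ff.vx)
        f.create_dataset("vy", data=ff.vy)
        if ff.mask is not None:
            f.create_dataset("mask", data=ff.mask)
        f.attrs["origin"] = ff.origin
        f.attrs["spacing"] = ff.spacing
        f.attrs["frame"] = ff.frame


def read_flowfield_hdf5(path) -> FlowField:
    import h5py

    with h5py.File(path, "r") as f:
        vx = f["vx"][...]
        vy = f["vy"][...]
        mask = f["mask"][...] if "mask" in f else None
        origin = tuple(f.attrs["origin"])
        spacing = tuple(f.attrs["spacing"])
        frame = str(f.attrs.get("frame", "cell"))
    return FlowField(origin, spacing, vx, vy, mask=mask, frame=frame)


def load_model_config(path) -> SwimmerModel:
    """Read a swimmer-model config from JSON or YAML."""
    text = open(path).read()
    try:
        cfg = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        cfg = yaml.safe_load(text)
    return SwimmerModel.from_config(cfg)
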