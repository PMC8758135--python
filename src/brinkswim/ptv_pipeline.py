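"""Beat-averaged flow-field reconstruction from tracer displacements.

Mirrors the particle-tracking-velocimetry reduction chain: per-frame
tracer displacements are rotated into a common cell frame, velocity
outliers beyond six standard deviations are removed, survivors are
averaged on a 2.24 um mesh, smoothed with a mask-aware 5 x 5 uniform
filter, and bilinearly interpolated onto a 1 um grid.  A comparison
section quantifies the match of two fields by RMSD of their normalized
velocities and by polar speed profiles at fixed radii.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .brinkman_core import FlowField

__all__ = [
    "ComparisonReport",
    "read_tracks_csv",
    "records_from_tracks",
    "to_cell_frame",
    "remove_outliers",
    "grid_average",
    "smooth_field",
    "interpolate_field",
    "rmsd_compare",
    "polar_profile_compare",
    "reconstruct_field",
]

logger = logging.getLogger(__name__)

#: default frame gap, s (500 frames/s)
DEFAULT_FRAME_GAP = 2.0e-3
#: default PTV mesh size, um
DEFAULT_MESH = 2.24


@dataclass(frozen=True)
class ComparisonReport:
    """RMSD of two co-registered fields on the normalized (v/vmax) scale,
    reported in percent, plus the number of overlapping grid points."""

    rmsd_vx: float
    rmsd_vy: float
    rmsd_speed: float
    n_grid: int

    def to_dict(self) -> dict:
        return asdict(self)


_TRACK_COLUMNS = {"track_id": "track_id", "t_s": "t_s", "x_um": "x_um", "y_um": "y_um"}


def read_tracks_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a track table with columns track_id, t_s, x_um, y_um.

    ``column_map`` renames source columns (e.g. exported spreadsheet
    headers) onto the canonical names.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(_TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table lacks columns: {sorted(missing)}")
    return df


def records_from_tracks(
    tracks: pd.DataFrame,
    pose: pd.DataFrame | None = None,
    frame_gap: float = DEFAULT_FRAME_GAP,
) -> pd.DataFrame:
    """Per-frame displacement records from track tables.

    For each track, consecutive samples separated by ``frame_gap`` yield
    one record holding the tracer position, its lab-frame velocity over
    the gap, and (when ``pose`` is given, indexed or merged on ``t_s``)
    the concurrent cell pose columns cx, cy, theta.
    """
    recs = []
    for _, g in tracks.groupby("track_id", sort=False):
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy()
        x = g["x_um"].to_numpy()
        y = g["y_um"].to_numpy()
        dt = np.diff(t)
        ok = np.isclose(dt, frame_gap, rtol=1e-3)
        recs.append(
            pd.DataFrame(
                {
                    "t_s": t[:-1][ok],
                    "x_um": x[:-1][ok],
                    "y_um": y[:-1][ok],
                    "vx": np.diff(x)[ok] / dt[ok],
                    "vy": np.diff(y)[ok] / dt[ok],
                }
            )
        )
    if not recs:
        raise ValueError("no tracks supplied")
    out = pd.concat(recs, ignore_index=True)
    if pose is not None:
        pose_cols = pose[["t_s", "cx", "cy", "theta"]]
        out = pd.merge_asof(
            out.sort_values("t_s"),
            pose_cols.sort_values("t_s"),
            on="t_s",
            direction="nearest",
            tolerance=frame_gap / 2,
        )
    return out


def to_cell_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Rotate/translate displacement records into the cell frame.

    Positions are translated by the cell centre and rotated by minus the
    heading so the cell swims along +x; velocities are rotated the same
    way.  Records with a missing pose are dropped (count logged).
    """
    df = records
    for col in ("cx", "cy", "theta"):
        if col not in df.columns:
            raise ValueError("records carry no cell pose; merge one first")
    ok = df[["cx", "cy", "theta"]].notna().all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("to_cell_frame: dropped %d records without pose", dropped)
    df = df[ok]
    c = np.cos(-df["theta"].to_numpy())
    s = np.sin(-df["theta"].to_numpy())
    rx = df["x_um"].to_numpy() - df["cx"].to_numpy()
    ry = df["y_um"].to_numpy() - df["cy"].to_numpy()
    vx = df["vx"].to_numpy()
    vy = df["vy"].to_numpy()
    return pd.DataFrame(
        {
            "x": c * rx - s * ry,
            "y": s * rx + c * ry,
            "vx": c * vx - s * vy,
            "vy": s * vx + c * vy,
        }
    )


def remove_outliers(vectors: pd.DataFrame, n_sigma: float = 6.0) -> pd.DataFrame:
    """Drop records whose speed is > n_sigma SDs from the mean speed.

    Single pass over the magnitude distribution, as a deterministic
    reading of the six-sigma rule.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    mag = np.hypot(vectors["vx"].to_numpy(), vectors["vy"].to_numpy())
    mu, sd = mag.mean(), mag.std()
    keep = np.abs(mag - mu) <= n_sigma * sd
    removed = int((~keep).sum())
    if removed:
        logger.info("remove_outliers: deleted %d of %d vectors", removed, len(vectors))
    out = vectors[keep].reset_index(drop=True)
    out.attrs["removed"] = removed
    return out


def grid_average(
    vectors: pd.DataFrame,
    cell_size: float = DEFAULT_MESH,
    window: float | None = None,
    frame: str = "cell",
) -> FlowField:
    """Arithmetic per-cell mean of the velocity vectors on a square mesh.

    ``window`` fixes a symmetric extent (full width, centred on the
    origin); by default the mesh spans the data.  Empty cells are masked.
    """
    if len(vectors) == 0:
        raise ValueError("no vectors to grid")
    x = vectors["x"].to_numpy()
    y = vectors["y"].to_numpy()
    if window is not None:
        half = window / 2.0
        x0 = y0 = -half
        nx = ny = max(int(np.ceil(window / cell_size)), 1)
    else:
        x0, y0 = x.min(), y.min()
        nx = max(int(np.floor((x.max() - x0) / cell_size)) + 1, 1)
        ny = max(int(np.floor((y.max() - y0) / cell_size)) + 1, 1)
    ix = np.floor((x - x0) / cell_size).astype(int)
    iy = np.floor((y - y0) / cell_size).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    ix, iy = ix[ok], iy[ok]
    flat = ix * ny + iy
    cnt = np.bincount(flat, minlength=nx * ny).astype(float)
    sx = np.bincount(flat, weights=vectors["vx"].to_numpy()[ok], minlength=nx * ny)
    sy = np.bincount(flat, weights=vectors["vy"].to_numpy()[ok], minlength=nx * ny)
    with np.errstate(invalid="ignore"):
        vx = np.where(cnt > 0, sx / np.maximum(cnt, 1), 0.0).reshape(nx, ny)
        vy = np.where(cnt > 0, sy / np.maximum(cnt, 1), 0.0).reshape(nx, ny)
    mask = (cnt == 0).reshape(nx, ny)
    # cell centres
    origin = (x0 + cell_size / 2, y0 + cell_size / 2)
    return FlowField(origin, (cell_size, cell_size), vx, vy,
                     mask=mask if mask.any() else None, frame=frame)


def smooth_field(field: FlowField, size: int = 5) -> FlowField:
    """Mask-aware uniform moving average (default 5 x 5).

    Masked cells contribute to neither the numerator nor the count;
    edges use the truncated kernel.  Cells masked on input stay masked.
    """
    if min(field.shape) < size:
        raise ValueError(f"grid smaller than the {size}x{size} kernel")
    from scipy.ndimage import uniform_filter

    W = field.valid().astype(float)
    out = []
    for comp in (field.vx, field.vy):
        num = uniform_filter(comp * W, size=size, mode="constant", cval=0.0)
        den = uniform_filter(W, size=size, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(den > 0, num / den, 0.0)
        out.append(sm)
    mask = None if field.mask is None else field.mask.copy()
    return FlowField(field.origin, field.spacing, out[0], out[1], mask=mask, frame=field.frame)


def interpolate_field(field: FlowField, spacing: float = 1.0) -> FlowField:
    """Bilinear interpolation onto a finer grid.

    The target grid spans the source extent at the requested spacing; a
    target cell is masked when any of its four source corners is masked.
    """
    xs, ys = field.x, field.y
    nx = int(np.floor((xs[-1] - xs[0]) / spacing + 1e-9)) + 1
    ny = int(np.floor((ys[-1] - ys[0]) / spacing + 1e-9)) + 1
    if nx < 2 or ny < 2:
        raise ValueError("target window exceeds the source grid")
    tx = xs[0] + spacing * np.arange(nx)
    ty = ys[0] + spacing * np.arange(ny)

    fx = (tx - xs[0]) / field.spacing[0]
    fy = (ty - ys[0]) / field.spacing[1]
    i0 = np.clip(np.floor(fx).astype(int), 0, len(xs) - 2)
    j0 = np.clip(np.floor(fy).astype(int), 0, len(ys) - 2)
    wx = (fx - i0)[:, None]
    wy = (fy - j0)[None, :]
    I0 = i0[:, None]
    J0 = j0[None, :]

    def bilin(a):
        return (
            a[I0, J0] * (1 - wx) * (1 - wy)
            + a[I0 + 1, J0] * wx * (1 - wy)
            + a[I0, J0 + 1] * (1 - wx) * wy
            + a[I0 + 1, J0 + 1] * wx * wy
        )

    vx = bilin(field.vx)
    vy = bilin(field.vy)
    mask = None
    if field.mask is not None:
        m = field.mask
        mask = m[I0, J0] | m[I0 + 1, J0] | m[I0, J0 + 1] | m[I0 + 1, J0 + 1]
        if not mask.any():
            mask = None
    return FlowField((tx[0], ty[0]), (spacing, spacing), vx, vy, mask=mask, frame=field.frame)


def _overlap_valid(expt: FlowField, theory: FlowField) -> np.ndarray:
    if expt.shape != theory.shape:
        raise ValueError("fields must be co-registered on the same grid")
    if not np.allclose(expt.origin, theory.origin) or not np.allclose(
        expt.spacing, theory.spacing
    ):
        raise ValueError("fields must share origin and spacing")
    return expt.valid() & theory.valid()


def rmsd_compare(
    expt: FlowField,
    theory: FlowField,
    cell_mask_radius: float | None = None,
) -> ComparisonReport:
    """RMSD of two fields on the normalized (v / own vmax) scale, in %.

    Each field is normalized by its own maximum speed over the shared
    unmasked region, which makes the metric invariant to the overall
    force scale.  ``cell_mask_radius`` additionally excludes a central
    disc (the cell body) from the comparison.
    """
    valid = _overlap_valid(expt, theory)
    if cell_mask_radius is not None:
        xg, yg = expt.meshgrid()
        valid &= np.hypot(xg, yg) > cell_mask_radius
    ng = int(valid.sum())
    if ng == 0:
        raise ValueError("no overlapping unmasked grid points")
    se = expt.speed()[valid]
    st = theory.speed()[valid]
    me, mt = se.max(), st.max()
    if me == 0 or mt == 0:
        raise ValueError("cannot normalize a zero field")
    dvx = expt.vx[valid] / me - theory.vx[valid] / mt
    dvy = expt.vy[valid] / me - theory.vy[valid] / mt
    dsp = se / me - st / mt
    return ComparisonReport(
        rmsd_vx=float(np.sqrt(np.mean(dvx**2)) * 100),
        rmsd_vy=float(np.sqrt(np.mean(dvy**2)) * 100),
        rmsd_speed=float(np.sqrt(np.mean(dsp**2)) * 100),
        n_grid=ng,
    )


def polar_profile_compare(
    expt: FlowField,
    theory: FlowField,
    radii: tuple[float, ...] = (7.0, 13.0, 20.0, 30.0),
    gap: float = 1.0,
) -> dict[float, dict[str, np.ndarray]]:
    """Normalized speed versus polar angle in annuli [r, r + gap).

    The polar angle is measured from +x in [0, 2 pi).  Returns, per
    radius, sorted angle arrays with the normalized speeds of both
    fields; empty annuli are skipped with a warning.
    """
    valid = _overlap_valid(expt, theory)
    xg, yg = expt.meshgrid()
    rad = np.hypot(xg, yg)
    theta = np.mod(np.arctan2(yg, xg), 2 * np.pi)
    se = expt.speed()
    st = theory.speed()
    me = se[valid].max()
    mt = st[valid].max()
    out: dict[float, dict[str, np.ndarray]] = {}
    for r in radii:
        ring = valid & (rad >= r) & (rad < r + gap)
        if not ring.any():
            warnings.warn(f"annulus [{r}, {r + gap}) contains no unmasked points")
            continue
        order = np.argsort(theta[ring])
        out[r] = {
            "theta": theta[ring][order],
            "expt": (se[ring] / me)[order],
            "theory": (st[ring] / mt)[order],
        }
    return out


def reconstruct_field(
    records: pd.DataFrame,
    mesh: float = DEFAULT_MESH,
    smooth: int = 5,
    interp: float = 1.0,
    window: float | None = None,
    cell_mask_radius: float | None = 6.0,
) -> FlowField:
    """Full PTV chain: cell frame -> outlier removal -> grid mean ->
    smoothing -> interpolation, with an optional cell-body mask."""
    cf = to_cell_frame(records)
    cf = remove_outliers(cf)
    field = grid_average(cf, cell_size=mesh, window=window)
    field = smooth_field(field, size=smooth)
    field = interpolate_field(field, spacing=interp)
    if cell_mask_radius is not None:
        xg, yg = field.meshgrid()
        body = np.hypot(xg, yg) <= cell_mask_radius
        mask = body if field.mask is None else (field.mask | body)
        field.mask = mask
    return field
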