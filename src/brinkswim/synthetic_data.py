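"""Ground-truth-known synthetic experiments.

Generates a posed swimmer following a scripted path, the model flow it
carries, and Brownian tracers advected by that flow, sampled with the
imaging geometry of the experiments (179 um x 143 um field of view,
500 frames/s, ~8 s recordings, 200 nm tracers).  Every pipeline stage can
be validated against the generating field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .brinkman_core import FlowField, GridSpec, SwimmerModel, swimmer_preset, synthesize_flow
from .trajectory_stats import TracerSet, Trajectory

__all__ = [
    "ScenarioConfig",
    "SyntheticExperiment",
    "scenario_config",
    "make_cell_path",
    "advect_tracers",
    "make_noisy_flowfield",
]

#: Stokes-Einstein diffusivity of a 200 nm sphere in water at 295 K, um^2/s.
DEFAULT_TRACER_D = 2.2


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic experiment.

    The seed determines the output bit-for-bit.  Defaults mirror the
    imaging parameters of the experiments: 500 frames/s, 8.2 s duration,
    179 um x 143 um field of view, ~500 tracers of 200 nm diameter.
    """

    scenario: str = "H10"
    preset: str = "two_gaussian"
    H: float = 10.0
    speed: float = 4.0
    path: str = "semicircle"  # "straight" | "semicircle" | "stationary"
    fov: tuple[float, float] = (179.0, 143.0)
    frame_rate: float = 500.0
    duration: float = 8.2
    n_tracers: int = 500
    tracer_D: float = DEFAULT_TRACER_D
    seed: int = 0
    F0: float = 11.31

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate)) + 1

    def model(self) -> SwimmerModel:
        return swimmer_preset(self.preset, H=self.H, F0=self.F0)


def scenario_config(scenario: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Named scenarios mirroring the two experimental regimes.

    ``H30``: fast straight swimmer (121 um/s) with the three-Gaussian
    neutral-puller flow in a 30 um chamber.  ``H10``: slow semicircular
    swimmer (4 um/s) carrying the two-Gaussian force-monopole flow in a
    10 um chamber.
    """
    if scenario == "H10":
        cfg = ScenarioConfig(
            scenario="H10", preset="two_gaussian", H=10.0, speed=4.0,
            path="semicircle", seed=seed,
        )
    elif scenario == "H30":
        cfg = ScenarioConfig(
            scenario="H30", preset="three_gaussian", H=30.0, speed=121.0,
            path="straight", seed=seed,
        )
    elif scenario == "custom":
        cfg = ScenarioConfig(scenario="custom", seed=seed)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return replace(cfg, **overrides)


def make_cell_path(config: ScenarioConfig) -> pd.DataFrame:
    """Pose series (t_s, cx, cy, theta) for the scripted swimmer.

    Straight paths start at the left field-of-view edge and head along
    +x; a warning is issued when the swimmer exits the field of view
    before the recording ends (the pose keeps extrapolating, as the real
    cell keeps swimming).  Semicircular paths run at constant speed on a
    circle of radius ``speed * duration / pi`` centred on the origin.
    """
    t = np.arange(config.n_frames) * config.dt
    u = config.speed
    if u == 0 or config.path == "stationary":
        cx = np.zeros_like(t)
        cy = np.zeros_like(t)
        th = np.zeros_like(t)
    elif config.path == "straight":
        x0 = -config.fov[0] / 2
        cx = x0 + u * t
        cy = np.zeros_like(t)
        th = np.zeros_like(t)
        if cx[-1] > config.fov[0] / 2:
            t_exit = config.fov[0] / u
            warnings.warn(
                f"swimmer exits the field of view after {t_exit:.2f} s "
                f"of the {config.duration} s recording"
            )
    elif config.path == "semicircle":
        R = u * config.duration / np.pi
        phi = -np.pi / 2 + u * t / R
        cx = R * np.cos(phi)
        cy = R * np.sin(phi)
        th = phi + np.pi / 2
    else:
        raise ValueError(f"unknown path {config.path!r}")
    return pd.DataFrame({"t_s": t, "cx": cx, "cy": cy, "theta": th})


@dataclass
class SyntheticExperiment:
    """Tracks and pose in the lab frame plus the generating truth field."""

    config: ScenarioConfig
    tracks: pd.DataFrame  # track_id, t_s, x_um, y_um
    pose: pd.DataFrame  # t_s, cx, cy, theta
    truth: FlowField  # cell-frame model field

    def tracer_set(self) -> TracerSet:
        out = []
        for _, g in self.tracks.groupby("track_id", sort=False):
            out.append(
                Trajectory(g["t_s"].to_numpy(), g["x_um"].to_numpy(), g["y_um"].to_numpy())
            )
        return TracerSet(out, self.config.frame_rate)


def advect_tracers(
    config: ScenarioConfig,
    model: SwimmerModel | None = None,
    truth_window: float = 90.0,
    field_window: float | None = None,
    flow_field: FlowField | None = None,
) -> SyntheticExperiment:
    """Euler-Maruyama advection-diffusion of tracers in the swimmer flow.

    Per frame each tracer moves by ``v dt`` (flow sampled in the
    instantaneous cell frame) plus an independent Gaussian kick of
    standard deviation ``sqrt(2 D dt)`` per component; tracers reflect at
    the field-of-view boundary.  When the advective step would exceed
    half the flow-grid spacing the step is subdivided.

    Returns the lab-frame tracks, the pose series, and the generating
    cell-frame field on a 1 um grid over ``truth_window``.

    ``flow_field`` injects an arbitrary cell-frame field in place of the
    synthesized model flow (useful for closed-form validation).
    """
    if model is None:
        model = config.model()
    rng = np.random.default_rng(config.seed)

    if flow_field is not None:
        flow = flow_field
    else:
        if field_window is None:
            field_window = 2.0 * max(config.fov)
        flow = synthesize_flow(
            model, GridSpec.centered(field_window, 1.0),
            mask_point_cores=False, pad_factor=2.0,
        )
    from scipy.interpolate import RegularGridInterpolator

    itp_x = RegularGridInterpolator(
        (flow.x, flow.y), flow.vx, bounds_error=False, fill_value=0.0
    )
    itp_y = RegularGridInterpolator(
        (flow.x, flow.y), flow.vy, bounds_error=False, fill_value=0.0
    )

    pose = make_cell_path(config)
    cx = pose["cx"].to_numpy()
    cy = pose["cy"].to_numpy()
    th = pose["theta"].to_numpy()

    wx, wy = config.fov
    lox, hix = -wx / 2, wx / 2
    loy, hiy = -wy / 2, wy / 2
    n = config.n_tracers
    pos = np.column_stack(
        [rng.uniform(lox, hix, size=n), rng.uniform(loy, hiy, size=n)]
    )

    dt = config.dt
    noise_sd = np.sqrt(2.0 * config.tracer_D * dt)
    n_frames = config.n_frames
    xs_out = np.empty((n_frames, n))
    ys_out = np.empty((n_frames, n))
    xs_out[0] = pos[:, 0]
    ys_out[0] = pos[:, 1]

    max_step = 0.5 * flow.spacing[0]
    for f in range(1, n_frames):
        c, s = np.cos(th[f - 1]), np.sin(th[f - 1])
        rel_x = pos[:, 0] - cx[f - 1]
        rel_y = pos[:, 1] - cy[f - 1]
        # rotate into the cell frame, sample, rotate back
        qx = c * rel_x + s * rel_y
        qy = -s * rel_x + c * rel_y
        pts = np.column_stack([qx, qy])
        ux = itp_x(pts)
        uy = itp_y(pts)
        vx = c * ux - s * uy
        vy = s * ux + c * uy
        vmax = np.max(np.hypot(vx, vy))
        n_sub = max(1, int(np.ceil(vmax * dt / max_step)))
        if n_sub == 1:
            pos[:, 0] += vx * dt
            pos[:, 1] += vy * dt
        else:
            sub = dt / n_sub
            for _ in range(n_sub):
                qx = c * (pos[:, 0] - cx[f - 1]) + s * (pos[:, 1] - cy[f - 1])
                qy = -s * (pos[:, 0] - cx[f - 1]) + c * (pos[:, 1] - cy[f - 1])
                uv = np.column_stack([itp_x(np.column_stack([qx, qy])),
                                      itp_y(np.column_stack([qx, qy]))])
                pos[:, 0] += (c * uv[:, 0] - s * uv[:, 1]) * sub
                pos[:, 1] += (s * uv[:, 0] + c * uv[:, 1]) * sub
        if config.tracer_D > 0:
            pos += noise_sd * rng.standard_normal(size=pos.shape)
        # reflecting boundaries
        pos[:, 0] = np.where(pos[:, 0] < lox, 2 * lox - pos[:, 0], pos[:, 0])
        pos[:, 0] = np.where(pos[:, 0] > hix, 2 * hix - pos[:, 0], pos[:, 0])
        pos[:, 1] = np.where(pos[:, 1] < loy, 2 * loy - pos[:, 1], pos[:, 1])
        pos[:, 1] = np.where(pos[:, 1] > hiy, 2 * hiy - pos[:, 1], pos[:, 1])
        xs_out[f] = pos[:, 0]
        ys_out[f] = pos[:, 1]

    t = pose["t_s"].to_numpy()
    truth = (
        flow if flow_field is not None
        else synthesize_flow(model, GridSpec.centered(truth_window, 1.0))
    )
    tracks = pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n), n_frames),
            "t_s": np.tile(t, n),
            "x_um": xs_out.T.ravel(),
            "y_um": ys_out.T.ravel(),
        }
    )
    return SyntheticExperiment(config, tracks, pose, truth)


def make_noisy_flowfield(
    model: SwimmerModel, grid: GridSpec, noise_sd: float, seed: int = 0
) -> FlowField:
    """Synthesized model field plus i.i.d. Gaussian noise per component."""
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    field = synthesize_flow(model, grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        field.vx = field.vx + noise_sd * rng.standard_normal(field.shape)
        field.vy = field.vy + noise_sd * rng.standard_normal(field.shape)
    return field
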