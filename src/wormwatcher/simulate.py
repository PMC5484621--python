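"""Ground-truthed synthetic recordings for pipeline validation.

The simulator produces the statistical structure the analysis assumes, at
two levels:

* **trajectory level** (fast): per-animal, per-epoch spontaneous and
  stimulated activity, response latency and duration, drawn from a
  parameterized aging model — the input to lifespan and decline analysis
  without any imaging;
* **image level**: dark-field frames in which each living animal is a
  bright Gaussian blob whose per-frame displacement tracks its current
  activity level, with a global brightness flash during the blue-light
  stimulus and configurable pixel noise — the input that exercises the
  differencing engine end to end.

Aging model
-----------
Each animal draws a lifespan ``L`` from a truncated normal distribution
(default mean 16.8 days, SD 4.4 days — a wild-type-like population).  Its
stimulated activity in life-fraction space is piecewise linear with a
single breakpoint (default 0.6): baseline minus an early decline, then a
late decline, floored at a small positive plateau.  The per-animal change
in decline rate is

    rate_change_i = mean_change + sd * (c * z_i + sqrt(1 - c^2) * eps_i)

where ``z_i`` is the animal's standardized lifespan, ``eps_i`` independent
noise, and ``c`` the lifespan-coupling coefficient.  ``c = 0`` with zero SD
reproduces pure temporal scaling (every animal shares one fraction-space
template); negative ``c`` reproduces the extended-twilight regime in which
long-lived animals plateau (the population correlation between rate change
and lifespan is ``c`` by construction).  Spontaneous activity is a fixed
fraction of stimulated activity.

All randomness flows from one seed; per-purpose substreams are derived
with ``numpy.random.SeedSequence`` so trajectory and rendering draws are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .activity import FrameStack
from .behavior import EpochSchedule
from .errors import ConfigurationError
from .geometry import WellMap, build_well_map

__all__ = [
    "LifespanModel",
    "TrajectoryModel",
    "StimulusResponseModel",
    "NoiseModel",
    "RenderModel",
    "SimConfig",
    "SimResult",
    "simulate_trajectories",
    "render_epochs",
    "render_all",
    "write_fixture",
    "load_sim_config",
]

HOURS_PER_DAY = 24.0


@dataclass
class LifespanModel:
    """Truncated-normal lifespan distribution (hours)."""

    mean_h: float = 16.8 * HOURS_PER_DAY
    sd_h: float = 4.4 * HOURS_PER_DAY
    min_h: float = 24.0
    max_h: float | None = None
    #: explicit per-well lifespans overriding the distribution (testing hook)
    fixed_h: list[float] | None = None

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.fixed_h is not None:
            vals = np.asarray(self.fixed_h, dtype=float)
            if len(vals) != n:
                raise ConfigurationError("fixed_h length must equal n_wells")
            return vals.copy()
        if self.sd_h < 0 or self.mean_h <= 0:
            raise ConfigurationError("invalid lifespan distribution parameters")
        out = np.empty(n)
        for i in range(n):  # rejection sampling; the bounds are generous
            for _ in range(1000):
                v = rng.normal(self.mean_h, self.sd_h)
                if v >= self.min_h and (self.max_h is None or v <= self.max_h):
                    out[i] = v
                    break
            else:
                raise ConfigurationError("lifespan truncation bounds too tight")
        return out


@dataclass
class TrajectoryModel:
    """Piecewise-linear fraction-space decline with lifespan coupling."""

    baseline_px: float = 250.0
    early_rate: float = 200.0  # px per life fraction, positive = declining
    late_rate_mean: float = 110.0
    rate_change_sd: float = 60.0
    lifespan_coupling: float = -0.32
    breakpoint: float = 0.6
    floor_px: float = 25.0
    spontaneous_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.breakpoint < 1:
            raise ConfigurationError("breakpoint fraction must lie in (0, 1)")
        if not -1 <= self.lifespan_coupling <= 1:
            raise ConfigurationError("lifespan coupling must lie in [-1, 1]")
        for v in (self.baseline_px, self.early_rate, self.late_rate_mean,
                  self.rate_change_sd, self.floor_px):
            if not np.isfinite(v):
                raise ConfigurationError("trajectory parameters must be finite")

    def value(self, fraction, early_rate: float, late_rate: float) -> np.ndarray:
        f = np.asarray(fraction, dtype=float)
        v = (self.baseline_px
             - early_rate * np.minimum(f, self.breakpoint)
             - late_rate * np.maximum(0.0, f - self.breakpoint))
        return np.maximum(self.floor_px, v)


@dataclass
class StimulusResponseModel:
    """Per-animal blue-light response parameters."""

    latency_mean_s: float = 5.0
    latency_sd_s: float = 3.0
    duration_mean_s: float = 120.0
    duration_sd_s: float = 40.0
    gain: float = 3.0  # evoked activity multiplier over baseline level

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        lat = np.clip(rng.normal(self.latency_mean_s, self.latency_sd_s, n), 0.0, None)
        dur = np.clip(rng.normal(self.duration_mean_s, self.duration_sd_s, n), 5.0, None)
        return lat, dur


@dataclass
class NoiseModel:
    """Measurement noise at the two simulation levels.

    The default per-pixel noise (SD 1 DN on an 8-bit dark-field background
    of ~20 DN) reflects the operating regime the differencing pipeline
    assumes: at this level the 0.25 normalized threshold suppresses sensor
    noise completely, so a dead animal never registers activity and the
    automated death call can only ever be at or before a manual one.  At
    SD ≳ 2 DN, rare noise clusters start to cross the threshold (~1e-4 of
    frame pairs) and that guarantee no longer holds.
    """

    activity_sd_px: float = 10.0  # additive on trace-level activity, truncated at 0
    pixel_noise_sd: float = 1.0  # per-pixel Gaussian (8-bit DN), image level
    spurious_rate: float = 0.0  # per-epoch probability of false activity after death


@dataclass
class RenderModel:
    """Dark-field appearance parameters for the image-level simulator."""

    blob_amplitude: float = 180.0
    blob_sigma_px: float = 1.6  # blob ~6 px across at default scale
    background: float = 20.0
    flash_boost: float = 60.0  # global brightness added during the stimulus
    step_px_per_activity: float = 0.012
    min_step_px: float = 0.8
    max_step_px: float = 4.0


@dataclass
class SimConfig:
    """Full specification of a synthetic recording."""

    # well grid
    rows: int = 6
    cols: int = 8
    origin: tuple[float, float] = (35.0, 35.0)
    pitch_px: float = 45.0
    radius_px: float = 20.0
    plate_id: str = "sim"
    # schedule
    n_epochs: int = 40
    first_epoch_s: float = 0.0
    epoch_period_s: float = 43200.0  # twice daily
    epoch_duration_s: float = 1800.0
    stimulus_onset_s: float = 900.0
    stimulus_duration_s: float = 10.0
    frame_interval_s: float = 5.0
    # models
    lifespan: LifespanModel = field(default_factory=LifespanModel)
    trajectory: TrajectoryModel = field(default_factory=TrajectoryModel)
    stimulus: StimulusResponseModel = field(default_factory=StimulusResponseModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    render: RenderModel = field(default_factory=RenderModel)
    #: wells rendered/simulated as empty (censoring injection)
    n_empty_wells: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.render.blob_sigma_px * 3 >= self.radius_px:
            raise ConfigurationError("blob radius must be smaller than the well radius")

    @property
    def n_wells(self) -> int:
        return self.rows * self.cols

    def well_map(self) -> WellMap:
        return build_well_map(self.rows, self.cols, self.origin,
                              self.pitch_px, self.radius_px, plate_id=self.plate_id)

    def schedule(self) -> EpochSchedule:
        return EpochSchedule(
            self.first_epoch_s + self.epoch_period_s * np.arange(self.n_epochs),
            epoch_duration_s=self.epoch_duration_s,
            stimulus_onset_s=self.stimulus_onset_s,
            stimulus_duration_s=self.stimulus_duration_s,
        )

    @property
    def frame_shape(self) -> tuple[int, int]:
        h = int(2 * self.origin[1] + (self.rows - 1) * self.pitch_px)
        w = int(2 * self.origin[0] + (self.cols - 1) * self.pitch_px)
        return h, w

    # -- convenience constructors for the two aging regimes ---------------
    @classmethod
    def temporal_scaling(cls, **kw) -> "SimConfig":
        """Model 1: one fraction-space template for every animal."""
        traj = kw.pop("trajectory", TrajectoryModel(lifespan_coupling=0.0, rate_change_sd=0.0))
        return cls(trajectory=traj, **kw)

    @classmethod
    def extended_twilight(cls, coupling: float = -0.5, **kw) -> "SimConfig":
        """Model 2: long-lived animals plateau in late life."""
        traj = kw.pop("trajectory", TrajectoryModel(lifespan_coupling=coupling))
        return cls(trajectory=traj, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["origin"] = list(d["origin"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key, sub in (("lifespan", LifespanModel), ("trajectory", TrajectoryModel),
                         ("stimulus", StimulusResponseModel), ("noise", NoiseModel),
                         ("render", RenderModel)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "origin" in d:
            d["origin"] = tuple(d["origin"])
        return cls(**d)


@dataclass
class SimResult:
    """Trajectory-level simulation output plus its ground truth."""

    config: SimConfig
    metrics: pd.DataFrame  # same tidy schema as the pipeline's epoch metrics
    ground_truth: pd.DataFrame  # one row per well

    @property
    def recording_end_h(self) -> float:
        sched = self.config.schedule()
        return float(sched.epoch_starts[-1] + sched.epoch_duration_s) / 3600.0


def _substream(seed: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, purpose]))


def simulate_trajectories(config: SimConfig, seed: int | None = None) -> SimResult:
    """Draw per-animal aging trajectories and emit epoch metrics + truth.

    The metrics table mirrors what the imaging pipeline would measure:
    activity values carry additive truncated-at-zero noise while the animal
    is alive and are exactly zero after death; latency and duration are
    quantized to the 5-s sampling step.  The ground-truth table records the
    generating parameters, the true (continuous) death time, and the death
    time the epoch-resolution call rule is expected to produce.
    """
    seed = config.seed if seed is None else seed
    rng = _substream(seed, 0)
    sched = config.schedule()
    n = config.n_wells
    traj = config.trajectory

    L = config.lifespan.sample(rng, n)
    z = (L - config.lifespan.mean_h) / max(config.lifespan.sd_h, 1e-12)
    eps = rng.standard_normal(n)
    c = traj.lifespan_coupling
    mean_change = traj.late_rate_mean - traj.early_rate
    rate_change = mean_change + traj.rate_change_sd * (c * z + np.sqrt(1 - c * c) * eps)
    early = np.full(n, traj.early_rate)
    late = early + rate_change
    latency, resp_dur = config.stimulus.sample(rng, n)

    empty = np.zeros(n, dtype=bool)
    if config.n_empty_wells:
        empty[rng.choice(n, size=config.n_empty_wells, replace=False)] = True

    starts_s = sched.epoch_starts
    stim_end_off = config.stimulus_onset_s + config.stimulus_duration_s
    days = sched.epoch_days()
    post_window = sched.post_window_s
    dt = config.frame_interval_s
    # number of complete post-stimulus 5-s pairs a recorded epoch contains
    n_post_pairs = int((config.epoch_duration_s - stim_end_off - dt) / dt)
    max_duration = n_post_pairs * dt

    rows = []
    gt_rows = []
    sd = config.noise.activity_sd_px
    for i in range(n):
        L_s = L[i] * 3600.0
        alive_start = starts_s < L_s
        alive_post = starts_s + stim_end_off < L_s
        f = np.minimum(starts_s / L_s, 1.0)
        v = traj.value(f, early[i], late[i])
        for j in range(len(starts_s)):
            if empty[i]:
                present = days[j] == 1  # escaped at the end of day 1
                spont_v = stim_v = (traj.baseline_px * traj.spontaneous_fraction) if present else 0.0
                alive_now, alive_p = present, present
            else:
                spont_v = traj.spontaneous_fraction * v[j]
                stim_v = v[j]
                alive_now, alive_p = alive_start[j], alive_post[j]
            noise = rng.normal(0.0, sd, 2) if sd > 0 else np.zeros(2)
            spont = max(0.0, spont_v + noise[0]) if alive_now else 0.0
            stim = max(0.0, stim_v + noise[1]) if alive_p else 0.0
            if not alive_p and config.noise.spurious_rate > 0:
                if rng.random() < config.noise.spurious_rate:
                    stim = float(rng.integers(1, 6))
            # latency/duration as differencing would measure them: an animal
            # with spontaneous post-stimulus movement is "moving" throughout
            # the window (latency 0); a quiescent responder shows its own
            # latency and response duration, quantized to the sampling step
            if stim > 0 and alive_p:
                if spont_v > 0:
                    lat_q, dur_q = 0.0, max_duration
                else:
                    lat_q = min(dt * np.floor(latency[i] / dt), post_window)
                    dur_q = float(np.clip(dt * np.round(resp_dur[i] / dt), dt,
                                          max_duration))
            else:
                lat_q, dur_q = post_window, 0.0
            rows.append(
                {
                    "plate_id": config.plate_id,
                    "well_index": i,
                    "epoch_index": j,
                    "time_h": starts_s[j] / 3600.0,
                    "day": int(days[j]),
                    "spontaneous": spont,
                    "stimulated": stim,
                    "duration_s": dur_q,
                    "latency_s": lat_q,
                    "valid": True,
                }
            )
        # expected epoch-resolution pipeline outcome (from the noiseless
        # alive flags: what censoring + the death-call rule must produce)
        has_day2_activity = bool(
            np.any((days >= 2) & (alive_start if traj.spontaneous_fraction > 0 else False))
            or np.any((days >= 2) & alive_post)
        )
        if empty[i] or not has_day2_activity:
            expected = np.nan
            expected_censored = True
            alive_at_end = False
        else:
            idx = np.flatnonzero(alive_post)
            if idx.size and idx[-1] == len(starts_s) - 1:
                expected = np.nan
                alive_at_end = True
                expected_censored = False
            else:
                # the call rule reads the stimulated (post-stimulus) series
                last_active = int(idx[-1]) if idx.size else -1
                expected = starts_s[last_active + 1] / 3600.0 if last_active >= 0 else starts_s[0] / 3600.0
                alive_at_end = False
                expected_censored = False
        gt_rows.append(
            {
                "well_index": i,
                "empty": bool(empty[i]),
                "lifespan_h": np.nan if empty[i] else L[i],
                "expected_death_call_h": expected,
                "expected_censored": expected_censored,
                "alive_at_end": alive_at_end,
                "baseline_px": traj.baseline_px,
                "early_rate": early[i],
                "late_rate": late[i],
                "rate_change": rate_change[i],
                "latency_s": latency[i],
                "response_duration_s": resp_dur[i],
            }
        )
    return SimResult(config=config, metrics=pd.DataFrame(rows),
                     ground_truth=pd.DataFrame(gt_rows))


# ---------------------------------------------------------------------------
# image-level rendering
# ---------------------------------------------------------------------------

def _blob_patch(shape, cx, cy, amplitude, sigma):
    """Additive Gaussian spot; evaluated on a local window only."""
    h, w = shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    patch = amplitude * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2))
    return (slice(y0, y1), slice(x0, x1)), patch


class _AnimalState:
    __slots__ = ("pos", "rng")

    def __init__(self, pos, rng):
        self.pos = pos
        self.rng = rng


def render_epochs(sim: SimResult, seed: int | None = None):
    """Yield one :class:`FrameStack` per epoch (memory-bounded rendering).

    Each living animal moves as a random walk whose step length is
    proportional to its current activity level (clamped to
    ``[min_step_px, max_step_px]``), confined to its well; dead animals and
    empty wells are static.  Stimulus frames carry a global brightness
    flash.  Rendering consumes per-animal substreams, so output is
    byte-identical for a fixed seed.
    """
    config = sim.config
    seed = config.seed if seed is None else seed
    sched = config.schedule()
    wmap = config.well_map()
    shape = config.frame_shape
    rm, traj = config.render, config.trajectory
    gt = sim.ground_truth
    noise_rng = _substream(seed, 1)
    r_limit = config.radius_px - (3 * rm.blob_sigma_px + 1)

    states = []
    for i in range(config.n_wells):
        states.append(_AnimalState(wmap.well_centers[i].copy(), _substream(seed, 100 + i)))

    n_frames = int(round(config.epoch_duration_s / config.frame_interval_s))
    L_s = gt["lifespan_h"].to_numpy() * 3600.0
    empty = gt["empty"].to_numpy()
    early = gt["early_rate"].to_numpy()
    late = gt["late_rate"].to_numpy()
    lat = gt["latency_s"].to_numpy()
    resp = gt["response_duration_s"].to_numpy()

    for e in range(sched.n_epochs):
        t0 = float(sched.epoch_starts[e])
        stim_on, stim_off = sched.stimulus_window(e)
        ts = t0 + config.frame_interval_s * np.arange(n_frames)
        frames = np.empty((n_frames,) + shape, dtype=np.uint8)
        for k, t in enumerate(ts):
            frame = np.full(shape, rm.background, dtype=np.float32)
            if config.noise.pixel_noise_sd > 0:
                frame += noise_rng.normal(0.0, config.noise.pixel_noise_sd, shape).astype(np.float32)
            if stim_on <= t < stim_off:
                frame += rm.flash_boost
            for i in range(config.n_wells):
                if empty[i]:
                    continue
                st = states[i]
                level = 0.0
                if np.isfinite(L_s[i]) and t < L_s[i]:
                    f = t / L_s[i]
                    v = float(traj.value(f, early[i], late[i]))
                    if stim_off + lat[i] <= t < stim_off + lat[i] + resp[i]:
                        level = config.stimulus.gain * v
                    else:
                        level = traj.spontaneous_fraction * v
                if level > 0:
                    step = float(np.clip(rm.step_px_per_activity * level,
                                         rm.min_step_px, rm.max_step_px))
                    ang = st.rng.uniform(0, 2 * np.pi)
                    st.pos = st.pos + step * np.array([np.cos(ang), np.sin(ang)])
                    center = wmap.well_centers[i]
                    d = np.hypot(*(st.pos - center))
                    if d > r_limit:
                        st.pos = center + (st.pos - center) * (r_limit / d)
                sl, patch = _blob_patch(shape, st.pos[0], st.pos[1],
                                        rm.blob_amplitude, rm.blob_sigma_px)
                frame[sl] += patch
            frames[k] = np.clip(frame, 0, 255).astype(np.uint8)
        yield FrameStack(frames, ts)


def render_all(sim: SimResult, seed: int | None = None) -> FrameStack:
    """Concatenate all epochs into one stack (small configurations only)."""
    stacks = list(render_epochs(sim, seed=seed))
    frames = np.concatenate([s.frames for s in stacks])
    ts = np.concatenate([s.timestamps for s in stacks])
    return FrameStack(frames, ts)


def write_fixture(config: SimConfig, out_dir, seed: int | None = None) -> dict:
    """Simulate, render, and write a complete on-disk fixture.

    Produces ``frames.tif`` (multi-page TIFF), ``timestamps.csv``
    (frame_index, time_s), ``ground_truth.json``, and ``sim_config.yaml``;
    the set round-trips through the pipeline readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_trajectories(config, seed=seed)
    stack = render_all(sim, seed=seed)
    paths = {
        "frames": out / "frames.tif",
        "timestamps": out / "timestamps.csv",
        "ground_truth": out / "ground_truth.json",
        "config": out / "sim_config.yaml",
    }
    tifffile.imwrite(paths["frames"], stack.frames, photometric="minisblack")
    pd.DataFrame(
        {"frame_index": np.arange(len(stack)), "time_s": stack.timestamps}
    ).to_csv(paths["timestamps"], index=False)
    truth = {
        "seed": int(config.seed if seed is None else seed),
        "wells": json.loads(sim.ground_truth.to_json(orient="records")),
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=1))
    paths["config"].write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return {k: str(v) for k, v in paths.items()}


def load_sim_config(path) -> SimConfig:
    return SimConfig.from_dict(yaml.safe_load(open(path).read()))
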