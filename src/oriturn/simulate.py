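"""Seeded simulators for the three data modalities the pipeline consumes.

The generators produce exactly the statistical structure the downstream
analyses assume, so that every stage can be validated against ground truth:

* 2D Brownian trajectories with one or more diffusive components, optional
  static<->mobile switching with exponential dwells, geometric
  (photobleaching-limited) track lengths, and optional localization error;
* single-exponential FRAP recovery traces with acquisition bleaching, an
  instantaneous bleach drop and a non-exchanging (immobile) pool;
* anti-phase two-compartment intensity oscillations with a conserved total.

All simulators take an explicit integer seed through
:class:`SimulationConfig`; there is no global random state, and identical
config + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientDataError, InvalidModelError
from .io import FrapTrace, OscillationTrace, TrackSet, Trajectory

__all__ = [
    "TrackLengthLaw",
    "SimulationConfig",
    "DiffusionModel",
    "simulate_brownian_tracks",
    "simulate_frap_trace",
    "simulate_oscillation_trace",
]


@dataclass
class TrackLengthLaw:
    """Distribution of track lengths in frames.

    ``geometric`` models photobleaching-limited observation: survival per
    frame is constant, so lengths are ``minimum + Geometric`` with the
    requested mean.  ``fixed`` gives every track ``mean`` frames (rounded).
    """

    distribution: str = "geometric"
    mean: float = 5.7
    minimum: int = 2

    def __post_init__(self):
        if self.distribution not in ("fixed", "geometric"):
            raise InvalidModelError(f"unknown track length law {self.distribution!r}")
        if self.minimum < 2:
            raise InvalidModelError("minimum track length must be >= 2 frames")
        if self.mean < self.minimum:
            raise InvalidModelError("mean track length must be >= minimum")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.distribution == "fixed":
            return np.full(n, int(round(self.mean)), dtype=int)
        # minimum + (G - 1), G geometric with mean (self.mean - minimum + 1)
        p = 1.0 / (self.mean - self.minimum + 1.0)
        return self.minimum + rng.geometric(p, size=n) - 1


@dataclass
class SimulationConfig:
    """Acquisition parameters shared by all simulators.

    Parameters
    ----------
    seed : int
        Seed for the simulator's private random generator.
    frame_interval : float
        Seconds between frames (default 0.041, i.e. 24.5 Hz stream
        acquisition; use 0.004 for 250 Hz fast streams).
    localization_error_sd : float
        Per-axis localization error in micrometers, added independently to
        every coordinate (default 0).
    track_length_law : TrackLengthLaw
        Length distribution for simulated tracks.
    """

    seed: int
    frame_interval: float = 0.041
    localization_error_sd: float = 0.0
    track_length_law: TrackLengthLaw = field(default_factory=TrackLengthLaw)

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise InvalidModelError("frame_interval must be > 0")
        if self.localization_error_sd < 0:
            raise InvalidModelError("localization_error_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class DiffusionModel:
    """Mixture of diffusive components, optionally with state switching.

    ``components`` is a list of ``(D, weight)`` pairs with D in um^2/s.
    Without switching, each molecule is assigned one component for its whole
    lifetime, drawn by weight.  With ``switching = (mean_static_dwell_s,
    mean_mobile_dwell_s)`` there must be exactly two components, ordered
    (static, mobile); molecules then alternate between the two states with
    geometrically distributed dwell lengths whose means match the configured
    dwell times, and the component weights are ignored (state occupancy is
    set by the dwell ratio).
    """

    components: list[tuple[float, float]]
    switching: tuple[float, float] | None = None

    def __post_init__(self):
        if not self.components:
            raise InvalidModelError("diffusion model needs >= 1 component")
        for d, w in self.components:
            if d < 0:
                raise InvalidModelError(f"negative diffusion coefficient {d}")
            if w < 0:
                raise InvalidModelError(f"negative component weight {w}")
        total = sum(w for _, w in self.components)
        if abs(total - 1.0) > 1e-9:
            raise InvalidModelError(f"component weights sum to {total}, not 1")
        if self.switching is not None:
            if len(self.components) != 2:
                raise InvalidModelError("switching requires exactly two components")
            if min(self.switching) <= 0:
                raise InvalidModelError("mean dwell times must be > 0")


def _switching_states(rng, n_steps: int, dt: float, switching) -> np.ndarray:
    """Per-step state sequence (0=static, 1=mobile) of a two-state chain.

    Dwell lengths in frames are geometric with switch probability dt/mean,
    so the mean dwell *time* equals the configured mean exactly.
    """
    mean_s, mean_m = switching
    q = np.array([min(1.0, dt / mean_s), min(1.0, dt / mean_m)])
    p_start_static = mean_s / (mean_s + mean_m)
    states = np.empty(n_steps, dtype=int)
    s = 0 if rng.random() < p_start_static else 1
    u = rng.random(n_steps)
    for i in range(n_steps):
        states[i] = s
        if u[i] < q[s]:
            s = 1 - s
    return states


def simulate_brownian_tracks(
    model: DiffusionModel, n_tracks: int, config: SimulationConfig
) -> TrackSet:
    """Simulate 2D Brownian trajectories under ``model``.

    Per-axis displacements of a molecule in component ``i`` are drawn from
    Normal(0, 2*D_i*dt); localization error is added independently to every
    observed coordinate.  Track lengths follow ``config.track_length_law``.
    """
    if n_tracks < 1:
        raise InvalidModelError("n_tracks must be >= 1")
    rng = config.rng()
    dt = config.frame_interval
    lengths = config.track_length_law.draw(rng, n_tracks)
    ds = np.array([d for d, _ in model.components])
    ws = np.array([w for _, w in model.components])

    trajectories = []
    for i, length in enumerate(lengths):
        n_steps = length - 1
        if model.switching is None:
            comp = rng.choice(len(ds), p=ws)
            step_sd = np.full(n_steps, math.sqrt(2.0 * ds[comp] * dt))
        else:
            states = _switching_states(rng, n_steps, dt, model.switching)
            step_sd = np.sqrt(2.0 * ds[states] * dt)
        steps = rng.normal(0.0, 1.0, size=(n_steps, 2)) * step_sd[:, None]
        pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        if config.localization_error_sd > 0:
            pos = pos + rng.normal(0.0, config.localization_error_sd, size=pos.shape)
        trajectories.append(
            Trajectory(
                track_id=f"sim-{i:05d}",
                frames=np.arange(length),
                x=pos[:, 0],
                y=pos[:, 1],
                frame_interval=dt,
            )
        )
    return TrackSet(trajectories=trajectories, frame_interval=dt)


def simulate_frap_trace(
    mobile_level: float,
    k_r: float,
    n_pre: int,
    n_post: int,
    config: SimulationConfig,
    bleach_depth: float = 1.0,
    acquisition_bleach_rate: float = 0.0,
    noise_sd: float = 0.0,
) -> FrapTrace:
    """Simulate a single-exponential FRAP recovery trace.

    The pre-bleach plateau is 1; at the bleach frame the ROI drops
    instantaneously by ``bleach_depth``; the mobile share then recovers as
    ``mobile_level * (1 - exp(-k_r * t))`` with t = 0 at the first
    post-bleach frame, so the noiseless post-bleach ROI is::

        (1 - b) + b * mobile_level * (1 - exp(-k_r t)),   b = bleach_depth

    and the non-recovering span ``b * (1 - mobile_level)`` is the immobile
    pool.  The whole trace, the control cell and the whole-cell channel all
    carry the multiplicative acquisition-bleach decay ``exp(-rate * t)``;
    the whole-cell channel is otherwise conserved (the bleached ROI is taken
    to be a small share of the cell).  Gaussian noise of sd ``noise_sd`` is
    added to every measured channel.
    """
    if not (0.0 <= mobile_level <= 1.0):
        raise InvalidModelError("mobile_level must lie in [0, 1]")
    if k_r <= 0:
        raise InvalidModelError("k_r must be > 0")
    if not (0.0 < bleach_depth <= 1.0):
        raise InvalidModelError("bleach_depth must lie in (0, 1]")
    if n_pre < 1 or n_post < 3:
        raise InsufficientDataError("need n_pre >= 1 and n_post >= 3")
    rng = config.rng()
    dt = config.frame_interval
    n = n_pre + n_post
    times = np.arange(n) * dt
    t_post = np.arange(n_post) * dt

    roi = np.ones(n)
    roi[n_pre:] = (1.0 - bleach_depth) + bleach_depth * mobile_level * (
        1.0 - np.exp(-k_r * t_post)
    )
    decay = np.exp(-acquisition_bleach_rate * times)
    roi *= decay
    control = decay.copy()
    whole = decay.copy()
    background = np.zeros(n)
    if noise_sd > 0:
        roi = roi + rng.normal(0.0, noise_sd, n)
        control = control + rng.normal(0.0, noise_sd, n)
        whole = whole + rng.normal(0.0, noise_sd, n)
        background = background + rng.normal(0.0, noise_sd, n)
    return FrapTrace(
        times=times,
        roi=roi,
        background=background,
        control_cell=control,
        whole_cell=whole,
        bleach_index=n_pre,
    )


def simulate_oscillation_trace(
    period: float,
    amplitude: float,
    noise_sd: float,
    n_frames: int,
    config: SimulationConfig,
    baseline: float = 0.5,
) -> OscillationTrace:
    """Simulate anti-phase intensity exchange between two cell halves.

    The clean signals are complementary sinusoids::

        I1 = baseline + amplitude * sin(2 pi t / period)
        I2 = 2*baseline - I1_clean

    so the total is conserved; independent Gaussian noise of sd ``noise_sd``
    is then added to each region channel.  The whole-cell channel is the
    conserved total without noise: it integrates over many more pixels than
    either region, so its relative fluctuation is negligible (a noisy
    denominator would couple the two normalized series spuriously).
    """
    dt = config.frame_interval
    if period <= 2.0 * dt:
        raise InvalidModelError("period must exceed twice the frame interval")
    if amplitude > baseline:
        raise InvalidModelError("amplitude > baseline would give negative intensity")
    if n_frames < 2:
        raise InsufficientDataError("need n_frames >= 2")
    rng = config.rng()
    times = np.arange(n_frames) * dt
    clean1 = baseline + amplitude * np.sin(2.0 * math.pi * times / period)
    total = 2.0 * baseline
    clean2 = total - clean1
    whole = np.full(n_frames, total)
    if noise_sd > 0:
        area1 = clean1 + rng.normal(0.0, noise_sd, n_frames)
        area2 = clean2 + rng.normal(0.0, noise_sd, n_frames)
    else:
        area1, area2 = clean1, clean2
    return OscillationTrace(times=times, area1=area1, area2=area2, whole_cell=whole)
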