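"""FRAP processing: normalization, clustering, recovery fitting, comparison.

The analysis chain mirrors standard practice for confocal/widefield FRAP of
bacterial protein foci:

1. *single normalization* — the background-subtracted ROI signal is divided
   by a background-subtracted unbleached control cell (removing acquisition
   bleaching), then by its own pre-bleach mean;
2. *double normalization* — as above but dividing by the whole-cell
   intensity of the bleached cell, which corrects for both acquisition
   bleaching and the bleach pulse itself and makes the recovery level
   interpretable as the mobile fraction;
3. traces are grouped into clusters of three cells with similar pre-bleach
   intensity, full-scale normalized (post-bleach minimum -> 0, pre-bleach
   mean -> 1) to equalize bleach depths, and averaged;
4. each cluster average is fitted post-bleach with the single-exponential
   recovery model ``f(t) = A * (1 - exp(-k_r * t))``, giving the recovery
   half-time ``t_1/2 = ln 2 / k_r`` and, for double-normalized data, the
   immobile fraction ``1 - A``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from lmfit import Model
from scipy import stats

from .exceptions import (
    DegenerateTraceError,
    FitError,
    InsufficientDataError,
)
from .io import FrapTrace

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedTrace",
    "FrapFit",
    "HalfTimeComparison",
    "detect_bleach_index",
    "single_normalize",
    "double_normalize",
    "cluster_traces",
    "fit_recovery",
    "summarize_halftimes",
    "compare_halftimes",
]


@dataclass
class NormalizedTrace:
    """A normalized recovery trace with the bleach at t = 0.

    ``times`` are seconds relative to the first post-bleach frame (pre-bleach
    frames are negative); ``n_pre`` pre-bleach points precede the recovery.
    """

    times: np.ndarray
    values: np.ndarray
    normalization_mode: str  # "single" | "double"
    prebleach_level: float   # mean raw ratio before the bleach
    n_pre: int
    n_traces: int = 1        # >1 for cluster averages

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DegenerateTraceError("normalized trace contains non-finite values")
        pre = self.values[: self.n_pre]
        if len(pre) and abs(pre.mean() - 1.0) > 1e-6:
            raise DegenerateTraceError(
                f"pre-bleach mean is {pre.mean():.6f}, expected 1 after normalization"
            )

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.n_pre:]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.n_pre:]


@dataclass
class FrapFit:
    """Fitted single-exponential recovery parameters for one cluster."""

    A: float                 # recovery level (mobile fraction under double norm.)
    k_r: float               # recovery rate, 1/s
    t_half: float            # ln2 / k_r, s
    immobile_fraction: float  # 1 - A clamped to [0, 1]
    n_traces: int
    residual_sse: float

    def __post_init__(self):
        if self.k_r <= 0:
            raise FitError(f"fitted k_r = {self.k_r} is not positive")
        if abs(self.t_half - math.log(2.0) / self.k_r) > 1e-12 * self.t_half:
            raise FitError("t_half does not equal ln2 / k_r")


@dataclass
class HalfTimeComparison:
    """Two-sample Student's t comparison of recovery half-times."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def detect_bleach_index(trace: FrapTrace) -> int:
    """Index of the first post-bleach frame: the largest single-frame
    fractional drop in the ROI channel."""
    roi = trace.roi
    drops = (roi[:-1] - roi[1:]) / np.maximum(np.abs(roi[:-1]), 1e-30)
    return int(np.argmax(drops)) + 1


def _normalize(trace: FrapTrace, reference: np.ndarray, mode: str,
               subtract_background_from_reference: bool = True) -> NormalizedTrace:
    bg = trace.background
    ref = reference - bg if subtract_background_from_reference else reference
    if np.any(ref <= 0):
        bad = int(np.argmax(ref <= 0))
        raise DegenerateTraceError(
            f"{mode} normalization: reference - background <= 0 at frame {bad}"
        )
    ratio = (trace.roi - bg) / ref
    bi = trace.bleach_index
    pre_mean = float(ratio[:bi].mean())
    if pre_mean <= 0:
        raise DegenerateTraceError("non-positive pre-bleach level")
    values = ratio / pre_mean
    times = trace.times - trace.times[bi]
    return NormalizedTrace(
        times=times, values=values, normalization_mode=mode,
        prebleach_level=pre_mean, n_pre=bi,
    )


def single_normalize(trace: FrapTrace,
                     subtract_background_from_control: bool = True) -> NormalizedTrace:
    """Normalize by an unbleached control cell, then by the pre-bleach mean.

    Corrects acquisition bleaching; by default the control channel is
    background-subtracted like the ROI (symmetric choice; configurable).
    """
    return _normalize(trace, trace.control_cell, "single",
                      subtract_background_from_control)


def double_normalize(trace: FrapTrace) -> NormalizedTrace:
    """Normalize by the whole-cell intensity, then by the pre-bleach mean.

    Corrects both acquisition bleaching and the bleach pulse; the fitted
    recovery level A is then the mobile fraction and 1 - A the fraction of
    molecules that do not exchange on the timescale of the experiment.
    """
    return _normalize(trace, trace.whole_cell, "double")


def full_scale_normalize(trace: NormalizedTrace) -> NormalizedTrace:
    """Map the post-bleach minimum to 0 and the pre-bleach mean to 1.

    Equalizes different bleach depths before traces are averaged:
    ``(v - min_post) / (pre_mean - min_post)``.
    """
    min_post = float(trace.post_values.min())
    pre_mean = float(trace.values[: trace.n_pre].mean())
    span = pre_mean - min_post
    if span <= 0:
        raise DegenerateTraceError("full-scale normalization: non-positive span")
    return NormalizedTrace(
        times=trace.times,
        values=(trace.values - min_post) / span,
        normalization_mode=trace.normalization_mode,
        prebleach_level=trace.prebleach_level,
        n_pre=trace.n_pre,
        n_traces=trace.n_traces,
    )


def cluster_traces(traces: list[NormalizedTrace],
                   cluster_size: int = 3) -> list[NormalizedTrace]:
    """Group traces of similar pre-bleach intensity and average them.

    Traces are sorted by pre-bleach intensity and partitioned into
    consecutive groups of ``cluster_size``; a remainder group is kept if it
    has at least two members, otherwise dropped (logged).  Each trace is
    full-scale normalized before the pointwise average.  All traces must
    share the same length and frame times (no resampling is attempted).
    """
    if len(traces) < cluster_size:
        raise InsufficientDataError(
            f"need >= {cluster_size} traces, got {len(traces)}"
        )
    n = len(traces[0].values)
    for t in traces[1:]:
        if len(t.values) != n or not np.allclose(t.times, traces[0].times):
            raise InsufficientDataError(
                "traces of unequal length/timing cannot be clustered"
            )
    ordered = sorted(traces, key=lambda t: t.prebleach_level)
    clusters = []
    for start in range(0, len(ordered), cluster_size):
        group = ordered[start:start + cluster_size]
        if len(group) < 2:
            logger.info("dropping remainder group of %d trace(s)", len(group))
            continue
        scaled = [full_scale_normalize(t) for t in group]
        mean_values = np.mean([t.values for t in scaled], axis=0)
        clusters.append(
            NormalizedTrace(
                times=traces[0].times.copy(),
                values=mean_values,
                normalization_mode=group[0].normalization_mode,
                prebleach_level=float(np.mean([t.prebleach_level for t in group])),
                n_pre=group[0].n_pre,
                n_traces=len(group),
            )
        )
    return clusters


def _recovery(t, a, kr):
    return a * (1.0 - np.exp(-kr * t))


def fit_recovery(trace: NormalizedTrace) -> FrapFit:
    """Least-squares fit of ``A (1 - exp(-k_r t))`` to the post-bleach points.

    The fit is initialized from the data: A0 is the mean of the last quartile
    of post-bleach values and k_r0 = ln2 / (time at which the trace first
    reaches A0/2, by linear interpolation).
    """
    t = trace.post_times
    v = trace.post_values
    if len(t) < 4:
        raise InsufficientDataError("need >= 4 post-bleach points to fit")
    a0 = float(v[-max(1, len(v) // 4):].mean())
    a0 = max(a0, 1e-3)
    half = a0 / 2.0
    above = np.nonzero(v >= half)[0]
    if len(above) and above[0] > 0:
        i = above[0]
        frac = (half - v[i - 1]) / (v[i] - v[i - 1])
        t_half0 = t[i - 1] + frac * (t[i] - t[i - 1])
    elif len(above):
        t_half0 = max(t[1], 1e-6)
    else:
        t_half0 = t[-1] / 2.0
    k0 = math.log(2.0) / max(t_half0, 1e-9)

    model = Model(_recovery)
    params = model.make_params(a=a0, kr=k0)
    params["a"].set(min=0.0)
    params["kr"].set(min=1e-9, max=1e6)
    result = model.fit(v, params, t=t)
    if not result.success:
        raise FitError(
            f"recovery fit did not converge: {result.message} "
            f"(n={len(t)}, span=[{v.min():.3g}, {v.max():.3g}])",
            initial_guess={"a": a0, "kr": k0},
        )
    kr = float(result.params["kr"].value)
    if kr <= 2e-9 or kr >= 9e5:
        logger.warning("fitted k_r = %g sits at a parameter bound", kr)
    a = float(result.params["a"].value)
    return FrapFit(
        A=a,
        k_r=kr,
        t_half=math.log(2.0) / kr,
        immobile_fraction=float(np.clip(1.0 - a, 0.0, 1.0)),
        n_traces=trace.n_traces,
        residual_sse=float(np.sum(result.residual ** 2)),
    )


def summarize_halftimes(fits: list[FrapFit]) -> tuple[float, float]:
    """Mean and standard error of cluster half-times."""
    if len(fits) < 2:
        raise InsufficientDataError("need >= 2 fits to summarize")
    th = np.array([f.t_half for f in fits])
    return float(th.mean()), float(th.std(ddof=1) / math.sqrt(len(th)))


def compare_halftimes(group_a, group_b, welch: bool = False) -> HalfTimeComparison:
    """Two-sided two-sample t-test on recovery half-times.

    Pooled-variance Student's test by default; set ``welch=True`` for the
    unequal-variance form.  Two zero-variance groups with equal means give
    p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    sem_a = float(a.std(ddof=1) / math.sqrt(len(a)))
    sem_b = float(b.std(ddof=1) / math.sqrt(len(b)))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(t_stat), float(p)
    return HalfTimeComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=sem_a, sem_b=sem_b,
        t_statistic=t_stat, p_value=p,
    )
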