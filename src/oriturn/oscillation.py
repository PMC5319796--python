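"""Two-region intensity-exchange (oscillation) quantification.

Intensities of two regions of one cell are normalized framewise to the
whole-cell signal — which cancels acquisition bleaching common to all
channels — and compared by their correlation coefficient.  Coordinated
relocation of molecules between the regions (anti-phase oscillation) gives
a strongly negative r; a static marker gives r near 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateTraceError, InsufficientDataError
from .io import OscillationTrace

__all__ = [
    "OscillationResult",
    "normalize_areas",
    "area_correlation",
    "estimate_period",
]


@dataclass
class OscillationResult:
    """Whole-cell-normalized region series and their correlation."""

    normalized_area1: np.ndarray
    normalized_area2: np.ndarray
    correlation: float
    n_frames: int

    def __post_init__(self):
        if len(self.normalized_area1) != len(self.normalized_area2):
            raise ValueError("series lengths differ")
        if not (-1.0 <= self.correlation <= 1.0):
            raise ValueError(f"correlation {self.correlation} outside [-1, 1]")


def normalize_areas(trace: OscillationTrace) -> tuple[np.ndarray, np.ndarray]:
    """Divide each region series framewise by the whole-cell intensity."""
    if np.any(trace.whole_cell <= 0):
        frame = int(np.argmax(trace.whole_cell <= 0))
        raise DegenerateTraceError(
            f"whole-cell intensity <= 0 at frame {frame}"
        )
    return trace.area1 / trace.whole_cell, trace.area2 / trace.whole_cell


def area_correlation(trace: OscillationTrace,
                     method: str = "pearson") -> OscillationResult:
    """Correlation between the two whole-cell-normalized region series.

    Pearson by default (``method="spearman"`` for the rank form).  Raises on
    zero variance in either series, where the coefficient is undefined.
    """
    if len(trace) < 5:
        raise InsufficientDataError("need >= 5 frames for a correlation")
    s1, s2 = normalize_areas(trace)
    if np.isclose(s1.std(), 0.0) or np.isclose(s2.std(), 0.0):
        raise DegenerateTraceError("zero variance: correlation undefined")
    if method == "pearson":
        r = stats.pearsonr(s1, s2).statistic
    elif method == "spearman":
        r = stats.spearmanr(s1, s2).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(np.clip(r, -1.0, 1.0))
    return OscillationResult(
        normalized_area1=s1, normalized_area2=s2,
        correlation=r, n_frames=len(trace),
    )


def estimate_period(trace: OscillationTrace) -> float:
    """Exploratory period estimate: twice the lag of the first minimum of
    the autocorrelation of the normalized first-region series.

    Anti-phase exchange puts the first autocorrelation minimum at half the
    oscillation period.  Returns NaN when no interior minimum exists.
    """
    s1, _ = normalize_areas(trace)
    v = s1 - s1.mean()
    ac = np.correlate(v, v, mode="full")[len(v) - 1:]
    if ac[0] <= 0:
        return float("nan")
    ac = ac / ac[0]
    minima = [k for k in range(1, len(ac) - 1)
              if ac[k] < ac[k - 1] and ac[k] <= ac[k + 1]]
    if not minima:
        return float("nan")
    dt = float(trace.times[1] - trace.times[0])
    return 2.0 * minima[0] * dt
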