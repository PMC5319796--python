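"""MSD-based diffusion estimation and step-size mixture decomposition.

Two independent estimators of molecular mobility are provided:

* the ensemble mean-squared-displacement (MSD) fit, which pools
  time-averaged MSD curves over all tracks and fits a straight line through
  the origin over the first few lags (slope = 4 D* for free 2D diffusion);
* a maximum-likelihood decomposition of the pooled per-axis frame-to-frame
  displacements into zero-mean normal components with variances
  sigma_i^2 = 2 d_i dt, whose weights give the static and mobile population
  fractions.

The mixture is fitted on the raw step values, not on binned histograms, by
expectation-maximization with seeded restarts.  The two estimators answer
different questions (whole-population apparent mobility vs per-population
coefficients) and are deliberately not reconciled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import InsufficientDataError, InvalidModelError
from .io import TrackSet, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "StepSample",
    "MSDCurve",
    "DiffusionEstimate",
    "MixtureFit",
    "MixtureOrderReport",
    "extract_steps",
    "msd_curve",
    "ensemble_msd",
    "fit_msd",
    "fit_step_mixture",
    "compare_mixture_orders",
]


@dataclass
class StepSample:
    """Frame-to-frame displacements, columnar.

    Only consecutive-frame pairs contribute; pairs spanning a gap are
    excluded at extraction time.  ``dx``/``dy`` are per-axis displacements in
    micrometers over one frame interval.
    """

    dx: np.ndarray
    dy: np.ndarray
    track_ids: np.ndarray
    frame_interval: float

    def __len__(self) -> int:
        return len(self.dx)

    @property
    def pooled(self) -> np.ndarray:
        """x and y displacements pooled as independent 1D draws."""
        return np.concatenate([self.dx, self.dy])


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track (or an ensemble) per lag."""

    lags: np.ndarray     # seconds, multiples of dt
    msd: np.ndarray      # um^2
    n_pairs: np.ndarray  # pairs contributing per lag

    def __post_init__(self):
        if np.any(self.msd < 0):
            raise InvalidModelError("MSD cannot be negative")


@dataclass
class DiffusionEstimate:
    """Apparent diffusion coefficient from the ensemble MSD fit."""

    d_star: float     # um^2/s
    sem: float        # bootstrap standard error, um^2/s
    n_tracks: int
    lags_used: int

    def __post_init__(self):
        if self.d_star < 0:
            raise InvalidModelError("d_star must be >= 0")


@dataclass
class MixtureFit:
    """Zero-mean Gaussian mixture decomposition of pooled step sizes.

    ``components`` are ``(d, weight)`` pairs sorted ascending in d, with
    d = sigma^2 / (2 dt); weights are the areas under the component curves,
    i.e. the population fractions.
    """

    components: list[tuple[float, float]]
    log_likelihood: float
    n_steps: int
    converged: bool

    def __post_init__(self):
        ws = [w for _, w in self.components]
        if abs(sum(ws) - 1.0) > 1e-9:
            raise InvalidModelError("mixture weights must sum to 1")
        ds = [d for d, _ in self.components]
        if any(b < a for a, b in zip(ds, ds[1:])):
            raise InvalidModelError("components must be sorted ascending by d")

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components])

    @property
    def ds(self) -> np.ndarray:
        return np.array([d for d, _ in self.components])


@dataclass
class MixtureOrderReport:
    """Model-selection summary for one mixture order."""

    order: int
    log_likelihood: float
    bic: float
    fit: MixtureFit


# ---------------------------------------------------------------------------
# Step extraction and MSD
# ---------------------------------------------------------------------------

def extract_steps(tracks: TrackSet) -> StepSample:
    """One sample per consecutive frame pair; gap-spanning pairs are omitted
    (and counted in the log)."""
    dx, dy, ids = [], [], []
    n_gap = 0
    for t in tracks:
        keep = np.diff(t.frames) == 1
        n_gap += int((~keep).sum())
        dx.append(np.diff(t.x)[keep])
        dy.append(np.diff(t.y)[keep])
        ids.append(np.repeat(t.track_id, int(keep.sum())))
    if n_gap:
        logger.info("extract_steps: omitted %d gap-spanning pairs", n_gap)
    return StepSample(
        dx=np.concatenate(dx) if dx else np.empty(0),
        dy=np.concatenate(dy) if dy else np.empty(0),
        track_ids=np.concatenate(ids) if ids else np.empty(0, dtype=str),
        frame_interval=tracks.frame_interval,
    )


def msd_curve(track: Trajectory, max_lag: int) -> MSDCurve:
    """Time-averaged MSD of one track for lags 1..max_lag.

    Gap-aware: only ordered pairs separated by exactly the lag's frame
    spacing contribute.
    """
    if max_lag >= len(track):
        raise InsufficientDataError(
            f"max_lag {max_lag} >= track length {len(track)}"
        )
    frames = track.frames
    lags, msd, n_pairs = [], [], []
    for lag in range(1, max_lag + 1):
        # pairs (i, j) with frames[j] - frames[i] == lag
        idx = {f: i for i, f in enumerate(frames)}
        sq = []
        for i, f in enumerate(frames):
            j = idx.get(f + lag)
            if j is not None:
                sq.append((track.x[j] - track.x[i]) ** 2 +
                          (track.y[j] - track.y[i]) ** 2)
        lags.append(lag * track.frame_interval)
        msd.append(float(np.mean(sq)) if sq else np.nan)
        n_pairs.append(len(sq))
    return MSDCurve(
        lags=np.array(lags), msd=np.array(msd), n_pairs=np.array(n_pairs)
    )


def ensemble_msd(curves: list[MSDCurve], max_lag: int) -> MSDCurve:
    """Pair-count-weighted mean of per-track MSD curves."""
    dt_lags = None
    num = np.zeros(max_lag)
    den = np.zeros(max_lag)
    for c in curves:
        m = min(max_lag, len(c.lags))
        w = c.n_pairs[:m].astype(float)
        valid = w > 0
        num[:m][valid] += w[valid] * c.msd[:m][valid]
        den[:m][valid] += w[valid]
        if dt_lags is None:
            dt_lags = c.lags[1] - c.lags[0] if len(c.lags) > 1 else c.lags[0]
    lag_times = np.arange(1, max_lag + 1) * (dt_lags if dt_lags else np.nan)
    with np.errstate(invalid="ignore"):
        msd = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return MSDCurve(lags=lag_times, msd=np.nan_to_num(msd, nan=0.0),
                    n_pairs=den.astype(int))


def _weighted_origin_slope(curves, lags_used):
    ens = ensemble_msd(curves, lags_used)
    mask = ens.n_pairs > 0
    if mask.sum() < 2:
        raise InsufficientDataError(
            "fewer than two lags have displacement pairs; tracks too short"
        )
    tau = ens.lags[mask]
    m = ens.msd[mask]
    w = ens.n_pairs[mask].astype(float)
    return float(np.sum(w * tau * m) / np.sum(w * tau * tau))


def fit_msd(
    curves: list[MSDCurve],
    lags_used: int = 4,
    n_boot: int = 200,
    seed: int = 0,
) -> DiffusionEstimate:
    """Mean-weighted linear MSD fit through the origin over the first lags.

    The ensemble MSD per lag is the pair-count-weighted mean over tracks; a
    line through the origin is fitted with each lag weighted by its total
    pair count, and D* = slope / 4.  The SEM is obtained by bootstrap
    resampling of tracks (``n_boot`` resamples, seeded).

    The default of 4 lags reflects that photobleaching-limited tracks
    (mean ~6 frames) cannot support longer linear fits.
    """
    if lags_used < 2:
        raise InvalidModelError("lags_used must be >= 2")
    slope = _weighted_origin_slope(curves, lags_used)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        sample = [curves[i] for i in rng.integers(0, len(curves), len(curves))]
        try:
            boots.append(_weighted_origin_slope(sample, lags_used) / 4.0)
        except InsufficientDataError:
            continue
    sem = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")
    return DiffusionEstimate(
        d_star=max(slope / 4.0, 0.0), sem=sem,
        n_tracks=len(curves), lags_used=lags_used,
    )


# ---------------------------------------------------------------------------
# Zero-mean Gaussian step-size mixture
# ---------------------------------------------------------------------------

def _em_zero_mean(v2: np.ndarray, sigma2_init: np.ndarray, w_init: np.ndarray,
                  max_iter: int, tol: float):
    """EM for a mixture of zero-mean normals on squared values ``v2``."""
    sigma2 = sigma2_init.copy()
    w = w_init.copy()
    n = len(v2)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step: log responsibilities
        log_pdf = (-0.5 * np.log(2.0 * np.pi * sigma2)[None, :]
                   - v2[:, None] / (2.0 * sigma2)[None, :])
        log_w = np.log(np.maximum(w, 1e-300))
        log_joint = log_pdf + log_w[None, :]
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        w = nk / n
        sigma2 = np.maximum((resp * v2[:, None]).sum(axis=0) / np.maximum(nk, 1e-300),
                            1e-12)
        if abs(ll - ll_old) <= tol * (abs(ll) + 1.0):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return sigma2, w, ll_old, converged


def fit_step_mixture(
    steps: StepSample,
    n_components: int = 2,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> MixtureFit:
    """Decompose pooled per-axis displacements into diffusive populations.

    x and y displacements are pooled as independent draws from a mixture of
    zero-mean normal densities with variances 2 d_i dt (the zero-mean
    constraint reflects unbiased Brownian steps).  Maximum likelihood is
    found by EM with ``n_restarts`` seeded restarts; the best restart is
    kept, so permuting the initialization order does not change the result.
    Components are reported sorted ascending in d with their weights (the
    areas under the component curves, i.e. population fractions).
    """
    v = steps.pooled
    n = len(v)
    if n < 10 * n_components:
        raise InsufficientDataError(
            f"need >= {10 * n_components} pooled steps, got {n}"
        )
    dt = steps.frame_interval
    v2 = v ** 2
    total_var = float(v2.mean())

    if n_components == 1:
        sigma2 = max(total_var, 1e-12)
        ll = float(np.sum(-0.5 * np.log(2 * np.pi * sigma2) - v2 / (2 * sigma2)))
        return MixtureFit(
            components=[(sigma2 / (2.0 * dt), 1.0)],
            log_likelihood=ll, n_steps=n, converged=True,
        )

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        # log-spaced variance spread around the pooled variance, jittered
        spread = np.logspace(-1.5, 0.5, n_components)
        jitter = np.exp(rng.normal(0.0, 0.5, n_components))
        sigma2_init = np.maximum(total_var * spread * jitter, 1e-12)
        w_init = rng.dirichlet(np.ones(n_components) * 5.0)
        sigma2, w, ll, conv = _em_zero_mean(v2, sigma2_init, w_init, max_iter, tol)
        if best is None or ll > best[2]:
            best = (sigma2, w, ll, conv)
    sigma2, w, ll, conv = best
    if not conv:
        logger.warning("mixture EM did not converge after %d restarts", n_restarts)
    order = np.argsort(sigma2)
    w = w[order] / w.sum()
    components = [(float(sigma2[k] / (2.0 * dt)), float(w[i]))
                  for i, k in enumerate(order)]
    return MixtureFit(components=components, log_likelihood=ll,
                      n_steps=n, converged=bool(conv))


def compare_mixture_orders(steps: StepSample, orders: list[int],
                           seed: int = 0) -> list[MixtureOrderReport]:
    """Fit mixtures of several orders and report log-likelihood and BIC.

    The free-parameter count of an order-k zero-mean mixture is 2k - 1
    (k variances, k - 1 independent weights).  Lower BIC means the extra
    components are supported by the data.
    """
    if not orders:
        raise InvalidModelError("orders must be non-empty")
    n = len(steps.pooled)
    reports = []
    for k in sorted(orders):
        fit = fit_step_mixture(steps, n_components=k, seed=seed)
        n_free = 2 * k - 1
        bic = n_free * np.log(n) - 2.0 * fit.log_likelihood
        reports.append(MixtureOrderReport(
            order=k, log_likelihood=fit.log_likelihood, bic=float(bic), fit=fit,
        ))
    return reports
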