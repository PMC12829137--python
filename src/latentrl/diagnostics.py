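"""Self-consistency and model-quality diagnostics.

The central check of the framework is that *estimated* explorations should
look like iid noise. Mutual average information (MAI) between a series and
its lag-k copy probes arbitrary (not just linear) lag dependence; a
surrogate white-noise reference absorbs the finite-sample bias of the MI
estimator, making the conclusion robust to estimator details.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MAIProfile",
    "mai_profile",
    "normalize_mai",
    "mai_whiteness",
    "ms2d",
    "smoothed_rmse",
    "normalized_final_pitch",
    "dprime",
    "autocorrelation",
    "default_lags",
]


def default_lags(n_lags: int = 50, max_lag: int = 1000) -> np.ndarray:
    """Log-spaced integer lags from 1 to ``max_lag``, deduplicated."""
    lags = np.unique(np.round(np.logspace(0, np.log10(max_lag), n_lags)).astype(int))
    return lags[lags >= 1]


def _mi_histogram(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Plug-in MI (nats) from an equal-frequency 2-D histogram of ranks."""
    rx = stats.rankdata(x, method="ordinal")
    ry = stats.rankdata(y, method="ordinal")
    bx = np.minimum((rx - 1) * n_bins // x.size, n_bins - 1)
    by = np.minimum((ry - 1) * n_bins // y.size, n_bins - 1)
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
    joint = joint.reshape(n_bins, n_bins) / x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log(joint / (px * py))
    return float(np.nansum(term))


@dataclass
class MAIProfile:
    """Lag profile of mutual average information with surrogate reference.

    ``ref_mean`` pools the surrogate MAI over all lags (the normalization
    zero level); ``ref_by_lag`` keeps the per-lag surrogate means, which
    share the estimator's lag-dependent finite-sample bias and therefore
    calibrate the whiteness band.
    """

    lags: np.ndarray
    raw: np.ndarray
    ref_mean: float
    ref_sd: float
    ref_by_lag: np.ndarray
    n_bins: int
    normalized: np.ndarray | None = None
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def lag1(self) -> float:
        i = np.flatnonzero(self.lags == 1)
        if i.size == 0:
            raise ValueError("profile has no lag-1 entry")
        return float(self.raw[i[0]])


def mai_profile(
    series: np.ndarray,
    lags: np.ndarray | None = None,
    n_ref: int = 3,
    seed: int | np.random.Generator = 0,
    estimator: str = "equal_freq_hist",
) -> MAIProfile:
    """Mutual average information between a series and its lag-k copies.

    Uses an equal-frequency histogram MI estimator with ceil(T^(1/3)) bins
    per axis on rank-transformed data, which makes the profile invariant
    under monotone (hence affine) transforms of the series. The reference
    level is the mean MAI over ``n_ref`` iid Gaussian surrogate series of
    the same length across all lags; its spread (SD over surrogate x lag
    values) calibrates the whiteness band. Lags exceeding T/2 are dropped
    with a warning. A constant series has MAI 0 at every lag.
    """
    if estimator != "equal_freq_hist":
        raise ValueError(f"unknown MI estimator {estimator!r}")
    x = np.asarray(series, dtype=float)
    T = x.size
    if lags is None:
        lags = default_lags()
    lags = np.asarray(lags, dtype=int)
    keep = lags <= T // 2
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} lags exceeding T/2")
    lags = lags[keep]
    if lags.size == 0:
        raise ValueError("series too short for any requested lag")
    n_bins = max(int(np.ceil(T ** (1.0 / 3.0))), 2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def profile_of(s):
        if np.std(s) == 0:
            return np.zeros(lags.size)
        return np.array([_mi_histogram(s[:-k], s[k:], n_bins) for k in lags])

    raw = profile_of(x)
    refs = np.stack([profile_of(rng.standard_normal(T)) for _ in range(n_ref)])
    return MAIProfile(
        lags=lags, raw=raw, ref_mean=float(refs.mean()),
        ref_sd=float(refs.std(ddof=1)), ref_by_lag=refs.mean(axis=0),
        n_bins=n_bins, meta={"T": T, "n_ref": n_ref},
    )


def normalize_mai(profile: MAIProfile, anchor: MAIProfile | None = None) -> MAIProfile:
    """Affine normalization: surrogate reference -> 0, anchor lag-1 -> 1.

    The anchor is the raw lag-1 MAI of the original pitch series; by
    default the profile anchors on itself. If the anchor does not exceed
    the reference the mapping is degenerate: the raw profile is returned
    with ``degenerate=True``.
    """
    src = anchor if anchor is not None else profile
    a1 = src.lag1
    denom = a1 - profile.ref_mean
    if denom <= 0:
        warnings.warn("lag-1 MAI does not exceed the surrogate reference; "
                      "returning raw profile")
        profile.normalized = profile.raw.copy()
        profile.degenerate = True
        return profile
    profile.normalized = (profile.raw - profile.ref_mean) / denom
    profile.degenerate = False
    return profile


def mai_whiteness(profile: MAIProfile, n_sd: float = 3.0) -> bool:
    """True when the raw MAI sits within ``n_sd`` surrogate SDs of the
    white-noise reference at every lag.

    The per-lag surrogate mean is used as the reference so that the MI
    estimator's lag-dependent bias (the effective sample size shrinks
    with the lag) cancels out of the band.
    """
    if profile.ref_sd == 0:
        return bool(np.all(profile.raw == profile.ref_by_lag))
    z = np.abs(profile.raw - profile.ref_by_lag) / profile.ref_sd
    return bool(np.max(z) <= n_sd)


def self_consistency_check(
    eps: np.ndarray,
    seed: int | np.random.Generator = 0,
    n_ref: int = 8,
    n_sd: float = 3.0,
    gauss_p: float = 1e-3,
) -> dict:
    """Battery testing whether estimated explorations look ideal (iid
    Gaussian), the model's self-consistency requirement.

    Two complementary probes: the 50-lag MAI whiteness band (catches any
    lag *dependence*, e.g. drifting exploration magnitude) and a
    Jarque-Bera normality test (catches non-Gaussian *marginals*, which
    no lag statistic can see on an iid series). ``n_ref`` surrogates
    calibrate the band; more than the normalization default keeps the
    3-SD band's false-alarm rate low across 50 simultaneous lags.
    """
    from scipy import stats as _st

    profile = mai_profile(eps, n_ref=n_ref, seed=seed)
    white = mai_whiteness(profile, n_sd=n_sd)
    jb = _st.jarque_bera(np.asarray(eps, dtype=float))
    gaussian = bool(jb.pvalue >= gauss_p)
    return {
        "white": white,
        "gaussian": gaussian,
        "passes": white and gaussian,
        "max_z": float(np.max(np.abs(profile.raw - profile.ref_by_lag))
                       / profile.ref_sd) if profile.ref_sd else 0.0,
        "jarque_bera_p": float(jb.pvalue),
        "profile": profile,
    }


def ms2d(
    bias_series: np.ndarray,
    day_index: np.ndarray,
    resample_n: int = 1000,
) -> float:
    """Mean squared second difference of the per-day-resampled bias.

    Per day the bias is linearly resampled onto ``resample_n`` uniform
    points; the mean of squared discrete second differences is averaged
    across days. Days with fewer than 3 renditions are skipped with a
    warning. A bias linear in rendition index gives 0.
    """
    b = np.asarray(bias_series, dtype=float)
    days = np.asarray(day_index)
    vals = []
    for d in np.unique(days):
        seg = b[days == d]
        if seg.size < 3:
            warnings.warn(f"day {d}: fewer than 3 renditions, skipped")
            continue
        grid = np.linspace(0, seg.size - 1, resample_n)
        res = np.interp(grid, np.arange(seg.size), seg)
        d2 = np.diff(res, n=2)
        vals.append(np.mean(d2 * d2))
    if not vals:
        raise ValueError("no day with at least 3 renditions")
    return float(np.mean(vals))


def smoothed_rmse(sim: np.ndarray, obs: np.ndarray, window: int = 50) -> float:
    """RMS difference of two running-average-smoothed pitch series.

    Both series are smoothed with a running average over the last
    ``window`` renditions (first window-1 points dropped).
    """
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("series length mismatch")
    if sim.size < window:
        raise ValueError("series shorter than the smoothing window")
    kern = np.ones(window) / window
    ds = np.convolve(sim, kern, mode="valid")
    do = np.convolve(obs, kern, mode="valid")
    return float(np.sqrt(np.mean((ds - do) ** 2)))


def normalized_final_pitch(
    traj,
    first_day_threshold: float | None = None,
    last_day_threshold: float | None = None,
) -> float:
    """Mean pitch of the last feedback day, normalized between the
    first-day threshold (0) and the last-day threshold (1)."""
    thr = traj.threshold
    fb = np.isfinite(thr)
    if not fb.any():
        raise ValueError("trajectory has no feedback renditions")
    day = traj.day
    fb_days = np.unique(day[fb])
    if first_day_threshold is None:
        first_day_threshold = float(np.nanmean(thr[fb & (day == fb_days[0])]))
    if last_day_threshold is None:
        last_day_threshold = float(np.nanmean(thr[fb & (day == fb_days[-1])]))
    if last_day_threshold == first_day_threshold:
        raise ValueError("first- and last-day thresholds are equal; "
                         "normalization undefined")
    last_mean = float(np.mean(traj.pitch[fb & (day == fb_days[-1])]))
    return (last_mean - first_day_threshold) / (last_day_threshold - first_day_threshold)


def dprime(sample_a, sample_b) -> float:
    """Standardized mean difference (Cohen's d with pooled SD)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 points")
    pooled = np.sqrt(
        ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1))
        / (a.size + b.size - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled SD")
    return float((a.mean() - b.mean()) / pooled)


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation r_0..r_max_lag (r_0 = 1)."""
    x = np.asarray(series, dtype=float)
    if x.size <= max_lag:
        raise ValueError("series shorter than max_lag")
    xc = x - x.mean()
    denom = float(xc @ xc)
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        out[k] = (xc[:-k] @ xc[k:]) / denom
    return out
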