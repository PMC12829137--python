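"""Pitch-step (discontinuity) detection, iterative removal, and the
equality-of-proportions test for WN-contingent stepping.

A step at rendition i is flagged when the mean pitch of the n_s renditions
before i and the mean of the n_s renditions from i onwards differ by more
than a fraction theta of the local mean. Because the criterion is relative
to the local mean, detection is invariant to rescaling the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StepEvent",
    "StepTestResult",
    "detect_steps",
    "remove_steps_iterative",
    "step_rate_ztest",
]


@dataclass
class StepEvent:
    index: int
    left_mean: float
    right_mean: float
    local_mean: float
    wn_preceded: bool | None = None

    @property
    def size(self) -> float:
        return abs(self.left_mean - self.right_mean)

    @property
    def direction(self) -> int:
        return int(np.sign(self.right_mean - self.left_mean))


@dataclass
class StepTestResult:
    """Equality-of-proportions Z test of WN-preceded step rate vs chance."""

    r_a: float      # fraction of detected steps preceded by WN, nD_WN / n_D
    r_c: float      # chance rate: fraction of renditions preceded, nWN / T
    r: float        # pooled rate
    z: float
    n_d: int        # number of detected steps
    n_d_wn: int     # steps preceded by WN within the lookback window
    n_wn: int       # renditions preceded by WN within the window
    T: int

    @property
    def significant(self) -> bool:
        return abs(self.z) > 1.96


def _window_means(series: np.ndarray, n_s: int):
    """Left/right/local window means at every admissible index.

    left over [i-n_s, i), right over [i, i+n_s), local over
    [i-n_s, i+n_s] (2 n_s + 1 renditions, the stated window taken
    literally)."""
    p = np.asarray(series, dtype=float)
    T = p.size
    cs = np.concatenate([[0.0], np.cumsum(p)])
    idx = np.arange(n_s, T - n_s)
    left = (cs[idx] - cs[idx - n_s]) / n_s
    right = (cs[idx + n_s] - cs[idx]) / n_s
    local = (cs[idx + n_s + 1] - cs[idx - n_s]) / (2 * n_s + 1)
    return idx, left, right, local


def detect_steps(series: np.ndarray, n_s: int = 20, theta: float = 0.05
                 ) -> list[StepEvent]:
    """Single-pass detection of pitch steps |p_l - p_r| > theta * p_m.

    Only indices in [n_s, T - n_s) are considered, so discontinuities at
    the series boundaries are deliberately ignored.
    """
    p = np.asarray(series, dtype=float)
    if p.size <= 2 * n_s:
        raise ValueError("series too short for the step windows")
    idx, left, right, local = _window_means(p, n_s)
    flag = np.abs(left - right) > theta * local
    return [
        StepEvent(int(i), float(l), float(r), float(m))
        for i, l, r, m in zip(idx[flag], left[flag], right[flag], local[flag])
    ]


def remove_steps_iterative(series: np.ndarray, n_s: int = 20,
                           theta: float = 0.05
                           ) -> tuple[np.ndarray, list[StepEvent]]:
    """Iteratively remove the largest detected step until none remains.

    Each iteration shifts all renditions from the step index onward by the
    signed step size (left mean minus right mean), which restores
    continuity; the paper's printed absolute-size shift would double
    upward steps instead of cancelling them. Ties in magnitude break to
    the earliest index. Events are returned in removal order with the
    window statistics measured at detection time.
    """
    p = np.asarray(series, dtype=float).copy()
    removed: list[StepEvent] = []
    for _ in range(p.size):
        events = detect_steps(p, n_s, theta)
        if not events:
            return p, removed
        best = max(events, key=lambda e: (e.size, -e.index))
        p[best.index:] += best.left_mean - best.right_mean
        removed.append(best)
    raise RuntimeError("step removal did not terminate")


def step_rate_ztest(events: list[StepEvent], wn_flags: np.ndarray,
                    lookback: int = 20) -> StepTestResult:
    """Z test for equality of the WN-preceded step rate and chance.

    ``wn_flags`` marks renditions on which WN was delivered (hits). A step
    (and, for the chance rate, any rendition) counts as WN-preceded when
    WN fell on any of the ``lookback`` renditions before it. The two
    proportions are r_A = nD_WN / n_D (the fraction of detected steps
    that follow WN, a proportion over n_D steps) and r_C = nWN / T (the
    fraction of renditions that follow WN, a proportion over T
    renditions); with the pooled rate r = (nD_WN + nWN) / (n_D + T),

        Z = (r_A - r_C) / sqrt(r (1 - r) (1/T + 1/n_D)),

    the standard pooled two-proportion statistic for sample sizes n_D
    and T.
    """
    wn = np.asarray(wn_flags, dtype=float) > 0.5
    T = wn.size
    if T < 1:
        raise ValueError("empty rendition series")
    n_d = len(events)
    if n_d == 0:
        raise ValueError("Z test undefined with zero detected steps")
    cs = np.concatenate([[0], np.cumsum(wn.astype(int))])
    t = np.arange(T)
    lo = np.maximum(0, t - lookback)
    preceded = (cs[t] - cs[lo]) > 0
    n_wn = int(preceded.sum())
    n_d_wn = 0
    for e in events:
        e.wn_preceded = bool(preceded[e.index]) if e.index < T else False
        n_d_wn += int(e.wn_preceded)
    r_a = n_d_wn / n_d
    r_c = n_wn / T
    r = (n_d_wn + n_wn) / (n_d + T)
    denom = np.sqrt(r * (1.0 - r) * (1.0 / T + 1.0 / n_d))
    z = (r_a - r_c) / denom if denom > 0 else 0.0
    return StepTestResult(r_a, r_c, r, float(z), n_d, n_d_wn, n_wn, T)
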