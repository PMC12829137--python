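"""Generative model: closed-loop pitch-conditioning experiments.

Simulates full experiments forward from parameters: a multi-day singing
schedule (morning-heavy, bout-structured), the repertoire components
(colored drift, circadian pattern, history offsets), the latent learner's
explorations and bias, and white-noise (WN) feedback contingent on a
threshold that is updated by a configurable policy. Synthetic birds come
with exact ground truth for every latent component, which makes them the
package's parameter-recovery and falsification fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import LearnerParams, rewards_from_hits
from .repertoire import (
    CircadianBasis,
    ColoredNoiseParams,
    HistoryModel,
    RepertoireParams,
)
from .trajectory import PitchTrajectory, history_counts

__all__ = [
    "ThresholdPolicy",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticBird",
    "default_repertoire",
    "make_schedule",
    "simulate_experiment",
    "threshold_update",
    "daily_improvement",
    "optimal_hit_probability",
    "compare_policies",
    "generate_synthetic_bird",
    "PRESETS",
]

#: lights-on window as fractions of the day (08:00 to 22:00, a 14-h day)
_DAY_START, _DAY_END = 8.0 / 24.0, 22.0 / 24.0


@dataclass
class ThresholdPolicy:
    """How the WN threshold is updated during the feedback period.

    kinds: ``daily_quantile`` (q-quantile of the previous day's pitches,
    held for the whole day), ``running_median`` (median of the last
    ``window`` renditions, recomputed every rendition), ``fixed``, and
    ``human_auto`` (running median re-engaged only when the escape rate
    over the last ``window`` renditions leaves [escape_lo, escape_hi]).
    """

    kind: str = "daily_quantile"
    q: float = 0.5
    window: int = 20
    value: float | None = None  # fixed threshold
    escape_hi: float = 0.80
    escape_lo: float = 0.05

    def __post_init__(self):
        if self.kind not in ("daily_quantile", "running_median", "fixed", "human_auto"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not 0 < self.q < 1:
            raise ValueError("quantile q must lie in (0, 1)")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class SimulationConfig:
    """Everything needed to simulate one bird's conditioning experiment."""

    rep: RepertoireParams
    learner: LearnerParams = field(default_factory=LearnerParams)
    n_baseline_days: int = 4
    n_feedback_days: int = 10
    contingency: str = "low"        # WN on low pitch -> escape direction is up
    renditions_per_day: tuple = (300, 1500)
    n_reps: int = 1
    seed: int = 0
    exploration: str = "gaussian"   # gaussian | non_gaussian | non_iid
    variant: str = "latent_basic"   # latent_basic | classical
    schedule: tuple | None = None   # optional explicit (day, h) arrays

    def __post_init__(self):
        if self.n_baseline_days + self.n_feedback_days < 1:
            raise ValueError("need at least one day")
        if self.contingency not in ("low", "high"):
            raise ValueError("contingency must be 'low' or 'high'")


@dataclass
class GroundTruth:
    """True per-rendition latent components of a simulated trajectory."""

    eps: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    o: np.ndarray
    pitch: np.ndarray
    rep: RepertoireParams
    learner: LearnerParams

    def __post_init__(self):
        total = self.rep.p_star + self.eps + self.b + self.c + self.d + self.o
        if not np.allclose(total, self.pitch, atol=1e-9):
            raise AssertionError("ground-truth components do not sum to pitch")


@dataclass
class SyntheticBird:
    traj: PitchTrajectory
    truth: GroundTruth
    post_traj: PitchTrajectory | None = None  # lesion pair: exploration deleted
    post_truth: GroundTruth | None = None


def default_repertoire(p_star: float = 1000.0) -> RepertoireParams:
    """Paper-scale repertoire for synthetic birds.

    Component magnitudes follow the observed variance split: exploration
    dominates, while colored drift, circadian pattern and history
    dependence each contribute roughly 10-15% of baseline pitch variance.
    The circadian shape is an inverted U (morning rise, evening decline)
    and the history offsets fall from the first motif of a bout onwards.
    """
    nodes = np.array([_DAY_START, 0.40, 0.46, 0.54, 0.64, 0.76, _DAY_END])
    circ = np.array([-2.0, 4.0, 5.0, 3.0, 0.0, -4.0, -6.0])
    hist = np.array([6.0, 0.5, -2.0, -3.5, -4.5])
    return RepertoireParams(
        p_star=p_star,
        circadian=CircadianBasis(nodes, circ),
        history=HistoryModel(2.0, 5, hist),
        noise=ColoredNoiseParams(tau=0.01, sigma_innov2=0.46),
    )


def make_schedule(
    n_days: int,
    rng: np.random.Generator,
    renditions_per_day=(300, 1500),
) -> tuple[np.ndarray, np.ndarray]:
    """Morning-heavy, bout-structured singing schedule.

    Bout start times follow a Beta(1.3, 2.0) over a 14-h day (more singing
    in the morning); bouts contain 1 + Poisson(1.5) renditions (capped at
    6) spaced ~0.7 s, so history counts within 2 s span 0..4.
    """
    days, hs = [], []
    for d in range(n_days):
        n = int(rng.integers(renditions_per_day[0], renditions_per_day[1] + 1))
        times = []
        while len(times) < n:
            start = _DAY_START + rng.beta(1.3, 2.0) * (_DAY_END - _DAY_START)
            size = min(1 + rng.poisson(1.5), 6)
            t = start * 86400.0
            for _ in range(size):
                times.append(t)
                t += max(rng.normal(0.7, 0.05), 0.5)
        times = np.sort(np.asarray(times[:n]))
        # enforce strictly increasing times for bout collisions
        for i in range(1, times.size):
            if times[i] <= times[i - 1]:
                times[i] = times[i - 1] + 1e-3
        days.append(np.full(n, d))
        hs.append(times / 86400.0)
    return np.concatenate(days), np.concatenate(hs)


def threshold_update(policy: ThresholdPolicy, state) -> float:
    """Compute a threshold from history per the policy.

    ``state`` is the pitch history the policy needs: the previous day's
    pitches for ``daily_quantile``, the recent pitches (last ``window``)
    for ``running_median``/``human_auto``.
    """
    state = np.asarray(state, dtype=float)
    if state.size == 0:
        raise ValueError("threshold update needs a non-empty pitch history")
    if policy.kind == "daily_quantile":
        return float(np.quantile(state, policy.q))  # linear interpolation
    if policy.kind in ("running_median", "human_auto"):
        return float(np.median(state[-policy.window:]))
    if policy.kind == "fixed":
        if policy.value is None:
            raise ValueError("fixed policy needs a value")
        return float(policy.value)
    raise ValueError(policy.kind)


def _draw_explorations(kind, sigma, T, rng):
    if kind == "gaussian":
        return rng.normal(0.0, sigma, T)
    if kind == "non_gaussian":
        # iid scale mixture: occasional large-variance renditions
        # (variance matched to sigma^2)
        s = sigma / np.sqrt(0.9 + 0.1 * 25.0)
        big = rng.random(T) < 0.1
        return np.where(big, rng.normal(0, 5 * s, T), rng.normal(0, s, T))
    if kind == "non_iid":
        # stochastic volatility: slowly wandering exploration magnitude
        # (marginal variance matched to sigma^2, but not independent)
        sv = 0.6
        v = np.empty(T)
        v[0] = rng.normal(0, sv)
        phi = 0.97
        innov = rng.normal(0, sv * np.sqrt(1 - phi * phi), T)
        for t in range(1, T):
            v[t] = phi * v[t - 1] + innov[t]
        return sigma * np.exp(v - sv * sv) * rng.standard_normal(T)
    if kind == "none":
        return np.zeros(T)
    raise ValueError(f"unknown exploration kind {kind!r}")


def _simulate_one(config: SimulationConfig, policy: ThresholdPolicy | None,
                  rng: np.random.Generator):
    rep, lp = config.rep, config.learner
    n_days = config.n_baseline_days + config.n_feedback_days
    if config.schedule is not None:
        day, h = config.schedule
        day = np.asarray(day, int)
        h = np.asarray(h, float)
    else:
        day, h = make_schedule(n_days, rng, config.renditions_per_day)
    T = day.size
    sched = PitchTrajectory(pd.DataFrame({
        "day": day, "h": h, "pitch_hz": np.ones(T),  # placeholder pitches
    }))

    classical = config.variant == "classical"
    if classical:
        d_t = np.zeros(T)
        o_t = np.zeros(T)
        c = np.zeros(T)
    else:
        d_t = rep.circadian.evaluate(h)
        o_t = rep.history.evaluate(sched)
        a = 1.0 - rep.noise.tau
        innov = rng.normal(0, np.sqrt(rep.noise.sigma_innov2), T)
        c = np.empty(T)
        c[0] = innov[0]
        for t in range(1, T):
            c[t] = a * c[t - 1] + innov[t]

    eps = _draw_explorations(config.exploration, np.sqrt(lp.sigma_eps2), T, rng)
    eta = rng.normal(0, np.sqrt(lp.sigma_eta2), T)

    fb_start = np.searchsorted(day, config.n_baseline_days)
    low = config.contingency == "low"
    esc, hit_val = lp.reward_convention

    b = np.zeros(T)
    pitch = np.empty(T)
    thr = np.full(T, np.nan)
    hits = np.full(T, np.nan)
    R_prev = 0.0  # baseline: reward-free
    cur_thr = np.nan
    cur_day = -1
    for t in range(T):
        # the learner's bias engages at feedback onset (baseline: b = 0,
        # matching the reward-free model in which the bias is absent)
        if t > 0 and t >= fb_start:
            b[t] = (1.0 - lp.delta) * b[t - 1] + lp.alpha * R_prev * eps[t - 1] + eta[t]
        pitch[t] = rep.p_star + c[t] + d_t[t] + o_t[t] + b[t] + eps[t]
        if t >= fb_start and policy is not None:
            if policy.kind == "daily_quantile":
                if day[t] != cur_day:
                    prev_mask = day == (day[t] - 1)
                    cur_thr = threshold_update(policy, pitch[:t][prev_mask[:t]])
                    cur_day = day[t]
            elif policy.kind == "running_median":
                cur_thr = threshold_update(policy, pitch[max(0, t - policy.window):t])
            elif policy.kind == "human_auto":
                if np.isnan(cur_thr):
                    cur_thr = threshold_update(policy, pitch[max(0, t - policy.window):t])
                else:
                    lo = max(fb_start, t - policy.window)
                    if t > lo:
                        esc_rate = 1.0 - np.nanmean(hits[lo:t])
                        if esc_rate > policy.escape_hi or esc_rate < policy.escape_lo:
                            cur_thr = threshold_update(
                                policy, pitch[max(0, t - policy.window):t])
            elif policy.kind == "fixed":
                cur_thr = threshold_update(policy, pitch[:t])
            thr[t] = cur_thr
            is_hit = pitch[t] < cur_thr if low else pitch[t] > cur_thr
            hits[t] = float(is_hit)
            R_prev = hit_val if is_hit else esc
        else:
            R_prev = esc if t >= fb_start else 0.0

    df = pd.DataFrame({
        "day": day, "h": h, "pitch_hz": pitch, "hit": hits,
        "threshold_hz": thr,
        "contingency": np.where(np.isfinite(thr), config.contingency, None),
    })
    traj = PitchTrajectory(df, {"subject": "synthetic"})
    truth = GroundTruth(eps=eps, b=b, c=c, d=d_t, o=o_t, pitch=pitch,
                        rep=rep, learner=lp)
    return traj, truth


def simulate_experiment(
    config: SimulationConfig,
    policy: ThresholdPolicy | None = None,
) -> tuple[list[PitchTrajectory], list[GroundTruth]]:
    """Simulate ``config.n_reps`` closed-loop experiments.

    Baseline days are reward-free; from the feedback onset the threshold
    follows ``policy`` (default: daily median of the previous day) and WN
    hits are determined by the contingency direction (ties count as
    escape). Reproducible per ``config.seed``.
    """
    if policy is None and config.n_feedback_days > 0:
        policy = ThresholdPolicy("daily_quantile", q=0.5)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    trajs, truths = [], []
    for ss in seeds:
        traj, truth = _simulate_one(config, policy, np.random.default_rng(ss))
        trajs.append(traj)
        truths.append(truth)
    return trajs, truths


def daily_improvement(traj: PitchTrajectory, n_days: int = 3,
                      morning_n: int = 100) -> float:
    """Mean daily pitch improvement (Hz/day) in the escape direction.

    Difference between the mean pitch of the first ``morning_n`` morning
    renditions of consecutive feedback days, averaged over the first
    ``n_days`` day-to-day steps. Days with fewer renditions use all of
    them (with a warning).
    """
    import warnings

    fb = traj.is_feedback
    if not fb.any():
        raise ValueError("no feedback renditions")
    day = traj.day
    fb_days = np.unique(day[fb])
    if fb_days.size < 2:
        raise ValueError("need at least 2 feedback days")
    means = []
    for d in fb_days[: n_days + 1]:
        seg = traj.pitch[fb & (day == d)]
        if seg.size < morning_n:
            warnings.warn(f"day {d}: only {seg.size} renditions, using all")
        means.append(seg[:morning_n].mean())
    diffs = np.diff(means)
    sign = 1.0 if traj.contingency == "low" else -1.0
    return float(sign * diffs.mean())


def optimal_hit_probability(
    exploration_distribution=None,
    grid_resolution: float = 1e-3,
) -> float:
    """Hit probability q* maximizing the expected per-trial bias drift.

    With WN delivered when the exploration falls below its q-quantile
    (reward -1 on hit, 0 on escape), the expected drift magnitude is
    |E[R eps]| = |int_0^q F^{-1}(u) du|. The argmax over q is returned on
    a grid of the given resolution. For any symmetric unimodal
    exploration density the optimum is exactly 1/2.
    """
    from scipy import stats

    dist = exploration_distribution or stats.norm()
    fine = grid_resolution / 10.0
    u = np.arange(fine / 2.0, 1.0, fine)  # midpoint rule; ppf endpoints diverge
    vals = dist.ppf(u)
    partial = np.cumsum(vals) * fine  # int_0^q ppf(u) du on the fine grid
    qs = np.arange(grid_resolution, 1.0, grid_resolution)
    idx = np.round(qs / fine).astype(int) - 1
    drift = np.abs(partial[idx])
    return float(qs[int(np.argmax(drift))])


def compare_policies(
    config: SimulationConfig,
    policies: dict[str, ThresholdPolicy],
    n_birds: int = 18,
) -> pd.DataFrame:
    """Per-policy mean daily improvement over matched synthetic birds.

    Common random numbers: each bird keeps its seed (hence its schedule
    and noise stream) across policies, sharpening paired contrasts.
    """
    rows = []
    for bird in range(n_birds):
        cfg = replace(config, seed=config.seed + 1000 * bird, n_reps=1)
        for name, pol in policies.items():
            trajs, _ = simulate_experiment(cfg, pol)
            rows.append({
                "bird": bird, "policy": name,
                "daily_improvement_hz": daily_improvement(trajs[0]),
            })
    return pd.DataFrame(rows)


def _preset_config(preset: str, seed: int, **overrides) -> SimulationConfig:
    rep = overrides.pop("rep", default_repertoire())
    learner = overrides.pop("learner", LearnerParams(
        alpha=0.003, delta=3e-4, sigma_eps2=100.0, sigma_eta2=0.01,
    ))
    base = dict(rep=rep, learner=learner, seed=seed)
    if preset == "baseline_only":
        base.update(n_baseline_days=4, n_feedback_days=0)
    elif preset == "feedback":
        base.update(n_baseline_days=4, n_feedback_days=18)
    elif preset == "lesion_pair":
        base.update(n_baseline_days=4, n_feedback_days=0)
    elif preset == "non_gaussian_exploration":
        base.update(n_baseline_days=4, n_feedback_days=0,
                    exploration="non_gaussian")
    elif preset == "non_iid_exploration":
        base.update(n_baseline_days=4, n_feedback_days=0,
                    exploration="non_iid")
    else:
        raise ValueError(f"unknown preset {preset!r}")
    base.update(overrides)
    return SimulationConfig(**base)


PRESETS = ("baseline_only", "feedback", "lesion_pair",
           "non_gaussian_exploration", "non_iid_exploration")


def generate_synthetic_bird(preset: str = "feedback", seed: int = 0,
                            **overrides) -> SyntheticBird:
    """Generate one synthetic bird with exact ground truth.

    Presets: ``baseline_only`` (free singing, bias = 0), ``feedback``
    (baseline + WN conditioning under the daily-median policy),
    ``lesion_pair`` (pre/post pair where the post trajectory deletes the
    exploration channel), ``non_gaussian_exploration`` and
    ``non_iid_exploration`` (falsification fixtures whose explorations
    violate the iid-Gaussian assumption).
    """
    config = _preset_config(preset, seed, **overrides)
    trajs, truths = simulate_experiment(config)
    bird = SyntheticBird(trajs[0], truths[0])
    if preset == "lesion_pair":
        post_cfg = replace(config, exploration="none", seed=seed + 7)
        post_trajs, post_truths = simulate_experiment(post_cfg)
        bird.post_traj = post_trajs[0]
        bird.post_truth = post_truths[0]
    return bird
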