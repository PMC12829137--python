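import numpy as np
import pytest
from scipy import stats

from latentrl.model import LearnerParams
from latentrl.simulate import (
    PRESETS,
    SimulationConfig,
    ThresholdPolicy,
    compare_policies,
    daily_improvement,
    default_repertoire,
    generate_synthetic_bird,
    make_schedule,
    optimal_hit_probability,
    simulate_experiment,
    threshold_update,
)

from conftest import make_traj


def _config(**kw):
    base = dict(rep=default_repertoire(),
                learner=LearnerParams(alpha=0.003, delta=3e-4,
                                      sigma_eps2=100.0, sigma_eta2=0.01),
                n_baseline_days=1, n_feedback_days=2,
                renditions_per_day=(300, 500), seed=0)
    base.update(kw)
    return SimulationConfig(**base)


def test_seed_determinism():
    t1, g1 = simulate_experiment(_config())
    t2, g2 = simulate_experiment(_config())
    np.testing.assert_array_equal(t1[0].pitch, t2[0].pitch)
    np.testing.assert_array_equal(g1[0].eps, g2[0].eps)
    t3, _ = simulate_experiment(_config(seed=1))
    assert not np.array_equal(t1[0].pitch, t3[0].pitch)


def test_ground_truth_conservation():
    trajs, truths = simulate_experiment(_config())
    g = truths[0]
    np.testing.assert_allclose(
        g.rep.p_star + g.eps + g.b + g.c + g.d + g.o, trajs[0].pitch,
        atol=1e-9)


def test_schedule_shape():
    rng = np.random.default_rng(0)
    day, h = make_schedule(3, rng, (300, 500))
    counts = np.bincount(day)
    assert np.all((counts >= 300) & (counts <= 500))
    assert np.all((h >= 8 / 24) & (h < 23 / 24))
    # morning-heavy: mean singing time before the midpoint of the day
    assert h.mean() < (8 / 24 + 22 / 24) / 2


def test_threshold_update_rules():
    pol = ThresholdPolicy("daily_quantile", q=0.5)
    assert threshold_update(pol, [1, 2, 3, 4, 5]) == 3.0
    pol8 = ThresholdPolicy("daily_quantile", q=0.8)
    assert threshold_update(pol8, np.arange(1, 11)) == pytest.approx(8.2)
    run = ThresholdPolicy("running_median", window=20)
    assert threshold_update(run, np.arange(100.0)) == np.median(np.arange(80, 100.0))
    fixed = ThresholdPolicy("fixed", value=42.0)
    assert threshold_update(fixed, [1.0]) == 42.0
    with pytest.raises(ValueError):
        threshold_update(pol, [])
    with pytest.raises(ValueError):
        ThresholdPolicy("daily_quantile", q=1.5)


def test_alpha_zero_no_bias_growth():
    cfg = _config(learner=LearnerParams(alpha=0.0, delta=3e-4,
                                        sigma_eps2=100.0, sigma_eta2=0.0),
                  n_feedback_days=4)
    _, truths = simulate_experiment(cfg)
    assert np.max(np.abs(truths[0].b)) < 1e-9


def test_reward_free_pitch_is_repertoire_plus_exploration():
    cfg = _config(learner=LearnerParams(alpha=0.003, delta=3e-4,
                                        sigma_eps2=100.0, sigma_eta2=0.0),
                  n_feedback_days=0)
    trajs, truths = simulate_experiment(cfg)
    g = truths[0]
    np.testing.assert_allclose(
        trajs[0].pitch, g.rep.p_star + g.c + g.d + g.o + g.eps, atol=1e-9)
    assert np.all(g.b == 0.0)


def test_escape_direction_learning():
    """Paper-scale parameters, daily-median policy: smoothed pitch moves in
    the escape direction."""
    cfg = _config(n_baseline_days=2, n_feedback_days=8,
                  renditions_per_day=(600, 900))
    trajs, _ = simulate_experiment(cfg)
    tr = trajs[0]
    fb = tr.is_feedback
    early = tr.pitch[fb][:500].mean()
    late = tr.pitch[fb][-500:].mean()
    assert late > early + 5.0  # contingency low -> escape is up


def test_daily_improvement_constructed():
    n = 300
    day = np.repeat([0, 1, 2], n)
    h = np.tile(np.linspace(0.34, 0.6, n), 3)
    pitch = 1000.0 + 4.0 * np.repeat([0, 1, 2], n)
    thr = np.full(3 * n, 990.0)
    hit = (pitch < thr).astype(float)
    traj = make_traj(day, h, pitch, threshold_hz=thr, hit=hit,
                     contingency=["low"] * (3 * n))
    assert daily_improvement(traj) == pytest.approx(4.0)
    flat = make_traj(day, h, np.full(3 * n, 1000.0), threshold_hz=thr,
                     hit=np.zeros(3 * n), contingency=["low"] * (3 * n))
    assert daily_improvement(flat) == 0.0


def test_daily_improvement_needs_two_days():
    n = 150
    traj = make_traj(np.zeros(n, int), np.linspace(0.34, 0.6, n),
                     np.full(n, 1000.0), threshold_hz=np.full(n, 990.0),
                     hit=np.zeros(n), contingency=["low"] * n)
    with pytest.raises(ValueError):
        daily_improvement(traj)


def test_optimal_hit_probability_symmetric_half():
    assert optimal_hit_probability() == pytest.approx(0.5, abs=1e-3)
    assert optimal_hit_probability(stats.t(5)) == pytest.approx(0.5, abs=2e-3)


def test_optimal_hit_probability_skewed_matches_quadrature():
    """Right-skewed (mean-centered lognormal) exploration: optimum moves
    off 1/2 and agrees with a brute-force quadrature of the truncated
    mean objective."""
    from scipy.integrate import quad

    dist = stats.lognorm(0.9, loc=-np.exp(0.9**2 / 2))  # mean approx 0
    q_star = optimal_hit_probability(dist, grid_resolution=1e-3)
    qs = np.arange(0.05, 1.0, 0.005)
    vals = [abs(quad(lambda x: x * dist.pdf(x), dist.ppf(1e-9), dist.ppf(q))[0])
            for q in qs]
    q_ref = qs[int(np.argmax(vals))]
    assert abs(q_star - q_ref) < 0.01
    assert abs(q_star - 0.5) > 0.05


def test_compare_policies_far_threshold_no_learning():
    cfg = _config(n_baseline_days=1, n_feedback_days=3)
    pols = {"never_hit": ThresholdPolicy("fixed", value=700.0)}
    tab = compare_policies(cfg, pols, n_birds=6)
    # no hits -> no learning; mean improvement indistinguishable from 0
    assert abs(tab["daily_improvement_hz"].mean()) < 1.5


def test_presets_and_lesion_pair():
    assert set(PRESETS) >= {"baseline_only", "feedback", "lesion_pair"}
    bird = generate_synthetic_bird("baseline_only", seed=2,
                                   n_baseline_days=1)
    assert not bird.traj.is_feedback.any()
    assert np.all(bird.truth.b == 0)
    pair = generate_synthetic_bird("lesion_pair", seed=3,
                                   n_baseline_days=2)
    assert pair.post_traj is not None
    assert np.all(pair.post_truth.eps == 0)
    pre_var = np.var(pair.traj.pitch)
    post_var = np.var(pair.post_traj.pitch)
    # post deletes the exploration channel (sigma_eps^2 = 100)
    assert abs((pre_var - post_var) - 100.0) < 0.5 * 100.0


def test_unknown_preset():
    with pytest.raises(ValueError):
        generate_synthetic_bird("bogus", seed=0)
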