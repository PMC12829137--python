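import numpy as np
import pytest

from latentrl.model import (
    LearnerParams,
    ModelVariant,
    assemble_baseline_ssm,
    assemble_feedback_ssm,
    bias_update,
    reward_map,
    rewards_from_hits,
    running_mean_reward,
    variant_increment,
)
from latentrl.simulate import default_repertoire
from latentrl.repertoire import RepertoireParams, ColoredNoiseParams


@pytest.mark.parametrize("hit,conv,expected", [
    (True, (0, -1), -1.0),
    (False, (0, -1), 0.0),
    (True, (1, -1), -1.0),
    (False, (1, -1), 1.0),
    (True, (1, 0), 0.0),
])
def test_reward_map(hit, conv, expected):
    assert reward_map(hit, conv) == expected


def test_reward_map_rejects_unknown_convention():
    with pytest.raises(ValueError):
        reward_map(True, (2, -1))


def test_rewards_from_hits_nan_is_escape():
    r = rewards_from_hits(np.array([np.nan, 0.0, 1.0]), (0, -1))
    np.testing.assert_array_equal(r, [0.0, 0.0, -1.0])


def test_bias_update_arithmetic():
    # reward-free leak
    assert bias_update(10.0, 0.0, 5.0, 0.003, 0.1) == pytest.approx(9.0)
    # direct substitution of the learning term
    assert bias_update(0.0, -1.0, 2.0, 0.003, 3e-4) == pytest.approx(-0.006)
    # alpha=0, delta->0: identity
    assert bias_update(7.0, -1.0, 2.0, 0.0, 0.0) == pytest.approx(7.0)


def test_variant_increments():
    kw = dict(R_prev=-1.0, Rbar_prev=-0.4, eps_prev=2.0, V_prev=3.0,
              p_prev=1005.0, p_star=1000.0, alpha=0.01)
    assert variant_increment("latent_basic", **kw) == pytest.approx(-0.02)
    assert variant_increment("classical", **kw) == pytest.approx(-0.02)
    assert variant_increment("efference_copy", **kw) == pytest.approx(-0.05)
    assert variant_increment("pitch_error", **kw) == pytest.approx(
        0.01 * (-1.0 + 0.4) * 5.0)
    # mean-centered reward -> zero increment
    assert variant_increment("pitch_error", R_prev=-0.4, Rbar_prev=-0.4,
                             eps_prev=1, V_prev=0, p_prev=1010, p_star=1000,
                             alpha=0.01) == 0.0
    # efference copy with V=0 reduces to the basic rule
    assert variant_increment("efference_copy", R_prev=-1, Rbar_prev=0,
                             eps_prev=2.0, V_prev=0.0, p_prev=0, p_star=0,
                             alpha=0.01) == variant_increment(
        "latent_basic", R_prev=-1, Rbar_prev=0, eps_prev=2.0, V_prev=0.0,
        p_prev=0, p_star=0, alpha=0.01)


def test_running_mean_reward_window():
    r = np.array([-1.0, 0.0, -1.0, -1.0, 0.0])
    rb = running_mean_reward(r, window=2)
    np.testing.assert_allclose(rb, [0.0, -1.0, -0.5, -0.5, -1.0])


def test_learner_params_validation():
    with pytest.raises(ValueError):
        LearnerParams(delta=1.0)
    with pytest.raises(ValueError):
        LearnerParams(alpha=-0.1)
    with pytest.raises(ValueError):
        LearnerParams(reward_convention=(2, 0))
    with pytest.raises(ValueError):
        ModelVariant("bogus")


def test_baseline_ssm_dimensions(split_small):
    base, _ = split_small
    rep = default_repertoire()
    ssm = assemble_baseline_ssm(rep, base, sigma_expl2=100.0)
    assert ssm.nstates == 2
    assert ssm.labels == ("c", "s")
    # input vector u_t has N_D + 1 + N_h = 12 entries
    from latentrl.model import baseline_input_matrix
    U = baseline_input_matrix(base, rep)
    assert U.shape == (len(base), 12)


def test_feedback_ssm_matches_scalar_recursions(split_small):
    """Iterating the assembled matrices with given noise draws reproduces
    the scalar pitch-learning recursions sample-path-exactly."""
    _, feed = split_small
    rep = default_repertoire()
    lp = LearnerParams(alpha=0.003, delta=3e-4, sigma_eps2=100.0,
                       sigma_eta2=0.01)
    rewards = rewards_from_hits(feed.hit)
    ssm = assemble_feedback_ssm(rep, lp, feed, rewards)
    assert ssm.nstates == 3
    T = len(feed)
    rng = np.random.default_rng(9)
    eps = rng.normal(0, 10, T)
    eta = rng.normal(0, 0.1, T)
    innov = rng.normal(0, 0.7, T)
    m = rep.deterministic_mean(feed)
    a = 1 - rep.noise.tau
    b = np.zeros(T)
    c = np.zeros(T)
    p = np.zeros(T)
    p[0] = m[0] + eps[0]
    for t in range(1, T):
        c[t] = a * c[t - 1] + innov[t]
        b[t] = bias_update(b[t - 1], rewards[t - 1], eps[t - 1],
                           lp.alpha, lp.delta, eta[t])
        p[t] = b[t] + c[t] + m[t] + eps[t]
    x = np.zeros((T, 3))
    x[0] = [0.0, 0.0, m[0] + eps[0]]
    for t in range(1, T):
        x[t] = ssm.A[t] @ x[t - 1] + ssm.d[t] + np.array(
            [eta[t], innov[t], eps[t]])
    np.testing.assert_allclose(x @ ssm.H, p, atol=1e-9)
    np.testing.assert_allclose(x[:, 0], b, atol=1e-9)


def test_feedback_ssm_reward_free_is_pure_leak(split_small):
    _, feed = split_small
    rep = default_repertoire()
    lp = LearnerParams(alpha=0.003, delta=0.01, sigma_eps2=100.0,
                       sigma_eta2=0.0)
    ssm = assemble_feedback_ssm(rep, lp, feed, np.zeros(len(feed)))
    x = np.array([5.0, 0.0, 0.0])
    for t in range(1, 50):
        x = ssm.A[t] @ x + ssm.d[t]
    assert x[0] == pytest.approx(5.0 * 0.99**49)


def test_bias_stationary_variance_under_no_reward():
    """Var(b) under R=0 converges to sigma_eta^2 / (1 - (1-delta)^2)."""
    rng = np.random.default_rng(3)
    delta, s2 = 0.01, 0.25
    T = 200000
    eta = rng.normal(0, np.sqrt(s2), T)
    b = np.empty(T)
    b[0] = 0.0
    for t in range(1, T):
        b[t] = (1 - delta) * b[t - 1] + eta[t]
    target = s2 / (1 - (1 - delta) ** 2)
    burn = b[5000:]
    # 5-SE tolerance (effective sample size reduced by autocorrelation)
    n_eff = burn.size * delta
    se = target * np.sqrt(2.0 / n_eff)
    assert abs(np.var(burn) - target) < 5 * se


def test_classical_variant_drops_repertoire(split_small):
    _, feed = split_small
    rep = default_repertoire()
    lp = LearnerParams()
    ssm = assemble_feedback_ssm(rep, lp, feed, rewards_from_hits(feed.hit),
                                variant="classical")
    assert ssm.nstates == 2
    np.testing.assert_allclose(ssm.d[1:, 1], rep.p_star)
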