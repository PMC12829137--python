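"""The latent learner, reward conventions, model variants, and the
state-space constructions used for baseline and feedback fitting.

The learner injects iid Gaussian explorations eps_t ~ N(0, sigma_eps^2)
into pitch and accumulates a bias by leaky correlation of exploration with
reward (the pitch-learning update):

    b_t = (1 - delta) b_{t-1} + alpha R_{t-1} eps_{t-1} + eta_t

Observed pitch is p_t = eps_t + b_t + V_t with the repertoire
V_t = p* + c_t + d_t + o_t. Both fitting stages are expressed as
linear-Gaussian state-space systems:

* baseline (reward-free, bias fixed at zero): state x_t = [c_t, s_t] with
  s_t = m_t + eps_t and m_t = p* + d_t + o_t a linear function of the
  circadian/history input vector u_t; exploration is the process noise of
  the memoryless second state.
* feedback: state x_t = [b_t, c_t, s_t] with the repertoire frozen. The
  bias row needs eps_{t-1} = s_{t-1} - m_{t-1}; since m is deterministic
  given the frozen repertoire, the input u_t = [m_t, m_{t-1}] makes the
  transition exactly linear with reward-dependent entries +-alpha R_{t-1}.

The observation noise variance G is fixed and tiny, so explorations are
estimated as hidden-state noise rather than output noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kalman import StateSpaceModel
from .repertoire import RepertoireParams
from .trajectory import PitchTrajectory

__all__ = [
    "LearnerParams",
    "ModelVariant",
    "OBS_NOISE_VAR",
    "REWARD_CONVENTIONS",
    "reward_map",
    "rewards_from_hits",
    "running_mean_reward",
    "bias_update",
    "variant_increment",
    "assemble_baseline_ssm",
    "assemble_feedback_ssm",
    "BaselineDesign",
    "FeedbackDesign",
]

#: fixed observation-noise variance (Hz^2); kept very small so that the
#: decomposition residual is negligible against the behavioral components
OBS_NOISE_VAR = 1e-4

#: supported (escape, hit) reward value pairs
REWARD_CONVENTIONS = {(0.0, -1.0), (1.0, 0.0), (1.0, -1.0)}

_VARIANTS = ("latent_basic", "classical", "efference_copy", "pitch_error")


@dataclass
class LearnerParams:
    """Latent-learner parameters.

    alpha: learning rate; delta: per-rendition bias leak in (0, 1);
    sigma_eps2: exploration variance (Hz^2); sigma_eta2: bias-noise
    variance (Hz^2); reward_convention: (escape, hit) values.
    """

    alpha: float = 0.003
    delta: float = 3e-4
    sigma_eps2: float = 100.0
    sigma_eta2: float = 0.01
    reward_convention: tuple = (0.0, -1.0)

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie strictly in (0, 1)")
        if self.sigma_eps2 < 0 or self.sigma_eta2 < 0:
            raise ValueError("variances must be >= 0")
        conv = (float(self.reward_convention[0]), float(self.reward_convention[1]))
        if conv not in REWARD_CONVENTIONS:
            raise ValueError(f"unsupported reward convention {conv}")
        self.reward_convention = conv

    @property
    def escape_value(self) -> float:
        return self.reward_convention[0]


@dataclass
class ModelVariant:
    """Which bias-increment rule to use when fitting the feedback period."""

    name: str = "latent_basic"
    window: int = 20  # running-mean window for the pitch-error variant

    def __post_init__(self):
        if self.name not in _VARIANTS:
            raise ValueError(f"unknown variant {self.name!r}; choose from {_VARIANTS}")
        if self.window < 1:
            raise ValueError("running-mean window must be >= 1")


def reward_map(hit: bool, convention=(0.0, -1.0)) -> float:
    """Scalar reward for one rendition under an (escape, hit) convention."""
    conv = (float(convention[0]), float(convention[1]))
    if conv not in REWARD_CONVENTIONS:
        raise ValueError(f"unsupported reward convention {conv}")
    return conv[1] if hit else conv[0]


def rewards_from_hits(hits: np.ndarray, convention=(0.0, -1.0)) -> np.ndarray:
    """Vectorized reward_map over a hit-flag array (NaN treated as escape)."""
    conv = (float(convention[0]), float(convention[1]))
    if conv not in REWARD_CONVENTIONS:
        raise ValueError(f"unsupported reward convention {conv}")
    h = np.nan_to_num(np.asarray(hits, dtype=float), nan=0.0)
    return np.where(h > 0.5, conv[1], conv[0])


def running_mean_reward(rewards: np.ndarray, window: int = 20) -> np.ndarray:
    """Rbar_t: mean reward over the (up to) ``window`` renditions before t.

    With no prior rendition (t=0) the mean defaults to 0.
    """
    R = np.asarray(rewards, dtype=float)
    cs = np.concatenate([[0.0], np.cumsum(R)])
    t = np.arange(R.size)
    lo = np.maximum(0, t - window)
    n = np.maximum(t - lo, 1)
    out = (cs[t] - cs[lo]) / n
    out[0] = 0.0
    return out


def bias_update(b_prev, R_prev, eps_prev, alpha, delta, eta=0.0):
    """One step of the pitch-learning update (leaky reward-exploration
    correlation)."""
    return (1.0 - delta) * b_prev + alpha * R_prev * eps_prev + eta


def variant_increment(
    variant: ModelVariant | str,
    R_prev: float,
    Rbar_prev: float,
    eps_prev: float,
    V_prev: float,
    p_prev: float,
    p_star: float,
    alpha: float,
) -> float:
    """The learning term of the bias update for a given model variant.

    The leak and the bias noise are shared with :func:`bias_update`; only
    the reward-weighted term differs between variants.
    """
    name = variant.name if isinstance(variant, ModelVariant) else variant
    if name in ("latent_basic", "classical"):
        return alpha * R_prev * eps_prev
    if name == "efference_copy":
        return alpha * R_prev * (eps_prev + V_prev)
    if name == "pitch_error":
        return alpha * (R_prev - Rbar_prev) * (p_prev - p_star)
    raise ValueError(f"unknown variant {name!r}")


# ---------------------------------------------------------------------------
# concrete system construction
# ---------------------------------------------------------------------------

def _baseline_arrays(U, a, beta, sigma_innov2, sigma_expl2, prior_mean,
                     prior_cov, G):
    T = U.shape[0]
    m = U @ beta
    A = np.zeros((T, 2, 2))
    A[:, 0, 0] = a
    d = np.zeros((T, 2))
    d[:, 1] = m
    return StateSpaceModel(
        H=np.array([1.0, 1.0]),
        A=A,
        d=d,
        qdiag=np.array([sigma_innov2, sigma_expl2]),
        G=G,
        x1_mean=np.asarray(prior_mean, dtype=float),
        x1_cov=np.asarray(prior_cov, dtype=float),
        labels=("c", "s"),
        meta={"design": "baseline", "m": m},
    )


def baseline_input_matrix(traj: PitchTrajectory, rep: RepertoireParams) -> np.ndarray:
    """Input u_t: circadian hat weights stacked with history indicators.

    Dimension N_D + 1 + N_h; exactly one history indicator is 1 per
    rendition and the circadian weights sum to 1 inside the node span.
    """
    theta = rep.circadian.weights(traj.h)
    counts = rep.history.counts(traj)
    onehot = np.zeros((len(traj), rep.history.n_h))
    onehot[np.arange(len(traj)), counts] = 1.0
    return np.hstack([theta, onehot])


def assemble_baseline_ssm(
    rep: RepertoireParams,
    traj: PitchTrajectory,
    sigma_expl2: float,
    G: float = OBS_NOISE_VAR,
) -> StateSpaceModel:
    """Baseline (reward-free) system: x_t = [c_t, s_t], H = [1, 1].

    The bias is held at zero; exploration enters as the process noise of
    the memoryless repertoire-mean state s_t.
    """
    U = baseline_input_matrix(traj, rep)
    beta = np.concatenate([
        rep.p_star + rep.circadian.coefficients, rep.history.offsets
    ])
    a = 1.0 - rep.noise.tau
    m = U @ beta
    pv = max(float(np.var(traj.pitch)), 1.0)
    prior_mean = np.array([0.0, m[0]])
    prior_cov = np.diag([min(rep.noise.stationary_var, pv), sigma_expl2])
    return _baseline_arrays(U, a, beta, rep.noise.sigma_innov2, sigma_expl2,
                            prior_mean, prior_cov, G)


def _feedback_arrays(m, k2, k3, alpha, delta, a, sigma_innov2, sigma_eta2,
                     sigma_expl2, prior_mean, prior_cov, G, has_c):
    T = m.shape[0]
    phi1 = 1.0 - delta
    if has_c:
        A = np.zeros((T, 3, 3))
        A[:, 0, 0] = phi1
        A[:, 0, 2] = alpha * k2
        A[:, 1, 1] = a
        d = np.zeros((T, 3))
        d[:, 0] = alpha * k3
        d[:, 2] = m
        qdiag = np.array([sigma_eta2, sigma_innov2, sigma_expl2])
        labels = ("b", "c", "s")
        H = np.array([1.0, 1.0, 1.0])
    else:
        A = np.zeros((T, 2, 2))
        A[:, 0, 0] = phi1
        A[:, 0, 1] = alpha * k2
        d = np.zeros((T, 2))
        d[:, 0] = alpha * k3
        d[:, 1] = m
        qdiag = np.array([sigma_eta2, sigma_expl2])
        labels = ("b", "s")
        H = np.array([1.0, 1.0])
    return StateSpaceModel(
        H=H, A=A, d=d, qdiag=qdiag, G=G,
        x1_mean=np.asarray(prior_mean, dtype=float),
        x1_cov=np.asarray(prior_cov, dtype=float),
        labels=labels,
        meta={"design": "feedback", "m": m, "k2": k2, "k3": k3},
    )


def _increment_covariates(variant: ModelVariant, rewards, m, pitch, p_star):
    """Per-step pieces (k2, k3) such that the bias learning term entering
    rendition t is alpha * (k2[t] * s_{t-1} + k3[t])."""
    T = rewards.shape[0]
    k2 = np.zeros(T)
    k3 = np.zeros(T)
    if variant.name == "latent_basic":
        k2[1:] = rewards[:-1]
        k3[1:] = -rewards[:-1] * m[:-1]
    elif variant.name == "classical":
        k2[1:] = rewards[:-1]
        k3[1:] = -rewards[:-1] * p_star
    elif variant.name == "efference_copy":
        k2[1:] = rewards[:-1]
    elif variant.name == "pitch_error":
        rbar = running_mean_reward(rewards, variant.window)
        k3[1:] = (rewards[:-1] - rbar[:-1]) * (pitch[:-1] - p_star)
    return k2, k3


def assemble_feedback_ssm(
    rep: RepertoireParams,
    learner: LearnerParams,
    traj: PitchTrajectory,
    rewards: np.ndarray,
    variant: ModelVariant | str = "latent_basic",
    G: float = OBS_NOISE_VAR,
) -> StateSpaceModel:
    """Feedback (reinforcement) system with the repertoire frozen.

    For the basic latent variant the state is x_t = [b_t, c_t, s_t] with
    s_t = m_t + eps_t; the transition carries the reward-dependent entries
    +-alpha R_{t-1} that implement eps_{t-1} = s_{t-1} - m_{t-1}. The
    classical / efference-copy / pitch-error variants drop the fluctuating
    repertoire (V_t = p*) and use a 2-state system [b_t, s_t].
    """
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    rewards = np.asarray(rewards, dtype=float)
    if rewards.shape[0] != len(traj):
        raise ValueError("one reward per rendition required")
    if variant.name == "latent_basic":
        m = rep.deterministic_mean(traj)
        has_c = True
    else:
        m = np.full(len(traj), rep.p_star)
        has_c = False
    k2, k3 = _increment_covariates(variant, rewards, m, traj.pitch, rep.p_star)
    pv = max(float(np.var(traj.pitch)), 1.0)
    phi1 = 1.0 - learner.delta
    b_var = learner.sigma_eta2 / max(1.0 - phi1 * phi1, 1e-12)
    b_var = min(b_var, pv)
    if has_c:
        prior_mean = np.array([0.0, 0.0, m[0]])
        prior_cov = np.diag([b_var, min(rep.noise.stationary_var, pv),
                             learner.sigma_eps2])
    else:
        prior_mean = np.array([0.0, m[0]])
        prior_cov = np.diag([b_var, learner.sigma_eps2])
    return _feedback_arrays(m, k2, k3, learner.alpha, learner.delta,
                            1.0 - rep.noise.tau, rep.noise.sigma_innov2,
                            learner.sigma_eta2, learner.sigma_eps2,
                            prior_mean, prior_cov, G, has_c)


# ---------------------------------------------------------------------------
# EM designs
# ---------------------------------------------------------------------------

_VAR_FLOOR = 1e-12


class BaselineDesign:
    """EM design for the baseline system (free: tau, repertoire
    coefficients, both variances).

    Works on a (possibly mean-centered) observation series; the prior is
    fixed at construction so the closed-form M-step is exact EM.
    """

    default_free = ("a", "beta", "sigma_innov2", "sigma_expl2")

    def __init__(self, y: np.ndarray, U: np.ndarray, G: float = OBS_NOISE_VAR):
        self.y = np.asarray(y, dtype=float)
        self.U = np.asarray(U, dtype=float)
        if self.U.shape[0] != self.y.shape[0]:
            raise ValueError("input matrix / series length mismatch")
        self.G = float(G)
        pv = max(float(np.var(self.y)), 1e-6)
        self._prior_mean = np.array([0.0, self.y[0]])
        self._prior_cov = np.diag([pv, pv])
        # normal-equation pieces for the coefficient update (t >= 1)
        self._UtU = self.U[1:].T @ self.U[1:]

    def init_params(self, y=None) -> dict:
        pv = max(float(np.var(self.y)), 1e-6)
        beta, *_ = np.linalg.lstsq(self.U, self.y, rcond=None)
        a0 = 0.99  # tau = 0.01
        return {
            "a": a0,
            "beta": beta,
            "sigma_innov2": max(0.25 * pv * (1 - a0 * a0), _VAR_FLOOR),
            "sigma_expl2": 0.5 * pv,
        }

    def build(self, params: dict) -> StateSpaceModel:
        return _baseline_arrays(
            self.U, params["a"], params["beta"], params["sigma_innov2"],
            params["sigma_expl2"], self._prior_mean, self._prior_cov, self.G,
        )

    def mstep(self, params: dict, moments: dict, free) -> dict:
        xs, Exx, Exx1 = moments["xs"], moments["Exx"], moments["Exx1"]
        p = dict(params)
        Tm1 = xs.shape[0] - 1
        # colored-noise row: c_t = a c_{t-1} + innovation
        s_cc1 = Exx1[1:, 0, 0].sum()
        s_cc0 = Exx[:-1, 0, 0].sum()
        s_cc = Exx[1:, 0, 0].sum()
        if "a" in free and s_cc0 > 0:
            p["a"] = float(np.clip(s_cc1 / s_cc0, 0.0, 1.0 - 1e-8))
        if "sigma_innov2" in free:
            a = p["a"]
            p["sigma_innov2"] = max(
                (s_cc - 2 * a * s_cc1 + a * a * s_cc0) / Tm1, _VAR_FLOOR
            )
        # repertoire-mean row: s_t = u_t' beta + exploration
        if "beta" in free:
            rhs = self.U[1:].T @ xs[1:, 1]
            p["beta"], *_ = np.linalg.lstsq(self._UtU, rhs, rcond=None)
        if "sigma_expl2" in free:
            mu = self.U[1:] @ p["beta"]
            p["sigma_expl2"] = max(
                (Exx[1:, 1, 1] - 2 * mu * xs[1:, 1] + mu * mu).sum() / Tm1,
                _VAR_FLOOR,
            )
        return p

    @property
    def n_free_params(self) -> int:
        return 1 + self.U.shape[1] + 2


def _box_qp_2d(M, v, phi0, lo1, hi1, n_iter=200):
    """Coordinate descent for min 0.5 phi'M phi - v'phi with
    phi1 in [lo1, hi1], phi2 >= 0. Exact for this convex 2-D quadratic."""
    phi1, phi2 = phi0
    for _ in range(n_iter):
        if M[0, 0] > 0:
            phi1 = np.clip((v[0] - M[0, 1] * phi2) / M[0, 0], lo1, hi1)
        if M[1, 1] > _VAR_FLOOR:
            phi2 = max((v[1] - M[0, 1] * phi1) / M[1, 1], 0.0)
    return float(phi1), float(phi2)


class FeedbackDesign:
    """EM design for the feedback system.

    Free parameters: the bias leak (via 1 - delta), the learning rate
    alpha, the bias-noise variance and the exploration variance. The
    colored-noise row (when present) is frozen at its baseline estimate,
    per the two-stage fitting procedure.
    """

    default_free = ("delta", "alpha", "sigma_eta2", "sigma_expl2")

    def __init__(self, y, m, k2, k3, a, sigma_innov2, has_c=True,
                 G: float = OBS_NOISE_VAR, c_var0: float | None = None):
        self.y = np.asarray(y, dtype=float)
        self.m = np.asarray(m, dtype=float)
        self.k2 = np.asarray(k2, dtype=float)
        self.k3 = np.asarray(k3, dtype=float)
        self.a = float(a)
        self.sigma_innov2 = float(sigma_innov2)
        self.has_c = bool(has_c)
        self.G = float(G)
        pv = max(float(np.var(self.y)), 1e-6)
        b_var0 = pv
        cv = pv if c_var0 is None else min(c_var0, pv)
        if has_c:
            self._prior_mean = np.array([0.0, 0.0, self.m[0]])
            self._prior_cov = np.diag([b_var0, cv, pv])
            self._ib, self._is = 0, 2
        else:
            self._prior_mean = np.array([0.0, self.m[0]])
            self._prior_cov = np.diag([b_var0, pv])
            self._ib, self._is = 0, 1
        if not np.any(self.k2[1:] != 0) and not np.any(self.k3[1:] != 0):
            warnings.warn(
                "no reward variation in feedback data: alpha is unidentifiable"
            )

    def init_params(self, y=None) -> dict:
        pv = max(float(np.var(self.y)), 1e-6)
        return {
            "alpha": 1e-3,
            "delta": 1e-4,
            "sigma_eta2": 0.01 * pv,
            "sigma_expl2": 0.5 * pv,
        }

    def build(self, params: dict) -> StateSpaceModel:
        return _feedback_arrays(
            self.m, self.k2, self.k3, params["alpha"], params["delta"],
            self.a, self.sigma_innov2, params["sigma_eta2"],
            params["sigma_expl2"], self._prior_mean, self._prior_cov,
            self.G, self.has_c,
        )

    def mstep(self, params: dict, moments: dict, free) -> dict:
        xs, Exx, Exx1 = moments["xs"], moments["Exx"], moments["Exx1"]
        p = dict(params)
        ib, isx = self._ib, self._is
        Tm1 = xs.shape[0] - 1
        k2, k3 = self.k2[1:], self.k3[1:]
        # bias row: b_t = phi1 b_{t-1} + phi2 z2_t + eta_t,
        # z2_t = k2_t s_{t-1} + k3_t
        Ez1z1 = Exx[:-1, ib, ib]
        Ez1z2 = k2 * Exx[:-1, ib, isx] + k3 * xs[:-1, ib]
        Ez2z2 = k2 * k2 * Exx[:-1, isx, isx] + 2 * k2 * k3 * xs[:-1, isx] + k3 * k3
        Ebz1 = Exx1[1:, ib, ib]
        Ebz2 = k2 * Exx1[1:, ib, isx] + k3 * xs[1:, ib]
        M = np.array([[Ez1z1.sum(), Ez1z2.sum()],
                      [Ez1z2.sum(), Ez2z2.sum()]])
        v = np.array([Ebz1.sum(), Ebz2.sum()])
        phi1, phi2 = 1.0 - p["delta"], p["alpha"]
        if "delta" in free and "alpha" in free:
            phi1, phi2 = _box_qp_2d(M, v, (phi1, phi2), 1e-8, 1.0 - 1e-8)
        elif "delta" in free and M[0, 0] > 0:
            phi1 = float(np.clip((v[0] - M[0, 1] * phi2) / M[0, 0],
                                 1e-8, 1.0 - 1e-8))
        elif "alpha" in free and M[1, 1] > _VAR_FLOOR:
            phi2 = max((v[1] - M[0, 1] * phi1) / M[1, 1], 0.0)
        p["delta"] = 1.0 - phi1
        p["alpha"] = phi2
        if "sigma_eta2" in free:
            sse = (
                Exx[1:, ib, ib].sum()
                - 2 * phi1 * v[0] - 2 * phi2 * v[1]
                + phi1 * phi1 * M[0, 0]
                + 2 * phi1 * phi2 * M[0, 1]
                + phi2 * phi2 * M[1, 1]
            )
            p["sigma_eta2"] = max(sse / Tm1, _VAR_FLOOR)
        if "sigma_expl2" in free:
            mu = self.m[1:]
            p["sigma_expl2"] = max(
                (Exx[1:, isx, isx] - 2 * mu * xs[1:, isx] + mu * mu).sum() / Tm1,
                _VAR_FLOOR,
            )
        return p

    @property
    def n_free_params(self) -> int:
        return 4
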