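"""Non-reinforced repertoire components of vocal pitch.

The repertoire V_t = p* + c_t + d_t + o_t collects everything the latent
learner does *not* control: the stable pitch target p*, a slow colored
drift c_t (AR(1)-type random walk with leak tau), a circadian pattern d_t
(piecewise-linear hat basis over the day), and a bout-history offset o_t
(a fixed pitch offset indexed by how many renditions fell into the
preceding x seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import PitchTrajectory, history_counts

__all__ = [
    "CircadianBasis",
    "HistoryModel",
    "ColoredNoiseParams",
    "RepertoireParams",
    "equal_count_nodes",
    "circadian_weights",
    "evaluate_repertoire",
    "sample_colored_noise",
    "select_history_model",
]


@dataclass
class CircadianBasis:
    """Piecewise-linear circadian pitch pattern.

    ``nodes`` are N_D + 1 strictly increasing time-of-day fractions
    H_1..H_{N_D+1}; ``coefficients`` D_j give the pitch offset (Hz) at each
    node. Between nodes the offset interpolates linearly; outside the node
    span it is 0. After fitting, the rendition-weighted mean of the
    evaluated pattern is constrained to zero (the average pitch lives in
    p*).
    """

    nodes: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.nodes.ndim != 1 or self.nodes.size < 2:
            raise ValueError("need at least 2 circadian nodes")
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("circadian nodes must be strictly increasing")
        if np.any((self.nodes < 0) | (self.nodes >= 1)):
            raise ValueError("circadian nodes must lie in [0, 1)")
        if self.coefficients.shape != self.nodes.shape:
            raise ValueError("one coefficient per node required")

    @property
    def n_bins(self) -> int:
        return self.nodes.size - 1

    def weights(self, h) -> np.ndarray:
        return circadian_weights(h, self.nodes)

    def evaluate(self, h) -> np.ndarray:
        return self.weights(h) @ self.coefficients


@dataclass
class HistoryModel:
    """Bout-history pitch offsets O_1..O_{N_h}.

    ``o_t = O[1 + n_h(t)]`` (1-based), where n_h(t) in {0, ..., N_h-1} is
    the clipped count of renditions within the preceding ``x`` seconds.
    """

    x: float = 2.0
    n_h: int = 5
    offsets: np.ndarray = None

    def __post_init__(self):
        if self.n_h < 1:
            raise ValueError("n_h must be >= 1")
        if self.offsets is None:
            self.offsets = np.zeros(self.n_h)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.shape != (self.n_h,):
            raise ValueError("need exactly n_h offsets")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("history offsets must be finite")

    def counts(self, traj: PitchTrajectory) -> np.ndarray:
        return history_counts(traj, self.x, self.n_h)

    def evaluate(self, traj: PitchTrajectory) -> np.ndarray:
        return self.offsets[self.counts(traj)]


@dataclass
class ColoredNoiseParams:
    """Leaky random-walk drift: c_t = (1 - tau) c_{t-1} + innovation."""

    tau: float = 0.01
    sigma_innov2: float = 1.0

    def __post_init__(self):
        if not 0 < self.tau <= 1:
            raise ValueError("tau must lie in (0, 1]")
        if self.sigma_innov2 < 0:
            raise ValueError("innovation variance must be >= 0")

    @property
    def stationary_var(self) -> float:
        a = 1.0 - self.tau
        return self.sigma_innov2 / (1.0 - a * a) if a < 1 else np.inf


@dataclass
class RepertoireParams:
    """Full non-reinforced repertoire: p*, circadian, history, colored noise."""

    p_star: float
    circadian: CircadianBasis
    history: HistoryModel
    noise: ColoredNoiseParams = field(default_factory=ColoredNoiseParams)

    def __post_init__(self):
        if not self.p_star > 0:
            raise ValueError("target pitch p* must be positive")

    def deterministic_mean(self, traj: PitchTrajectory) -> np.ndarray:
        """m_t = p* + d_t + o_t (everything but the colored drift)."""
        return (
            self.p_star
            + self.circadian.evaluate(traj.h)
            + self.history.evaluate(traj)
        )

    def to_dict(self) -> dict:
        return {
            "p_star": float(self.p_star),
            "circadian_nodes": self.circadian.nodes.tolist(),
            "circadian_coefficients": self.circadian.coefficients.tolist(),
            "history_x": float(self.history.x),
            "history_n_h": int(self.history.n_h),
            "history_offsets": self.history.offsets.tolist(),
            "tau": float(self.noise.tau),
            "sigma_innov2": float(self.noise.sigma_innov2),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RepertoireParams":
        return cls(
            p_star=d["p_star"],
            circadian=CircadianBasis(
                np.asarray(d["circadian_nodes"]),
                np.asarray(d["circadian_coefficients"]),
            ),
            history=HistoryModel(
                d["history_x"], d["history_n_h"], np.asarray(d["history_offsets"])
            ),
            noise=ColoredNoiseParams(d["tau"], d["sigma_innov2"]),
        )


def equal_count_nodes(traj: PitchTrajectory, n_d: int = 6) -> np.ndarray:
    """Equal-count circadian nodes H_1..H_{N_D+1} pooled across days.

    Each daytime bin [H_j, H_{j+1}) receives an equal (+-1) number of
    renditions across all days pooled, which yields narrower bins where the
    subject sings more (typically the morning). The last node sits just
    above the latest observed h so every rendition falls inside the span.
    """
    if n_d < 1:
        raise ValueError("need at least one circadian bin")
    h = np.sort(traj.h)
    if h.size < n_d:
        raise ValueError(f"fewer renditions ({h.size}) than circadian bins ({n_d})")
    # exact equal-count cuts: bin j receives the sorted renditions with
    # index in [j*N//n_d, (j+1)*N//n_d), so counts differ by at most 1;
    # ties broken by rendition order through the stable sort
    idx = (np.arange(n_d + 1) * h.size) // n_d
    idx[-1] = h.size - 1
    nodes = h[idx].astype(float)
    nodes[-1] = np.nextafter(h[-1], 2.0)  # just above the latest h
    nodes[-1] = min(nodes[-1], np.nextafter(1.0, 0.0))
    # guard against duplicate cuts in heavily tied data
    for j in range(1, nodes.size):
        if nodes[j] <= nodes[j - 1]:
            nodes[j] = np.nextafter(nodes[j - 1], 2.0)
    return nodes


def circadian_weights(h, nodes: np.ndarray) -> np.ndarray:
    """Piecewise-linear hat weights theta_j(h) over the circadian nodes.

    Inside the node span the weights are a partition of unity with at most
    two nonzero entries; outside [H_1, H_{N_D+1}) all weights are zero.
    Accepts a scalar or an array of h; returns shape (..., N_D + 1).
    """
    h = np.asarray(h, dtype=float)
    scalar = h.ndim == 0
    hv = np.atleast_1d(h)
    nn = np.asarray(nodes, dtype=float)
    w = np.zeros((hv.size, nn.size))
    inside = (hv >= nn[0]) & (hv < nn[-1])
    if inside.any():
        j = np.searchsorted(nn, hv[inside], side="right") - 1  # bin index
        frac = (hv[inside] - nn[j]) / (nn[j + 1] - nn[j])
        rows = np.flatnonzero(inside)
        w[rows, j] = 1.0 - frac
        w[rows, j + 1] = frac
    return w[0] if scalar else w


def evaluate_repertoire(
    params: RepertoireParams,
    traj: PitchTrajectory,
    colored_path: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Evaluate the repertoire components on a trajectory.

    Returns a dict with per-rendition arrays ``d`` (circadian), ``o``
    (history offset), ``total`` = p* + d + o (+ c if ``colored_path``
    given), and ``c`` when supplied. Renditions whose h falls outside the
    node span contribute 0 circadian offset.
    """
    d = params.circadian.evaluate(traj.h)
    o = params.history.evaluate(traj)
    total = params.p_star + d + o
    out = {"d": d, "o": o, "total": total}
    if colored_path is not None:
        c = np.asarray(colored_path, dtype=float)
        if c.shape != d.shape:
            raise ValueError("colored_path length mismatch")
        out["c"] = c
        out["total"] = total + c
    return out


def sample_colored_noise(
    params: ColoredNoiseParams, T: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Sample c_1..c_T from c_t = (1 - tau) c_{t-1} + innovation, c_0 = 0."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    innov = rng.normal(0.0, np.sqrt(params.sigma_innov2), size=T)
    a = 1.0 - params.tau
    if a == 0.0:
        return innov
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -a], innov)


def select_history_model(
    traj: PitchTrajectory,
    candidate_x=(1.0, 2.0, 3.0, 5.0, 10.0, 60.0),
    candidate_n_h=(3, 4, 5, 6),
    fitter=None,
    **fit_kwargs,
):
    """Grid-search the history horizon x and quantization N_h by BIC.

    ``fitter(traj, x=..., n_h=...)`` must return an object with attributes
    ``loglik`` and ``n_free_params`` (the baseline fit from
    :mod:`latentrl.decompose` does). Returns ``(x*, n_h*, table)`` where
    the table is a list of dicts; failed candidates are recorded with
    ``bic = nan`` and excluded from the argmin.
    """
    import warnings

    from .kalman import bic as _bic

    if fitter is None:
        from .decompose import fit_baseline

        def fitter(tr, x, n_h):
            return fit_baseline(tr, x=x, n_h=n_h, **fit_kwargs)

    table = []
    for x in candidate_x:
        for n_h in candidate_n_h:
            row = {"x": x, "n_h": n_h, "bic": np.nan, "loglik": np.nan}
            try:
                fit = fitter(traj, x=x, n_h=n_h)
                row["loglik"] = fit.loglik
                row["bic"] = _bic(fit.loglik, fit.n_free_params, len(traj))
            except Exception as exc:  # noqa: BLE001 -- candidate failures are data
                warnings.warn(f"history candidate (x={x}, n_h={n_h}) failed: {exc}")
            table.append(row)
    valid = [r for r in table if np.isfinite(r["bic"])]
    if not valid:
        raise RuntimeError("all history-model candidates failed")
    best = min(valid, key=lambda r: r["bic"])
    return best["x"], best["n_h"], table
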