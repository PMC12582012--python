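"""Gaussian-emission hidden Markov models for intensity trajectories.

One model is fitted *pooled* across all trajectories of an experimental
condition (the per-molecule chemistry is identical, so pooling a few hundred
traces is what gives the transition matrix statistical power).  Fitting is
maximum likelihood via Baum-Welch with scaled forward-backward recursions,
vectorised over traces of equal length; decoding is Viterbi with deterministic
tie-breaking toward the lower state index; the number of states is chosen by
the Bayesian Information Criterion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .simulate import IntensityTrace

__all__ = [
    "HmmModel",
    "HmmOptions",
    "FitResult",
    "DecodedPath",
    "fit_hmm",
    "select_state_number",
    "bic_score",
    "log_likelihood",
    "viterbi_decode",
    "decode_ensemble",
    "label_states",
]

_LOG2PI = math.log(2.0 * math.pi)
_PROB_FLOOR = 1e-12


@dataclass
class HmmModel:
    """K hidden states with Gaussian emissions and a per-frame transition matrix."""

    initial_probs: np.ndarray
    trans: np.ndarray
    emission_means: np.ndarray
    emission_sds: np.ndarray
    state_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.emission_means = np.asarray(self.emission_means, dtype=float)
        self.emission_sds = np.asarray(self.emission_sds, dtype=float)
        K = len(self.initial_probs)
        if self.trans.shape != (K, K):
            raise ValueError("trans must be K x K")
        if len(self.emission_means) != K or len(self.emission_sds) != K:
            raise ValueError("emission parameter lengths must equal K")
        if abs(self.initial_probs.sum() - 1.0) > 1e-9:
            raise ValueError("initial_probs must sum to 1")
        if np.any(np.abs(self.trans.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.emission_sds <= 0):
            raise ValueError("emission sds must be > 0")

    @property
    def K(self) -> int:
        return len(self.initial_probs)

    def label_of(self, index: int) -> str:
        if self.state_labels is None:
            return str(index)
        return self.state_labels[index]


@dataclass
class HmmOptions:
    """Baum-Welch controls.

    ``tol`` is the relative log-likelihood change that stops EM; restarts
    perturb the quantile initialisation and the best final likelihood wins.
    """

    tol: float = 1e-6
    max_iter: int = 500
    init_seed: int = 0
    n_restarts: int = 3
    sd_floor_frac: float = 1e-6


@dataclass
class FitResult:
    model: HmmModel
    log_likelihood: float
    n_iterations: int
    converged: bool
    bic: float
    loglik_trace: list[float] = field(default_factory=list)


@dataclass
class DecodedPath:
    """Viterbi path and forward-backward posterior for one trace."""

    trace_id: str
    states: np.ndarray  # (T,) int state indices
    posterior: np.ndarray  # (T, K)


# ---------------------------------------------------------------------------
# data packing


def _as_arrays(traces, min_len: int = 2) -> tuple[list[np.ndarray], list[str]]:
    xs: list[np.ndarray] = []
    ids: list[str] = []
    for i, tr in enumerate(traces):
        if isinstance(tr, IntensityTrace):
            x = np.asarray(tr.intensities, dtype=float)
            ids.append(tr.trace_id)
        else:
            x = np.asarray(tr, dtype=float)
            ids.append(str(i))
        if x.ndim != 1 or len(x) < min_len:
            raise ValueError(f"each trace must be a 1-D array with >= {min_len} frames")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"trace {ids[-1]} contains non-finite intensities")
        xs.append(x)
    if not xs:
        raise ValueError("need at least one trace")
    return xs, ids


def _group_by_length(xs: list[np.ndarray]) -> dict[int, tuple[np.ndarray, list[int]]]:
    groups: dict[int, list[int]] = {}
    for i, x in enumerate(xs):
        groups.setdefault(len(x), []).append(i)
    return {
        T: (np.stack([xs[i] for i in idx]), idx) for T, idx in sorted(groups.items())
    }


def _log_emission(X: np.ndarray, model: HmmModel) -> np.ndarray:
    """(n, T) observations -> (n, T, K) Gaussian log-densities."""
    mu = model.emission_means
    sd = model.emission_sds
    z = (X[..., None] - mu) / sd
    return -0.5 * (z * z) - np.log(sd) - 0.5 * _LOG2PI


# ---------------------------------------------------------------------------
# forward-backward (scaled, vectorised over traces)


def _forward(X: np.ndarray, model: HmmModel):
    """Scaled forward pass.

    Returns per-trace log-likelihoods plus the scaled alphas, scale factors
    and shifted emission likelihoods needed by the backward pass.
    """
    n, T = X.shape
    K = model.K
    logB = _log_emission(X, model)
    m = logB.max(axis=2)
    B = np.exp(logB - m[..., None])  # max entry 1 per frame: no underflow
    alpha = np.empty((n, T, K))
    c = np.empty((n, T))
    a = model.initial_probs * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    A = model.trans
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    ll = np.log(c).sum(axis=1) + m.sum(axis=1)
    return ll, alpha, c, B


def _posteriors(X: np.ndarray, model: HmmModel):
    """Per-frame state posteriors gamma (n, T, K) and per-trace log-likelihoods."""
    ll, alpha, c, B = _forward(X, model)
    n, T, K = alpha.shape
    A = model.trans
    gamma = np.empty_like(alpha)
    beta = np.ones((n, K))
    gamma[:, T - 1] = alpha[:, T - 1]
    for t in range(T - 2, -1, -1):
        w = (B[:, t + 1] * beta) / c[:, t + 1, None]
        beta = w @ A.T
        gamma[:, t] = alpha[:, t] * beta
    return gamma, ll


def log_likelihood(model: HmmModel, traces) -> float:
    """Total forward log-likelihood of *traces* under *model*."""
    xs, _ = _as_arrays(traces, min_len=1)
    total = 0.0
    for _, (X, _) in _group_by_length(xs).items():
        ll, *_ = _forward(X, model)
        total += ll.sum()
    return float(total)


# ---------------------------------------------------------------------------
# Baum-Welch


def _init_model(
    pooled: np.ndarray, K: int, rng: np.random.Generator, restart: int
) -> HmmModel:
    """Initial parameters for EM restart number *restart*.

    Restart 0 spreads the emission means evenly over the robust data range
    (bin midpoints between the 0.5th and 99.5th percentiles), which finds
    minority states even when one level dominates the pooled histogram;
    restart 1 places them at occupancy-weighted quantiles; further restarts
    perturb these two alternately with seeded noise.
    """
    sd = pooled.std()
    if sd == 0:
        sd = 1.0
    if restart % 2 == 0:
        lo, hi = np.percentile(pooled, [0.5, 99.5])
        if hi <= lo:
            lo, hi = lo - 1.0, hi + 1.0
        means = lo + (np.arange(K) + 0.5) * (hi - lo) / K
    else:
        qs = np.array([0.5]) if K == 1 else np.linspace(0.1, 0.9, K)
        means = np.quantile(pooled, qs)
    if restart >= 2:
        means = means + rng.normal(0.0, sd / 4.0, size=K)
    sds = np.full(K, sd / 2.0)
    trans = np.full((K, K), 0.05 / max(K - 1, 1))
    np.fill_diagonal(trans, 0.95 if K > 1 else 1.0)
    trans /= trans.sum(axis=1, keepdims=True)
    pi = np.full(K, 1.0 / K)
    return HmmModel(pi, trans, means, sds)


def _em_step(groups, model: HmmModel, sd_floor: float):
    """One EM iteration; returns (loglik of current model, updated model)."""
    K = model.K
    ll_total = 0.0
    n_traces = 0
    pi_acc = np.zeros(K)
    xi_acc = np.zeros((K, K))
    g_acc = np.zeros(K)
    gx_acc = np.zeros(K)
    gxx_acc = np.zeros(K)
    A = model.trans
    for T, (X, _) in groups.items():
        ll, alpha, c, B = _forward(X, model)
        ll_total += ll.sum()
        n = X.shape[0]
        n_traces += n
        beta = np.ones((n, K))
        g = alpha[:, T - 1]
        g_acc += g.sum(axis=0)
        gx_acc += g.T @ X[:, T - 1]
        gxx_acc += g.T @ (X[:, T - 1] ** 2)
        for t in range(T - 2, -1, -1):
            w = (B[:, t + 1] * beta) / c[:, t + 1, None]
            xi_acc += (alpha[:, t].T @ w) * A
            beta = w @ A.T
            g = alpha[:, t] * beta
            g_acc += g.sum(axis=0)
            gx_acc += g.T @ X[:, t]
            gxx_acc += g.T @ (X[:, t] ** 2)
        pi_acc += g.sum(axis=0)  # g is gamma at t = 0 after the loop

    pi = pi_acc / n_traces
    pi = np.clip(pi, _PROB_FLOOR, None)
    pi /= pi.sum()
    row = xi_acc.sum(axis=1, keepdims=True)
    trans = np.where(row > 0, xi_acc / np.maximum(row, 1e-300), A)
    trans = np.clip(trans, _PROB_FLOOR, None)
    trans /= trans.sum(axis=1, keepdims=True)
    occupied = g_acc > 0
    means = np.where(occupied, gx_acc / np.maximum(g_acc, 1e-300), model.emission_means)
    var = gxx_acc / np.maximum(g_acc, 1e-300) - means**2
    sds = np.sqrt(np.maximum(var, sd_floor**2))
    sds = np.where(occupied, sds, model.emission_sds)
    new = HmmModel(pi, trans, means, sds, state_labels=model.state_labels)
    return ll_total, new


def _run_em(groups, model: HmmModel, options: HmmOptions, sd_floor: float):
    loglik_trace: list[float] = []
    converged = False
    ll_prev = -np.inf
    for it in range(options.max_iter):
        ll, model = _em_step(groups, model, sd_floor)
        if loglik_trace:
            # EM guarantees monotone likelihood; tolerate float round-off only.
            if ll < ll_prev - 1e-8 * (abs(ll_prev) + 1.0):
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it}: {ll_prev} -> {ll}"
                )
        loglik_trace.append(ll)
        if it > 0 and abs(ll - ll_prev) < options.tol * (abs(ll_prev) + 1.0):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    # Log-likelihood of the final parameters (one extra forward pass).
    ll_final = 0.0
    for _, (X, _) in groups.items():
        ll, *_ = _forward(X, model)
        ll_final += ll.sum()
    loglik_trace.append(ll_final)
    return model, ll_final, len(loglik_trace) - 1, converged, loglik_trace


def n_free_parameters(K: int) -> int:
    """Free parameters of a K-state Gaussian HMM: initial distribution,
    transition matrix rows, and mean + sd per state."""
    return (K - 1) + K * (K - 1) + 2 * K


def bic_score(log_likelihood: float, K: int, n_obs: int) -> float:
    return -2.0 * log_likelihood + n_free_parameters(K) * math.log(n_obs)


def fit_hmm(traces, K: int, options: HmmOptions | None = None) -> FitResult:
    """Fit one pooled K-state model to an ensemble by Baum-Welch.

    Runs ``options.n_restarts`` EM runs from a quantile initialisation (the
    first unperturbed, the rest with seeded mean perturbations) and keeps the
    highest final log-likelihood.
    """
    options = options or HmmOptions()
    if K < 1:
        raise ValueError("K must be >= 1")
    xs, _ = _as_arrays(traces)
    pooled = np.concatenate(xs)
    if K > len(np.unique(pooled)):
        raise ValueError(
            f"degenerate fit: K={K} exceeds the {len(np.unique(pooled))} distinct "
            "intensity values in the data"
        )
    groups = _group_by_length(xs)
    n_obs = sum(len(x) for x in xs)
    sd_floor = max(options.sd_floor_frac * pooled.std(), 1e-12)
    rng = np.random.Generator(np.random.PCG64(options.init_seed))

    best: FitResult | None = None
    for r in range(max(options.n_restarts, 1)):
        model0 = _init_model(pooled, K, rng, restart=r)
        model, ll, n_iter, converged, trace = _run_em(groups, model0, options, sd_floor)
        result = FitResult(
            model=model,
            log_likelihood=ll,
            n_iterations=n_iter,
            converged=converged,
            bic=bic_score(ll, K, n_obs),
            loglik_trace=trace,
        )
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    assert best is not None
    return best


def select_state_number(
    traces, K_range=range(1, 6), options: HmmOptions | None = None
) -> tuple[int, list[FitResult]]:
    """Fit every K in *K_range* and return the BIC-minimising state count."""
    ks = list(K_range)
    if not ks:
        raise ValueError("K_range is empty")
    results: list[FitResult] = []
    fitted_ks: list[int] = []
    for K in ks:
        try:
            results.append(fit_hmm(traces, K, options))
            fitted_ks.append(K)
        except Exception as exc:  # noqa: BLE001 - skip, warn, keep going
            warnings.warn(f"HMM fit failed for K={K}: {exc}", stacklevel=2)
    if not results:
        raise RuntimeError("all HMM fits failed over the requested K range")
    best = int(np.argmin([r.bic for r in results]))
    return fitted_ks[best], results


# ---------------------------------------------------------------------------
# decoding


def _viterbi_group(X: np.ndarray, model: HmmModel) -> np.ndarray:
    n, T = X.shape
    K = model.K
    logB = _log_emission(X, model)
    logA = np.log(np.clip(model.trans, _PROB_FLOOR, None))
    logpi = np.log(np.clip(model.initial_probs, _PROB_FLOOR, None))
    delta = logpi + logB[:, 0]  # (n, K)
    psi = np.empty((n, T, K), dtype=np.int32)
    for t in range(1, T):
        cand = delta[:, :, None] + logA[None]  # (n, from, to)
        # argmax over the source axis; np.argmax returns the first (lowest
        # index) maximiser, which is the documented tie-break.
        psi[:, t] = np.argmax(cand, axis=1)
        delta = np.take_along_axis(cand, psi[:, t][:, None, :], axis=1)[:, 0] + logB[:, t]
    states = np.empty((n, T), dtype=np.int32)
    states[:, T - 1] = np.argmax(delta, axis=1)
    for t in range(T - 2, -1, -1):
        states[:, t] = np.take_along_axis(
            psi[:, t + 1], states[:, t + 1][:, None], axis=1
        )[:, 0]
    return states


def decode_ensemble(model: HmmModel, traces) -> list[DecodedPath]:
    """Viterbi-decode every trace (with forward-backward posteriors attached)."""
    xs, ids = _as_arrays(traces, min_len=1)
    out: list[DecodedPath | None] = [None] * len(xs)
    for _, (X, idx) in _group_by_length(xs).items():
        states = _viterbi_group(X, model)
        gamma, _ = _posteriors(X, model)
        for row, i in enumerate(idx):
            out[i] = DecodedPath(ids[i], states[row].copy(), gamma[row].copy())
    return [d for d in out if d is not None]


def viterbi_decode(model: HmmModel, trace) -> DecodedPath:
    """Maximum-probability state sequence for one trace."""
    return decode_ensemble(model, [trace])[0]


# ---------------------------------------------------------------------------
# labelling


def label_states(model: HmmModel, convention=("S", "IM1", "IM2")) -> HmmModel:
    """Attach species labels to hidden states by emission-mean rank.

    ``convention`` lists species from brightest to dimmest; the default maps
    the highest mean to S and the lowest to IM2.  Which chemical species is
    brightest is an assay convention, hence configurable (pass the reversed
    tuple to flip it).
    """
    convention = tuple(convention)
    if model.K != len(convention):
        raise ValueError(
            f"convention names {len(convention)} states but the model has {model.K}"
        )
    order = np.argsort(-model.emission_means, kind="stable")
    labels = {int(order[rank]): convention[rank] for rank in range(model.K)}
    return replace(model, state_labels=labels)
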