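"""Pooled Gaussian HMM: oracle equivalence, EM behaviour, decoding, labelling."""

import itertools

import numpy as np
import pytest
from scipy import stats

import tracekin as tk
from tracekin.hmm import HmmModel, HmmOptions, bic_score, n_free_parameters


def _random_model(K, rng):
    pi = rng.dirichlet(np.ones(K))
    trans = rng.dirichlet(np.ones(K), size=K)
    means = np.sort(rng.uniform(0, 1, K)) * 2
    sds = rng.uniform(0.05, 0.3, K)
    return HmmModel(pi, trans, means, sds)


def _brute_force(model, x):
    """Exhaustive sum over all K^T hidden sequences; also the MAP sequence.

    Ties in the MAP search cannot occur for generic float data; sequences are
    enumerated in lexicographic order so an exact tie would keep the lower
    state indices, matching the documented Viterbi tie-break.
    """
    K, T = model.K, len(x)
    best_seq, best_lp, total = None, -np.inf, -np.inf
    for seq in itertools.product(range(K), repeat=T):
        lp = np.log(model.initial_probs[seq[0]])
        lp += stats.norm.logpdf(x[0], model.emission_means[seq[0]], model.emission_sds[seq[0]])
        for a, b, xt in zip(seq, seq[1:], x[1:]):
            lp += np.log(model.trans[a, b])
            lp += stats.norm.logpdf(xt, model.emission_means[b], model.emission_sds[b])
        total = np.logaddexp(total, lp)
        if lp > best_lp:
            best_lp, best_seq = lp, seq
    return total, np.array(best_seq)


@pytest.mark.parametrize("K,T", [(2, 2), (2, 5), (2, 8), (3, 4), (3, 7)])
def test_forward_and_viterbi_match_exhaustive_enumeration(K, T, rng):
    """Oracle equivalence on all short traces: likelihood and MAP path."""
    for rep in range(3):
        model = _random_model(K, rng)
        x = rng.normal(1.0, 0.7, size=T)
        ll_bf, path_bf = _brute_force(model, x)
        assert tk.log_likelihood(model, [x]) == pytest.approx(ll_bf, rel=1e-9)
        decoded = tk.viterbi_decode(model, x)
        assert np.array_equal(decoded.states, path_bf)
        assert np.allclose(decoded.posterior.sum(axis=1), 1.0, atol=1e-9)


def test_forward_likelihood_matches_hmmlearn(rng):
    """Independent cross-check of the forward recursion against hmmlearn."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    model = _random_model(3, rng)
    xs = [rng.normal(0.8, 0.5, size=60) for _ in range(4)]
    gh = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
    gh.startprob_ = model.initial_probs
    gh.transmat_ = model.trans
    gh.means_ = model.emission_means[:, None]
    gh.covars_ = (model.emission_sds**2)[:, None]
    ref = sum(gh.score(x[:, None]) for x in xs)
    assert tk.log_likelihood(model, xs) == pytest.approx(ref, rel=1e-9)


def test_k1_fit_reduces_to_pooled_gaussian(rng):
    xs = [rng.normal(0.5, 0.2, size=80) for _ in range(3)]
    res = tk.fit_hmm(xs, 1, HmmOptions(init_seed=0, n_restarts=1))
    pooled = np.concatenate(xs)
    assert res.model.emission_means[0] == pytest.approx(pooled.mean(), abs=1e-9)
    assert res.model.emission_sds[0] == pytest.approx(pooled.std(), rel=1e-6)
    iid = stats.norm.logpdf(pooled, pooled.mean(), pooled.std()).sum()
    assert res.log_likelihood == pytest.approx(iid, rel=1e-9)


def test_em_loglikelihood_is_monotone(small_fit):
    trace = small_fit["fit"].loglik_trace
    assert len(trace) >= 2
    diffs = np.diff(trace)
    assert np.all(diffs >= -1e-6 * (np.abs(trace[:-1]) + 1))


def test_fit_recovers_emission_parameters(small_fit):
    means = np.sort(small_fit["fit"].model.emission_means)
    assert np.allclose(means, [0.25, 0.60, 1.00], atol=0.02)
    assert np.allclose(small_fit["fit"].model.emission_sds, 0.08, atol=0.02)


def test_model_rows_normalise(small_fit):
    m = small_fit["fit"].model
    assert np.allclose(m.trans.sum(axis=1), 1.0, atol=1e-9)
    assert m.initial_probs.sum() == pytest.approx(1.0, abs=1e-9)


def test_self_transitions_imply_generating_exit_rates(small_fit):
    """-ln(trans[i,i])/dt within 20% of the generating total exit rates."""
    m = small_fit["model"]
    dt = small_fit["cfg"].frame_period
    true_exit = {"S": 0.35625, "IM1": 0.41, "IM2": 0.22}
    for i in range(3):
        implied = -np.log(m.trans[i, i]) / dt
        expected = true_exit[m.label_of(i)]
        assert abs(implied - expected) / expected < 0.20


def test_fit_is_invariant_to_trace_order(small_ensemble):
    traces, _ = small_ensemble
    opts = HmmOptions(init_seed=1)
    a = tk.fit_hmm(traces, 3, opts)
    b = tk.fit_hmm(list(reversed(traces)), 3, opts)
    assert a.log_likelihood == pytest.approx(b.log_likelihood, rel=1e-8)
    assert np.allclose(
        np.sort(a.model.emission_means), np.sort(b.model.emission_means), rtol=1e-6
    )


def test_decoding_accuracy_against_ground_truth(small_fit):
    traces = small_fit["traces"]
    decoded = small_fit["decoded"]
    lab = small_fit["label_map"]
    hits = total = 0
    for tr, d in zip(traces, decoded):
        true = tr.truth.state_at_frames(tr.times)
        est = [lab[int(s)] for s in d.states]
        hits += sum(a == b for a, b in zip(true, est))
        total += len(true)
    assert hits / total > 0.95


def test_noiseless_trace_decodes_exactly():
    model = HmmModel(
        np.array([0.5, 0.5]),
        np.array([[0.95, 0.05], [0.05, 0.95]]),
        np.array([1.0, 0.6]),
        np.array([1e-6, 1e-6]),
    )
    x = np.array([1.0, 1.0, 0.6, 0.6, 0.6, 1.0])
    decoded = tk.viterbi_decode(model, x)
    assert decoded.states.tolist() == [0, 0, 1, 1, 1, 0]


def test_single_frame_trace_decodes_to_map_state():
    model = HmmModel(
        np.array([0.9, 0.1]),
        np.array([[0.5, 0.5], [0.5, 0.5]]),
        np.array([0.0, 1.0]),
        np.array([0.5, 0.5]),
    )
    # Emission slightly favours state 1, but the prior favours state 0.
    d = tk.viterbi_decode(model, np.array([0.6]))
    post = model.initial_probs * stats.norm.pdf(0.6, model.emission_means, model.emission_sds)
    assert d.states[0] == int(np.argmax(post))


def test_bic_selects_one_state_for_structureless_data(rng):
    xs = [rng.normal(0.5, 0.1, size=200) for _ in range(5)]
    k, results = tk.select_state_number(xs, range(1, 4), HmmOptions(init_seed=2))
    assert k == 1
    for r in results:
        K = r.model.K
        n_obs = sum(len(x) for x in xs)
        assert r.bic == pytest.approx(bic_score(r.log_likelihood, K, n_obs))
        assert n_free_parameters(K) == (K - 1) + K * (K - 1) + 2 * K


def test_degenerate_k_is_rejected():
    x = np.array([1.0, 1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        tk.fit_hmm([x], 2)


def test_nonfinite_intensities_are_rejected():
    with pytest.raises(ValueError):
        tk.fit_hmm([np.array([1.0, np.nan, 0.5])], 1)


def test_label_states_by_mean_rank():
    model = HmmModel(
        np.full(3, 1 / 3), np.full((3, 3), 1 / 3), np.array([1.0, 0.6, 0.25]), np.full(3, 0.1)
    )
    lab = tk.label_states(model)
    assert [lab.label_of(i) for i in range(3)] == ["S", "IM1", "IM2"]
    rev = tk.label_states(model, ("IM2", "IM1", "S"))
    assert [rev.label_of(i) for i in range(3)] == ["IM2", "IM1", "S"]


def test_label_states_is_permutation_invariant():
    perm = HmmModel(
        np.full(3, 1 / 3), np.full((3, 3), 1 / 3), np.array([0.25, 1.0, 0.6]), np.full(3, 0.1)
    )
    lab = tk.label_states(perm)
    assert {i: lab.label_of(i) for i in range(3)} == {0: "IM2", 1: "S", 2: "IM1"}


def test_label_states_requires_matching_k():
    model = HmmModel(np.array([1.0]), np.array([[1.0]]), np.array([0.5]), np.array([0.1]))
    with pytest.raises(ValueError):
        tk.label_states(model)
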