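"""Transition density plots, group comparisons and fold changes."""

import numpy as np
import pytest

import tracekin as tk
from tracekin.hmm import DecodedPath
from tracekin.tdp import significance_stars


def _decoded(states):
    states = np.asarray(states)
    return DecodedPath("t", states, np.ones((len(states), 1)))


def test_single_transition_lands_in_the_right_bin():
    x = np.array([1.0] * 5 + [0.6] * 5)
    d = _decoded([0] * 5 + [1] * 5)
    tdp = tk.build_tdp([x], [d], n_bins=10)
    assert tdp.counts.sum() == 1
    i = np.searchsorted(tdp.bin_edges, 1.0) - 1
    j = np.searchsorted(tdp.bin_edges, 0.6) - 1
    assert tdp.counts[i, j] == 1
    assert np.allclose(tdp.transitions, [[1.0, 0.6]])


def test_tdp_counts_equal_number_of_transitions(small_fit):
    tdp = tk.build_tdp(small_fit["traces"], small_fit["decoded"])
    n_trans = sum(
        int(np.sum(d.states[1:] != d.states[:-1])) for d in small_fit["decoded"]
    )
    assert tdp.counts.sum() == n_trans == tdp.n_transitions


def test_tdp_shows_four_clusters_and_no_direct_s_im2(small_fit):
    """Sequential scheme: S<->IM1 and IM1<->IM2 clusters dominate; direct
    S<->IM2 coordinates are rare."""
    means = {"S": 1.0, "IM1": 0.6, "IM2": 0.25}
    lab = small_fit["label_map"]
    coords = tk.build_tdp(small_fit["traces"], small_fit["decoded"]).transitions

    def nearest(v):
        return min(means, key=lambda s: abs(means[s] - v))

    kinds = {}
    for before, after in coords:
        kinds.setdefault((nearest(before), nearest(after)), 0)
        kinds[(nearest(before), nearest(after))] += 1
    total = len(coords)
    for pair in [("S", "IM1"), ("IM1", "S"), ("IM1", "IM2"), ("IM2", "IM1")]:
        assert kinds.get(pair, 0) / total > 0.10
    direct = kinds.get(("S", "IM2"), 0) + kinds.get(("IM2", "S"), 0)
    assert direct / total < 0.02


def test_noiseless_tdp_centroids_equal_emission_pairs():
    x = np.array([1.0] * 4 + [0.6] * 4 + [0.25] * 4 + [0.6] * 4)
    d = _decoded([0] * 4 + [1] * 4 + [2] * 4 + [1] * 4)
    tdp = tk.build_tdp([x], [d])
    assert np.allclose(
        tdp.transitions, [[1.0, 0.6], [0.6, 0.25], [0.25, 0.6]], atol=1e-12
    )


def test_empty_decoding_warns_and_returns_empty_density():
    x = np.array([1.0, 1.0, 1.0])
    with pytest.warns(UserWarning):
        tdp = tk.build_tdp([x], [_decoded([0, 0, 0])])
    assert tdp.counts.sum() == 0


def test_welch_identical_samples():
    res = tk.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == pytest.approx(1.0)
    assert res.effect == pytest.approx(0.0)
    assert res.ci_low <= res.effect <= res.ci_high


def test_welch_constant_identical_samples():
    res = tk.compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert res.p_value == 1.0 and res.effect == 0.0


def test_welch_detects_extreme_separation(rng):
    a = rng.normal(0, 1, 100)
    b = rng.normal(5, 1, 100)
    res = tk.compare_groups(a, b)
    assert res.p_value < 1e-10
    assert res.ci_low > 4.0


def test_welch_statistic_matches_textbook_formula():
    a = [1.0, 2.0, 3.0]
    b = [2.0, 4.0, 9.0]
    res = tk.compare_groups(a, b)
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1) / 3, np.var(b, ddof=1) / 3
    t = (mb - ma) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
    assert res.statistic == pytest.approx(t)
    assert res.extra["df"] == pytest.approx(df)


def test_mannwhitney_option():
    res = tk.compare_groups([1, 2, 3, 4], [10, 11, 12, 13], method="mannwhitney")
    assert res.method == "mannwhitney"
    assert res.p_value < 0.05


def test_degenerate_variance_falls_back_to_rank_test():
    with pytest.warns(UserWarning):
        res = tk.compare_groups([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])
    assert res.method == "mannwhitney"


def test_fold_change_identity():
    vals = np.linspace(0.5, 1.5, 30)
    res = tk.fold_change(vals, vals, seed=11)
    assert res.effect == pytest.approx(1.0)
    assert res.ci_low <= 1.0 <= res.ci_high


def test_fold_change_detects_doubling(rng):
    a = rng.normal(1.0, 0.1, 100)
    res = tk.fold_change(a, 2 * a, seed=11)
    assert res.effect == pytest.approx(2.0, rel=0.05)
    assert res.ci_low > 1.0


def test_fold_change_seeded_reproducibility(rng):
    a = rng.normal(1.0, 0.2, 50)
    b = rng.normal(1.6, 0.2, 50)
    r1 = tk.fold_change(a, b, seed=42)
    r2 = tk.fold_change(a, b, seed=42)
    assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


def test_fold_change_zero_denominator():
    with pytest.raises(ValueError):
        tk.fold_change([0.0, 0.0], [1.0, 1.0])


def test_bootstrap_ci_coverage(rng):
    """Percentile-bootstrap CIs cover the true mean ratio >= 90% of the time.

    Cheap stand-in for trace-level metrics: per-trace occupancy-like fractions
    drawn from Beta distributions with known mean ratio 1.5.
    """
    true_ratio = (0.3) / (0.2)
    hits = 0
    reps = 100
    for _ in range(reps):
        a = rng.beta(2.0, 8.0, size=80)  # mean 0.2
        b = rng.beta(3.0, 7.0, size=80)  # mean 0.3
        res = tk.fold_change(a, b, n_boot=200, seed=int(rng.integers(2**31)))
        hits += res.ci_low <= true_ratio <= res.ci_high
    assert hits / reps >= 0.90


def test_significance_star_convention():
    assert significance_stars(0.5) == "ns"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.005) == "**"
    assert significance_stars(1e-5) == "****"
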