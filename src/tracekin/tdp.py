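"""Transition density plots and between-group statistics.

The transition density plot (TDP) is the field's standard visual check of
which state pairs interconvert: every decoded transition contributes one
point at (mean intensity of the dwell before, mean intensity of the dwell
after).  Dwell-mean coordinates (rather than single transition frames) make
the clusters robust to per-frame noise.  Group comparisons default to Welch's
unequal-variance t-test, with a rank (Mann-Whitney) alternative; fold changes
come with trace-level percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TransitionDensity",
    "ComparisonResult",
    "build_tdp",
    "compare_groups",
    "fold_change",
    "plot_tdp",
]


@dataclass
class TransitionDensity:
    """2-D histogram of (intensity before, intensity after) per transition."""

    bin_edges: np.ndarray  # shared by both axes
    counts: np.ndarray  # (n_bins, n_bins); [i, j] = before-bin i, after-bin j
    transitions: np.ndarray  # (N, 2) raw coordinate pairs

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    effect: float
    ci_low: float
    ci_high: float
    method: str
    extra: dict = field(default_factory=dict)


def _dwell_mean_pairs(intensities: np.ndarray, states: np.ndarray) -> list[tuple[float, float]]:
    """(before, after) dwell-mean intensity for every state change in one trace."""
    states = np.asarray(states)
    x = np.asarray(intensities, dtype=float)
    change = np.flatnonzero(states[1:] != states[:-1]) + 1  # run starts
    bounds = np.concatenate([[0], change, [len(states)]])
    means = [float(x[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]
    return [(means[i], means[i + 1]) for i in range(len(means) - 1)]


def build_tdp(traces, decoded_paths, n_bins: int = 50) -> TransitionDensity:
    """Transition density plot over a decoded ensemble.

    *traces* and *decoded_paths* are matched by position.  Axes share one set
    of bin edges spanning both coordinates symmetrically.
    """
    pairs: list[tuple[float, float]] = []
    for tr, d in zip(traces, decoded_paths):
        x = tr.intensities if hasattr(tr, "intensities") else np.asarray(tr, dtype=float)
        pairs.extend(_dwell_mean_pairs(x, d.states))
    coords = np.array(pairs, dtype=float).reshape(-1, 2)
    if len(coords) == 0:
        warnings.warn("no transitions in the decoded ensemble; TDP is empty", stacklevel=2)
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        return TransitionDensity(edges, np.zeros((n_bins, n_bins)), coords)
    lo = coords.min()
    hi = coords.max()
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    pad = 1e-9 * (hi - lo)
    edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    counts, _, _ = np.histogram2d(coords[:, 0], coords[:, 1], bins=[edges, edges])
    return TransitionDensity(edges, counts, coords)


def compare_groups(sample_a, sample_b, method: str = "welch") -> ComparisonResult:
    """Two-sample location test: Welch's t (default) or Mann-Whitney U.

    The effect is the mean difference b - a with a 95% CI (Welch df).  When
    both samples are degenerate (zero variance) the t statistic is undefined
    and the comparison falls back to the rank test with a warning.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both samples need >= 3 values")
    effect = float(b.mean() - a.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if method == "welch" and (va + vb) == 0:
        if effect == 0.0:
            return ComparisonResult(0.0, 1.0, 0.0, 0.0, 0.0, "welch")
        warnings.warn("degenerate variances; falling back to rank test", stacklevel=2)
        method = "mannwhitney"
    if method == "welch":
        res = stats.ttest_ind(b, a, equal_var=False)
        se = math.sqrt(va / len(a) + vb / len(b))
        df = se**4 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        tcrit = stats.t.ppf(0.975, df)
        return ComparisonResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            effect=effect,
            ci_low=effect - tcrit * se,
            ci_high=effect + tcrit * se,
            method="welch",
            extra={"df": df},
        )
    if method == "mannwhitney":
        res = stats.mannwhitneyu(b, a, alternative="two-sided")
        # Rank test reports the same mean-difference effect with a bootstrap CI.
        rng = np.random.default_rng(0)
        boots = [
            rng.choice(b, len(b)).mean() - rng.choice(a, len(a)).mean()
            for _ in range(1000)
        ]
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return ComparisonResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            effect=effect,
            ci_low=float(min(lo, effect)),
            ci_high=float(max(hi, effect)),
            method="mannwhitney",
        )
    raise ValueError(f"unknown method {method!r}")


def fold_change(
    values_a,
    values_b,
    statistic=np.mean,
    n_boot: int = 1000,
    seed: int = 0,
) -> ComparisonResult:
    """Ratio statistic(b)/statistic(a) with a trace-level percentile bootstrap CI.

    *values_a*/*values_b* are per-trace metrics; traces are resampled with
    replacement within each group (default 1000 resamples, seeded).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one value")
    denom = statistic(a)
    if denom == 0:
        raise ValueError("zero denominator in fold change")
    ratio = float(statistic(b) / denom)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        da = statistic(rng.choice(a, size=len(a)))
        db = statistic(rng.choice(b, size=len(b)))
        boots[i] = db / da if da != 0 else np.nan
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p = 2.0 * min(float(np.mean(boots <= 1.0)), float(np.mean(boots >= 1.0)))
    return ComparisonResult(
        statistic=ratio,
        p_value=min(p, 1.0),
        effect=ratio,
        ci_low=float(lo),
        ci_high=float(hi),
        method="bootstrap_fold_change",
        extra={"n_boot": int(len(boots))},
    )


def significance_stars(p: float) -> str:
    """Conventional star annotation (report formatting only)."""
    if p < 1e-4:
        return "****"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def plot_tdp(tdp: TransitionDensity, ax=None, cmap: str = "jet"):
    """Render a TDP heat map (blue = sparse, red = dense transitions)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = (tdp.bin_edges[0], tdp.bin_edges[-1]) * 2
    ax.imshow(
        tdp.counts.T, origin="lower", extent=extent, aspect="equal", cmap=cmap
    )
    ax.set_xlabel("intensity before transition (a.u.)")
    ax.set_ylabel("intensity after transition (a.u.)")
    return ax
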