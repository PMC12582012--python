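# tracekin

Single-molecule reaction kinetics from fluorescence intensity trajectories.

`tracekin` analyses per-molecule intensity time traces I(t) from TIRF-type
single-molecule experiments in which a surface-tethered substrate cycles
through optically distinguishable chemical states.  The motivating system is
the iminium-catalysed Diels–Alder reaction of a BODIPY-tagged
α,β-unsaturated aldehyde **S**, which reversibly forms an N,O-acetal
intermediate **IM1** with a secondary-amine catalyst, dehydrates to the
iminium ion **IM2**, and — with a diene present — reacts irreversibly to the
cycloadduct **P**:

```
S  ⇌  IM1  ⇌  IM2  →  P
```

Each state emits fluorescence at a distinct mean level, so a trajectory is a
noisy piecewise-constant signal.  The package provides the full chain from
raw traces to rate constants:

1. **Segmentation** — a Gaussian-emission hidden Markov model fitted by
   Baum–Welch, *pooled* across all trajectories of a condition; the number of
   hidden states is chosen by the Bayesian Information Criterion
   (BIC = −2 log L + p ln N); each trace is decoded by Viterbi.
2. **Dwell-time kinetics** — run-length encoding into dwells with censoring
   flags; gamma dwell-density fits t^(n−1)e^(−kt) (shape n ≈ 1 ⇒ single
   rate-limiting step, n ≈ 2 ⇒ hidden two-step process); per-transition rate
   constants from the continuous-time Markov chain MLE k(n→m) = N(n→m)/T(n);
   per-frame transition probabilities P(n→m); occupancy fractions and event
   frequencies.
3. **Concentration series** — a bimolecular step appears pseudo-first-order,
   1/⟨τ⟩ = k·[X], so weighted least squares of the decoded rate against
   concentration (through the origin) yields the bimolecular constant in
   M⁻¹ s⁻¹.  An optically invisible product channel is still measurable via
   the Markov property: τ_IM2 = 1/(k_IM2→IM1 + k_IM2→P), with the reference
   rate taken from a diene-free control.
4. **Statistics** — transition density plots (intensity before vs after each
   transition), Welch/Mann–Whitney group comparisons, bootstrap fold-changes.
5. **Synthetic trajectories** — an exact stochastic (Gillespie) simulator of
   any kinetic scheme with concentration-coupled rates, camera frame
   integration, state-dependent Gaussian noise and optional photobleaching.
   Every estimator in the package is validated by parameter recovery against
   this generator.

## Worked example

Recover the catalyst-addition constant from a simulated six-point
concentration series (the defaults emulate ~100 ms frames, 1 min traces,
200 molecules per condition):

```python
from tracekin import benchmarks as bm

series = bm.run_g1_series(seed=0)
est = series.k_S_IM1
print(f"k(S->IM1) = {est.value:.2f} +/- {est.se:.2f} M^-1 s^-1 "
      f"(r^2 = {est.diagnostics['r_squared']:.4f})")
for key, d in series.unimolecular.items():
    print(f"k({key}) = {d['weighted_mean']:.3f} +/- {d['se']:.3f} s^-1")
```

prints

```
k(S->IM1) = 22.95 +/- 0.30 M^-1 s^-1 (r^2 = 0.9991)
k(IM1->S) = 0.195 +/- 0.003 s^-1
k(IM1->IM2) = 0.190 +/- 0.003 s^-1
k(IM2->IM1) = 0.213 +/- 0.003 s^-1
```

The generating constants were 23.75 M⁻¹ s⁻¹ and 0.21 / 0.20 / 0.22 s⁻¹: the
bimolecular slope is recovered to ~3% (a small systematic underestimate from
the 0.1 s frame quantisation is expected — see `docs/methods.md`), and the
unimolecular constants show no concentration trend, i.e. zero-order
behaviour in catalyst.

The same pipeline is scriptable from the shell:

```bash
tracekin simulate --cat-conc 15 --n-traces 200 --seed 0 --out data/
tracekin fit --traces data/traces.csv --meta data/metadata.json --k 3 --out model.json
tracekin analyze --config analysis.yaml --out results/
tracekin report --analysis results/report.json
```

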