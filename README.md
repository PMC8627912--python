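# rnclink

Quantitative analysis of interactions between unfolded nascent protein
chains and the ribosome surface, and of their consequence for
co-translational folding.

## The problem

During biosynthesis a nascent chain emerges next to the charged ribosome
surface, and segments of it — aromatic clusters, basic stretches — bind
that surface transiently.  Such binding stabilizes the unfolded state
and so delays folding: the ribosome acts as an ATP-independent holdase.
Establishing this link quantitatively requires estimating, from NMR
observables, the *bound fraction* `p_B` of a chain segment as a function
of nascent-chain (linker) length, and comparing the implied folding
destabilization with directly measured co-translational stabilities.

`rnclink` implements that analysis chain for ribosome–nascent chain
complex (RNC) data:

- **Broadening profiles** — per-residue intensity ratios between RNC
  and isolated-protein spectra, with noise-propagated errors and a
  moving average (`nmr_io`).
- **Transferred cross-correlated relaxation** — under fast exchange,
  Δη_xy = p_B·η_xy^bound, so excess DD/CSA cross-correlated relaxation
  converts directly to bound populations; the rigid-limit
  η_xy^bound (~7,000 s⁻¹ for a 70S particle) can be supplied or
  computed from the rotational correlation time (`relaxation`).
- **Global fast-exchange CSP fit** — chemical-shift perturbations obey
  CSP = p_B·Δδ_max.  A joint fit of two charge variants across linker
  lengths, with a length-independent inter-variant offset ΔΔG and
  shared endpoint shifts Δδ_max, resolves absolute populations per
  (variant, length) with bootstrap uncertainties; collinearity of CSP
  trajectories in the (¹H, ¹⁵N) plane is tested to select valid
  reporter resonances (`csp_binding`).
- **Thermodynamic linkage** — ΔG(U_free→U) = RT ln(1 − p_B) converts
  bound fractions into folding destabilizations, and predicts the
  inter-variant stability gap on the ribosome (`folding_thermo`).
- **Global two-state denaturation fits** — CD and PEGylation curves
  fitted to y = α_N + α_D·e^x/(1+e^x), x = m([D]−[D]₅₀)/RT, with a
  shared or fixed m value, per-curve urea masks, and ΔG = m·[D]₅₀
  (`folding_thermo`).
- **Coarse-grained contact analysis** — Debye–Hückel pair energies,
  cutoff-based contact probabilities, segment bound fractions, and
  their correlation with measured binding across lengths
  (`cg_contacts`).
- **Synthetic data** for every input class, generated from explicit
  ground truths and seeds, so the whole pipeline is testable with no
  external data (`synthetic_data`).

## Worked example

Simulate a two-variant CSP dataset at realistic noise, run the global
fast-exchange fit, and convert the short-linker population into a
folding destabilization:

```python
import rnclink as rl

# ground truth: reference variant 90%/60% bound at the 26/42-residue
# linkers, charge-reversed variant offset by 1.9 kcal/mol
truth = rl.BindingGroundTruth.from_populations(ddg=1.9)
data = rl.simulate_csp_dataset(truth, noise_sd=(0.003, 0.02), seed=12)

tables = {
    v: {L: rl.compute_csp(rl.match_peaks(data[(v, L)], data[(v, None)]))
        for L in truth.lengths}
    for v in truth.variants
}
fit = rl.global_exchange_fit(tables, sigma=(0.0042, 0.028),
                             n_starts=12, n_boot=200, seed=0)
print(f"ddG (A3A3 -> A3A3E6) = {fit.ddg:.2f} +/- {fit.ddg_se:.2f} kcal/mol")
for _, r in fit.populations.query("variant == 'A3A3'").iterrows():
    print(f"  L={r['length']:>3.0f}: p_B = {r['p_B']:.2f} +/- {r['p_B_se']:.2f}")

p26 = fit.p_bound("A3A3", 26)
destab = rl.unfolded_state_stabilization(p26).destabilization
print(f"predicted folding destabilization at L=26: {destab:.2f} kcal/mol")
```

prints

```
ddG (A3A3 -> A3A3E6) = 1.91 +/- 0.70 kcal/mol
  L= 26: p_B = 0.92 +/- 0.05
  L= 31: p_B = 0.87 +/- 0.06
  L= 42: p_B = 0.64 +/- 0.05
  L= 47: p_B = 0.52 +/- 0.04
  L= 67: p_B = 0.26 +/- 0.03
  L=110: p_B = 0.09 +/- 0.03
predicted folding destabilization at L=26: 1.45 kcal/mol
```

The fit recovers the injected inter-variant binding free-energy gap
(1.9 kcal/mol) and the per-length bound fractions of the strong-binding
variant; the linkage relation then says that ~90% binding at the
shortest linker destabilizes folding by more than 1 kcal/mol.  Strong
binding is required for a thermodynamically meaningful holdase effect —
a 1 kcal/mol destabilization needs `p_B` > 80%
(`rl.required_binding_for_destabilization(1.0)` → 0.831).

A command-line interface mirrors the library
(`rnclink simulate|fit-csp|ccr|fit-denat|link|contacts|pipeline`); every
run writes a manifest with seed, config hash and input checksums, e.g.

```sh
rnclink pipeline --seed 1 --out demo/
rnclink link --ddg 1.0
```

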