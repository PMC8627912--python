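# Methods

This note records the models implemented in `rnclink`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices that affect
results.

## Physical setting

An arrested ribosome–nascent chain complex (RNC) tethers an unfolded
protein domain to the ribosome by a linker of `L` residues.  Segments of
the unfolded chain bind transiently to the ribosome surface; the bound
fraction `p_B` of a segment depends on the variant (its sequence and
charge) and on `L` through the effective ribosome concentration the
segment experiences.  Binding stabilizes the unfolded state and thereby
inhibits folding.  All defaults refer to 283 K and use
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹.

## Fast-exchange CSP model (`csp_binding`)

Under fast exchange a resonance sits at the population-weighted average
of the free and bound positions, so the chemical-shift perturbation of
residue `r` in dimension `d` (¹H or ¹⁵N) is

    CSP(v, L, r, d) = p_B(v, L) · Δδ_max(r, d),
    p_B = K/(1+K),   K(v, L) = exp(−ΔG_bind(v, L)/RT).

The global fit ties two variants together with a single length-
independent free-energy offset ΔΔG:

    ln K(v₂, L) = ln K(v₁, L) − ΔΔG/RT,

and shares `Δδ_max` between variants.  These two assumptions (same
effective concentration at a given `L`; same bound-state shift change)
are what make the absolute populations identifiable: a single variant at
a single length only determines the product `p_B·Δδ_max`.  The sign
convention is ΔΔG > 0 when the second variant binds more weakly.

Free parameters: `ln K(v₁, L)` per length (no parametric form in `L` is
assumed), one ΔΔG per non-reference variant, and `Δδ_max` per
(resonance, dimension).  No monotonicity of `p_B` in `L` is enforced;
it is reported as a diagnostic.

*Collinearity screening.*  If a single two-site equilibrium drives the
shifts, peak positions across lengths move along the fixed direction
`Δδ_max` in the (¹H, w·¹⁵N) plane.  `collinearity_test` fits a
total-least-squares line (SVD of the centred, scaled positions) per
residue and flags residues whose RMS perpendicular deviation exceeds a
tolerance; flagged residues (typically those closest to the exit
tunnel) can be excluded from the global fit.  The ¹⁵N weighting
`w = 0.14` is a common reporting convention; the global fit itself uses
per-dimension CSPs, so `w` affects only reporting and collinearity
scaling.

*Interpolation.*  `bound_fraction_curve` interpolates fitted `p_B` over
`L` with a shape-preserving monotone (PCHIP) interpolant and refuses
extrapolation: outside the fitted range the effective concentration is
unconstrained.

## Transferred relaxation (`relaxation`)

For a segment in fast exchange with a rigidly attached bound state, the
excess transverse DD/CSA cross-correlated relaxation rate is

    Δη_xy = p_B · η_xy^bound,

so `p_B = Δη_xy / η_xy^bound`.  The default `η_xy^bound = 7,000 s⁻¹` is
a configuration scalar; alternatively `eta_bound_from_tauc` evaluates
the rigid-limit rate from the rotational correlation time:

    η_xy = ½ · d · c · P₂(cos θ) · [4J(0) + 3J(ω_N)],
    d = (μ₀/4π) ħ γ_H γ_N / r³,   c = γ_N B₀ |Δσ|/3,
    J(ω) = (2/5) τ_C / (1 + (ωτ_C)²),

with defaults r_NH = 1.02 Å, Δσ_N = −160 ppm, θ = 17° (all
overridable).  Literature prefactor conventions differ by small
rational factors; with this one, the τ_C reproducing 7,000 s⁻¹ at
22.3 T is 4.3 µs, consistent with a 70S particle.  τ_C itself is a
required user input.  Negative Δη (expected under noise for
non-interacting residues) is clipped to zero and flagged, not rejected.

Note that `p_B = Δη/η_bound` assumes a rigid bound state; flexibility
in the bound state lowers `η_xy^bound` and makes the quotient a lower
bound on the true population.

*Fast-exchange lifetime bound.*  A single averaged resonance requires
the bound-state lifetime to satisfy τ ≪ 1/(4πΔν) for the largest
bound–free frequency difference Δν; `exchange_lifetime_bound` returns
this τ_max and k_off,min = 4πΔν.

## Thermodynamic linkage (`folding_thermo`)

A segment bound a fraction `p_B` of the time has its unfolded state
stabilized by

    ΔG(U_free→U) = RT ln(1 − p_B)  ≤ 0,

which destabilizes folding by the same magnitude (the native state
cannot bind).  The inverse map is `p_B = 1 − exp(−ΔG/RT)`.  For two
variants with isolated-state stability gap ΔΔG_iso, the predicted gap
on the ribosome is

    ΔΔG_pred = ΔΔG_iso + RT ln[(1 − p_B,wt)/(1 − p_B,e6)].

## Two-state denaturation fits (`folding_thermo`)

Curves (CD signal or fraction PEGylated vs denaturant) follow

    y([D]) = α_N + α_D · f,   f = e^x/(1+e^x),
    x = m([D] − [D]₅₀)/RT,    ΔG_D−N = m·[D]₅₀.

Baselines are per-curve constants (the printed model); a linear-slope
extension was considered and deliberately not implemented, keeping
12-point designs well identified.  The global fit shares a single `m`
across curves, or fixes `m` to a supplied value (used for nascent-chain
curves, where `m` comes from the isolated proteins).  Nascent-chain
curves are fitted only below a per-curve urea cutoff (ribosomes
dissociate at high urea); the mask is a strict inequality, and masked
points provably never influence the fit.  Uncertainties come from the
whitened-Jacobian covariance scaled by reduced χ², or from a seeded
residual bootstrap when requested; stability differences propagate the
shared-`m` covariance.

## Coarse-grained contacts (`cg_contacts`)

Bead trajectories (one bead per chain residue; grouped beads for
ribosome residues; rigid ribosome) are analysed with a cutoff
criterion: ribosome residue `j` is contacted in a frame when any
segment bead lies within the cutoff (default 0.8 nm, recorded in
outputs — no cutoff is dictated by the data) of any of its beads; a
frame is *bound* when the total number of contact pairs reaches
`min_contacts` (default 1).  Probabilities are frame averages, hence
invariant under frame permutation.  Electrostatics use Debye–Hückel
screening, `U = k q₁q₂ e^{−r/λ_D}/(ε_r r)` with
k = 33.206 kcal mol⁻¹ nm e⁻², default λ_D = 1.0 nm and ε_r = 80.
`correlate_contacts_with_binding` computes, per ribosome residue, the
Pearson correlation between contact probability and experimentally
determined `p_B` across ≥ 3 linker lengths.

## Synthetic generators (`synthetic_data`)

All generators are pure functions of (truth, seed).

**CSP datasets.**  Default truth: lengths {26, 31, 42, 47, 67, 110},
reference-variant populations {0.90, 0.82, 0.60, 0.47, 0.25, 0.06}
(anchored at 90% for L=26 and 60% for L=42, decaying to near zero),
ΔΔG = 1.9 kcal/mol, four reporter resonances with Δδ_max of
0.15–0.345 ppm (¹⁵N) and 0.035–0.055 ppm (¹H) — the largest
corresponds to ~30 Hz at 22.3 T when 90% bound.  Shift noise defaults
to 0.003 ppm (¹H) and 0.02 ppm (¹⁵N) per spectrum, so a CSP carries
√2 of that.  Intensities decay as `(1−p_B)·exp(−β·p_B)` (β = 1), a
monotone phenomenological broadening model, with residues dropped below
an attenuation threshold to mimic resonances broadened beyond
detection.  Before noise, per-resonance CSPs across lengths are exactly
collinear and inter-variant odds ratios are exactly length-independent.

**CCR datasets.**  `η_rnc = η_free + p_B·η_bound + ε`, isolated tables
carry independent noise around `η_free`.

**Denaturation curves.**  Two-state sigmoids on a user grid with
Gaussian noise; midpoints must fall inside the grid (otherwise the
truth is rejected).  Fraction-style curves are not clipped to [0, 1] —
densitometry noise genuinely produces small excursions.

**Trajectories.**  Frames are labelled bound i.i.d. at the target
fraction (default 0.6, matching the calibration of the CG model against
the measured binding of the 730–746 segment); bound frames dock segment
beads within the cutoff of ribosome residues drawn from a contact-
propensity profile, free frames place all beads far from the surface.
The empirical bound fraction equals the label fraction exactly by
construction, and agrees with the target to binomial error.

*What the generators do not emulate*: realistic chemical-shift values
(free positions are deterministic placeholders), field- or
temperature-dependent relaxation of the free chain, baseline drifts or
correlated noise in denaturation data, and any real ribosome geometry
or force field in trajectories.  Passing recovery tests therefore
demonstrates the estimators are correct and calibrated for data obeying
the stated models at the stated noise — not robustness to systematic
effects absent from the models.

## Numerical choices

- **Global CSP fit**: trust-region least squares with bounds
  (|ln K| ≤ 12, |ΔΔG| ≤ 10 kcal/mol, |Δδ_max| ≤ 3 ppm), ≥ 8–16
  multi-starts (one deterministic start plus seeded random starts over
  ln K, ΔΔG and a data-driven Δδ_max guess), best cost kept.
  Confidence intervals by seeded residual bootstrap (whitened residuals
  resampled, refit from the optimum; 100–200 draws).  Designs with a
  single length or a single variant raise an identifiability error.
- **Saturation boundary**: when a dataset is consistent with `p_B → 1`
  at the shortest length, the maximum-likelihood fit genuinely sits at
  the saturation boundary and ΔΔG inflates.  This heavy right tail is a
  property of the estimator near saturation, so replicate studies here
  summarize recoveries by the median, which is unbiased in simulation.
- **Two-state fit**: least squares with `m > 0` bound; baseline and
  midpoint initial values taken from curve ends and the half-amplitude
  crossing; covariance from the whitened Jacobian scaled by reduced χ²
  (superseded by bootstrap covariance when bootstrap is on).
- **Smoothing** (`intensity_ratio_profile`): centred moving average of
  odd width over residues present; the window shrinks at chain ends
  (no padding); flagged residues (non-positive reference intensity)
  are excluded.  Window 1 is the identity.
- **Problem sizes** used by the test suite and the acceptance script
  (replicate counts of 8–48, trajectories of 10³–10⁴ frames, bootstrap
  of 100–200 draws) were chosen so that Monte-Carlo summaries have
  sampling error well below the tolerances they are compared at.

## Known limitations

- The CSP fit supports exactly the two-variant linkage design (plus
  additional variants, each with its own offset); it does not model
  ionic-strength dependence quantitatively.
- `p_B` from CCR assumes a rigid bound state (lower bound otherwise).
- Per-curve independent `m` values are not fitted globally; fit curves
  individually if `m` is not shared.
- Interpolated confidence bands in `bound_fraction_curve` interpolate
  the per-node intervals, which ignores inter-node correlation.
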