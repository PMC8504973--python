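# Methods

## Model

`mwcgate` treats a pentameric proton-gated channel as a concerted
(MWC-type) three-state allosteric system: resting R, pre-active pA
(compacted ECD, shifted M2-M3 loop, closed pore), active A (open pore).
Desensitization is excluded: fluorescence is quenching-fast and peak
currents are used, so neither observable reports the slow desensitized
state. Two classes of proton-binding site, each present in five
identical, independent copies (one per subunit), bias the equilibrium.
The statistical weight of state *s* at proton concentration
h = 10^(−pH) M is

    w_s = L_s · (1 + h/K_s)^n · (1 + h/K_s')^n,      n = 5 by default

with zero-ligand prefactors L_R = L_pA·L_A, L_pA-state = L_A, L_A-state = 1,
and populations w_s / Σ w. Activity corrections to [H⁺] are ignored; the
isomerization constants are defined strictly at zero ligand (at pH 8 the
occupancy of every fitted site is < 1%, so "resting ratio near-neutral pH"
and "zero-ligand ratio" are interchangeable at the reported precision).

The site-class assignment used throughout (and enforceable via
`constraint_flags`) is K_pA = K_A for class 1 (it drives R → pA only) and
K_R′ = K_pA′ > K_A′ for class 2 (it drives pA → A only). All weights are
computed in log space and exponentiated after subtracting the maximum, so
(1 + h/K)^5 never overflows even at h/K ~ 10⁸; populations sum to one to
10⁻¹² over the full parameter ranges exercised by the tests.

Observables: sensor fluorescence F = R̄ F_R + pA̅ F_pA + Ā F_A on the
F/F_SDS scale, with the per-state intensities fixed at the published
values (0.70/0.30/0.30 for the ECD-compaction sensor, 0.56/0.92/0.92 for
the M2-M3-loop sensor; F_pA = F_A because the quenching change completes
during pre-activation); and current proportional to Ā, normalized to its
maximum over the pH grid so constructs whose active fraction saturates
below one still share the [0, 1] scale with normalized peak-current data.

Midpoints are located by a 0.01-pH sign scan followed by bisection to
10⁻⁴ pH; responses that never cross their half level, or cross more than
once (bell-shaped), raise a named error rather than return a number.
Apparent cooperativity is d logit(normalized response)/d ln[H⁺] at the
midpoint by a centered 0.01-pH difference; for a pure Hill curve this is
the Hill exponent exactly.

## Data preparation

Fluorescence is normalized once by the denatured-protein value F_SDS
(a second normalization is an error). Oocyte recordings are corrected for
rundown with the interleaved reference applications: each reference,
relative to the first, gives the rundown factor at its application index;
the factor at test applications is interpolated piecewise-linearly in
index (an exponential option interpolates the log factor), test responses
are divided by it, and references are dropped. For a linear rundown the
linear interpolation is exact. A construct whose resting-state
fluorescence is itself altered can be affinely remapped onto its parent's
fitted plateau range (`renormalize_to_reference`), with the coefficients
recorded in the series provenance.

## Empirical Hill fits

Fluorescence: y = F₀ + ΔF·xⁿ/(xⁿ + EC₅₀ⁿ) with x = [H⁺] and a *signed*
amplitude (summary tables report |ΔF|); current: y = I_max·xⁿ/(xⁿ+EC₅₀ⁿ).
Fits are bounded trust-region least squares with ≥ 5 starts over
log-spaced EC₅₀ (ties broken by lowest RSS then lowest n_H), evaluated
through a logistic in log[H⁺] for overflow safety. n_H may be fixed or
bounded above, mirroring the constraints applied to poorly determined
steep curves in the source tables. Points below pH 3.5 can be excluded
per construct (some sensors show a small opposite-direction intensity
change there). Data whose interior deviates beyond the band spanned by
the two end plateaus by more than 3× the local noise *and* 25% of the
span are declared bell-shaped and not fitted.

Group comparison uses Welch two-sample t-tests with Holm adjustment for
the mutant-vs-parent family — a deliberate, documented stand-in for
one-way ANOVA with Dunnett's multiple comparisons, which no installed
library provides exactly; the stand-in is conservative at these group
sizes. Single-replicate groups report their shift with the test marked ND.

## Stepwise MWC fitting

1. **Anchor.** A pore-opening-dead construct reduces the model to R/pA.
   Its curve constrains a midpoint and a steepness but three constants
   (L_pA, K_R, K_pA) would be free, so the fit is anchored: L_pA is fixed
   (default 100) and the class-1 affinities are fitted. Asked for an
   unanchored joint fit, the code profiles L_pA one decade off its
   optimum, refits the K's, and refuses if the rms misfit stays below the
   0.01 noise scale of normalized fluorescence — the flat valley that
   makes the joint fit meaningless. (A Jacobian condition number was
   considered for this guard but does not discriminate here: it is only
   ~27 at the optimum even though the valley is flat relative to noise.)
2. **Sensor.** With the K's fixed, each sensor's own L_pA is fitted on its
   fluorescence curve in the two-state reduction, then the activation
   branch is added and (L_pA, L_A) are refined jointly on fluorescence +
   normalized current with equal per-modality weight (each modality's
   residuals scaled by 1/√n). The two-state L_pA is kept as the starting
   value; refining it matters because the reduction ignores the A state
   and otherwise biases L_pA low by ~15–20%. The primed-site affinities
   are *chosen*, not fitted (defaults K_pA′ = 10⁻⁴ M, K_A′ = 10⁻⁶ M, a
   pKa 4 → 6 shift on activation, plausible for carboxylate clusters):
   with F_pA = F_A the fluorescence cannot separate pA from A, the
   normalized current constrains fewer features than the branch has
   parameters, and the remaining (K_A′, L_A) trade-off is flatter than
   the noise floor. Setting `K_pAp_fixed`/`K_Ap_fixed` to None restores
   the full joint fit, which recovers its own noise-free output exactly —
   the degeneracy is statistical, not structural.
3. **Mutants.** Each mutant adjusts only log₁₀ L_pA and log₁₀ L_A
   (bounds 10⁻⁴–10⁸), reported as multiplication factors relative to its
   parent sensor. Constructs without measurable current (peak response
   under 6× the high-pH baseline spread, or flagged in the roster) are
   fitted in the two-state mode and report no activation factor. A fit
   whose per-point RSS exceeds 3× the sensor's (floored at 10⁻⁴, the
   σ = 0.01 noise variance, so near-perfect synthetic sensors don't flag
   everything) is marked "poor".
4. **Anchor sensitivity.** The whole chain re-runs at alternative anchors
   (default 1000 and 100 000); the mutant factor *ordering* (Spearman
   rank correlation across anchors) is the robust output, the absolute
   factors are not.

### Why two site classes

With a single site class and full-amplitude constraints (R̄ sweeping
0.98 → 0.02 and Ā 0.02 → 0.98 over pH 9 → 0), the resting-occupancy
requirement forces L_pA ≥ 49, which pins the fluorescence midpoint at
h ≥ 1.18·K_pA while the current midpoint cannot exceed ~0.9·K_pA: the
two curves cannot separate. `single_site_separation_scan` documents this
by exhaustive log-grid search (default 12⁵ ≈ 250 000 combinations over
K_A ∈ [10⁻⁹, 10⁻⁴], K ratios up to 10⁴, L up to 10⁸, evaluated in
chunked vectorized log-space arithmetic); the two-site model reproduces
the M2-M3-loop sensor's observed >10-fold (>1 pH) separation.

## Synthetic data generator

The generator emulates the study's experimental design so the pipeline
is testable end to end: an 11-point pH 8 → 3 grid; additive Gaussian
noise on the normalized response (default σ = 0.02, which yields
pH₅₀ SDs of ~0.1–0.3 over 3 replicates, the range of the study's summary
table; several tests use σ = 0.01 where a stated recovery property
assumes it); per-replicate protein-amount scale factors that cancel on
F_SDS normalization; current recordings with reference applications at
both ends and every 3 test applications, a linear multiplicative rundown
to 0.8, and the reference pH snapped per construct to the grid point
nearest its half-maximal current (a fixed pH-5 reference would sit at the
response foot of strongly shifted mutants, and dividing by a near-zero
noisy reference would amplify noise several-fold — real recordings choose
a reference that evokes a robust response). Mutant panels apply
(f_L_pA, f_L_A) to a sensor truth; f_L_A = ∞ marks a non-functional
construct, generated as the two-state reduction with pure-noise currents.
One RNG per panel is split per series by a CRC of the series label, so
values are independent of iteration order.

Truth parameter sets for the two sensors were derived analytically, once,
from the published anchor affinities and the printed sensor midpoints
(fluorescence 5.85/5.83, current 5.42/4.66): L_pA = 15 and L_A = 1738
(ECD sensor) or 2.235×10⁶ (loop sensor, max pA̅ = 0.90). The primed-site
affinities were chosen with enough dynamic range that the largest
published activation factor (700) remains representable on the normalized
current scale; with a 10-fold K_pA′/K_A′ ratio the model saturates near a
factor of 240 and larger factors become unidentifiable.

What the generator does **not** emulate: heteroscedastic noise across pH,
oocyte expression variability beyond a scale factor, desensitization,
photobleaching, or the multi-step character of pre-activation suggested
by the real curves' low cooperativity. Passing recovery tests therefore
show the pipeline is correct and well-conditioned under the stated noise
model, not that real-data fits carry the same accuracy.

## Structure metrics

Multi-MODEL PDB files are parsed with gemmi; altlocs resolve to the
highest occupancy, ties alphabetically; coordinates are Å and residue
numbering follows the file. Metrics:

* **Twist angle** — per subunit, the signed pseudo-dihedral of (subunit
  ECD centroid, whole ECD centroid, whole TMD centroid, subunit TMD
  centroid), positive when the ECD is rotated counterclockwise relative
  to the TMD viewed from the extracellular side. The exact formula of the
  prior literature is not published, so the residue ranges and sign
  convention are configurable and this definition is documented as an
  interpretation.
* **Pair distances** — Cα, Cβ, a named atom, or the unweighted side-chain
  heavy-atom centroid (all heavy atoms for non-standard residues such as
  a placed bimane); all five subunits (intra) or all five ordered i → i+1
  interfaces (inter), reported per frame with mean ± sample SD.
* **Ring radius** — mean perpendicular distance of a residue's ring atoms
  to the pore axis (total-least-squares line through the per-chain ECD
  and TMD centroids), optionally minus a 1.7 Å carbon van der Waals
  radius. This is a geometric stand-in for solvent-channel free radii
  from channel-tracing software; no numeric equivalence is claimed.
* **RMSD** — after optimal proper-rotation (Kabsch) superposition by
  default, on atoms corresponded by (chain, residue, atom).
* **Asymmetry** — per-frame mean/SD/range of a per-interface metric, plus
  a detector for SD declining from first to last frame (ECD
  symmetrization along a trajectory).

All metrics are rigid-motion invariant to 10⁻⁶ and recover their
construction parameters exactly on the synthetic C5 pentamer builder
(two ring-arc layers per chain with controllable twist, radius,
layer separation and ECD compaction).

## Problem sizes and numerical choices

Default test problem sizes: 3 replicates per construct, 11-point grids,
panels of 4 mutants + anchor + sensor; the Hill-recovery property uses
200 seeds; the bulk population-normalization check uses 10⁶ draws
(1000 parameter sets × 1000 pH points); the single-site scan uses 8–12
points per axis (33 000–250 000 combinations). Optimizer tolerances are
xtol = ftol = gtol = 10⁻¹⁴/10⁻¹⁵ so noise-free self-consistency holds to
10⁻⁶ relative; EC₅₀, K and L are always optimized in log₁₀ space; ties in
multi-start are broken by lowest RSS then lowest n_H.

## Known limitations

* Absolute isomerization constants are anchor-relative by construction;
  only multiplication factors and their ordering are interpretable.
* The activation-branch affinities are conventions, not estimates; a
  different choice rescales every L_A and f_L_A.
* The fluorescence model predicts sharper curves than real sensors show
  (a single concerted pre-activation step); nothing in the fitting
  corrects for that, matching the source analysis.
* Welch+Holm is not Dunnett; borderline significance stars may differ
  from tables computed with the exact procedure.
* The pipeline fits the printed study design (one parent sensor per
  panel, shared class-1 constants); crossed designs would need roster
  extensions.
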