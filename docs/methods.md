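# Methods

## Scope and model

`degronscreen` analyses degron screens in which random peptides are fused to
the C-terminus of a Ura3-HA reporter. Three measurement types are modelled:

1. **Colony growth on −Ura medium.** Ura3 activity, and hence colony size,
   reflects the reporter's steady-state level, which falls as the degron's
   degradation rate constant rises. Rescue of growth in an E3-deletion
   mutant is the screening readout for dependence on that ligase.
2. **Cycloheximide chase.** After translation shutoff the substrate signal
   decays; degradation is assumed first-order, `P(t) = 100·e^(−λt)` on the
   percent-remaining scale, with half-life `t½ = ln 2 / λ`.
3. **Steady-state blots.** Loading-normalized levels relative to the
   no-degron reporter (set to 1).

## Sequence features

GRAVY is the arithmetic mean of per-residue hydropathy values; the default
scale is Kyte–Doolittle (values from Biopython, range −4.5…4.5), which
reproduces the bundled tester-set table to the printed three decimals. The
scale is injectable. The longest hydrophobic stretch is computed over a
configurable residue set, by default {A, C, F, I, L, M, V, W} — the
positive-hydropathy residues minus glycine; no single field definition
exists, hence the parameter. Nonstandard residues (B, J, O, U, X, Z) are
rejected rather than imputed: a translated library contains only the
standard alphabet. Fusion translation starts in frame 0 of the insert and
runs into the vector tail `TAAATAAATAA`, which carries a stop codon in all
three frames, so termination is guaranteed for any insert length;
translation uses the standard genetic code via Biopython.

## Synthetic screen generator

The generator exists so every downstream statistic can be tested against a
known truth. What it emulates, and its defaults:

* **Library**: fragments uniform over a random genome, sizes uniform in
  50–400 bp, forward/reverse-complement orientation with probability ½
  (blunt cloning is orientation-blind), translated in the fusion frame;
  empty translations are discarded. Fragment provenance is recorded
  0-based, half-open.
* **Kinetics**: `log λᵢ = a + b·gravyᵢ + c·1[runᵢ ≥ 5] + ε`,
  `ε ~ N(0, σ_λ)`, with a = log 0.12 (median t½ ≈ 5.8 min), b = 0.25,
  c = 0.4, σ_λ = 0.5. These place the bulk of half-lives between ~2 and
  ~16 min, matching the very fast turnover such screens select for, with a
  mild hydrophobicity dependence. Strain effects: each degron is dependent
  on a mutated ligase with probability π (default 0.5, a "doa10"-like
  strain) and, if dependent, its rate drops by the stabilization factor
  f (default 8).
* **Steady state**: synthesis/(degradation + dilution), normalized so the
  no-degron construct sits at 1: `S = μ/(λ+μ)` with dilution
  μ = ln 2/100 min⁻¹ (a ~100-min doubling time).
* **Plates**: 96-position layout with 4 excluded corner wells, 6 reference
  (Ura3-HA) and 6 no-Ura3 wells scattered at fixed positions, up to 80
  degron wells; quadruplicate pinning. Expected area is a saturating
  function of steady state, `A_max·(b₀ + (1−b₀)·S/(S+K))` with baseline
  fraction b₀ = 0.05 and K = ⅓ (in units of the no-degron level), so a
  fully degraded construct approaches the no-Ura3 baseline and
  stabilization restores growth. The mapping from reporter level to colony
  size is not measurable from blot/plate data alone; any monotone
  saturating choice is a modelling assumption. Each physical plate carries
  a lognormal(0, 0.05) plate effect — which is exactly what within-plate
  normalization removes — and each pinned replicate lognormal noise with
  CV 0.10.
* **Chase/blots**: substrate `I(t) = I₀·e^(−λt)·ε_t`, loading
  `L(t) = L₀·ε′_t`, with independent lognormal errors of log-SD σ = 0.1
  per channel. Default timepoints 0, 2, 4, 8, 15, 30 min span half-lives
  from under 2 to ~30 min (fast degrons need the early points); triplicate
  series.
* **Determinism**: one master seed; per-stage streams are spawned from a
  `SeedSequence`, so regenerating a later stage never perturbs an earlier
  one.

What the generator does **not** emulate: colony-morphology or edge effects
beyond a scalar plate factor, spatial gradients within plates, saturating
or nonlinear blot chemistry, mRNA-level effects, multi-phase decay, and
biological replicate-to-replicate rate variation. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
generative model, not robustness to every artefact of real plate images or
gels.

## Plate growth analysis

Normalization per physical plate:
`norm = (area − mean(no-Ura3)) / (mean(ref) − mean(no-Ura3))`, clipped below
at 0 (a zero colony is a true Ura⁻ phenotype, not missing data); corner
wells are excluded. The formula anchors the two control roles present on
every plate and is invariant to any common multiplicative factor.
Relative growth is `log₂(mean(norm_mut)/mean(norm_wt))`; a non-positive
group mean makes the ratio undefined and the degron is flagged
*indeterminate*, not dropped. The Mann–Whitney test is exact when
min(n) ≤ 8 and the pooled sample is tie-free, otherwise the tie-corrected
normal approximation is used; two-sided by default, with a one-sided
(`greater`) option because stabilization is directional. Correction across
the degron grid within each mutant: Benjamini–Hochberg by default, `holm`
and `none` available (`none` reproduces per-test masking). α defaults
to 0.05.

## Decay kinetics

Percent remaining divides each timepoint's loading-normalized signal by the
0-min value, so `P(0) ≡ 100`. The fit minimizes `Σ(P − 100·e^(−λt))²` over
λ ≥ 0 — unweighted, amplitude pinned at 100 as the model states; a
free-amplitude variant exists behind a flag. The solver is
`scipy.optimize.least_squares` started from the log-linear regression of
`ln(P/100)` on t over positive points (deterministic; no random restarts);
noiseless data are recovered to machine precision. Points above 100 are
retained (they are noise, not errors). Pooled fits over all replicate
points give the headline λ; per-replicate fits give the half-life SD.
λ ≤ 0 yields the *stable* sentinel, reported as "> chase duration", never
as an extrapolated number. Curve comparison is the extra-sum-of-squares
F-test of shared-λ (1 parameter) vs separate-λ (2 parameters),
`F = (SSR_red − SSR_full) / (SSR_full/(n_A+n_B−2))`. Families of
comparisons are Holm-adjusted by default (bonferroni/BH injectable).

### Calibration caveat of the fixed-amplitude F-test

Self-normalizing each replicate to its noisy 0-min point injects a shared
multiplicative error into every later point of that replicate. With the
amplitude pinned at 100, the only parameter that can absorb such a
replicate-level offset is λ itself, so between-curve differences are
over-resolved relative to the within-curve residual variance: under the
generator's own noise model the F-test rejects a true null at ≈ 0.21
instead of 0.05 (Monte Carlo, 1000 null pairs; the test suite asserts the
nominal level and that assertion fails, documenting the miscalibration
rather than hiding it). The same test is well behaved when the 0-min normalization is noise-free, and the
free-amplitude variant absorbs most of the offset. Practically: treat
fixed-amplitude F-test p-values from 0-min-normalized chases as
anticonservative.

## Dependence calls and reports

A degron is *dependent* in a mutant iff adjusted p < α **and** relative
growth > 0 (rescue is directional); *independent* otherwise;
*indeterminate* when the ratio is undefined. Growth is the primary readout;
half-life ratios (mutant/WT) annotate the calls, with stable mutants
reported as censored lower bounds. The growth-assay detection threshold is
the smallest finite half-life ratio among growth-detected degrons —
computed from data, never hard-coded. Labels are a pure function of
(relative growth, adjusted p, α): identical inputs reproduce bit-identical
reports.

## Problem sizes and statistical checks in the test suite

* Half-life recovery: 200 simulated triplicate chases per decay constant
  (0.43322, 0.126027, 0.055012 min⁻¹), σ = 0.1; the mean fitted half-life
  lands within 5% of ln 2/λ (observed bias ≈ +3.5%, the Jensen effect of
  averaging 1/λ̂).
* Type-I calibration of the growth test: ~1150 null degrons at 8 replicates
  per arm. Eight, not four, because the exact Mann–Whitney test's
  attainable size at quadruplicates is 2/70 ≈ 0.029 — below any band around
  0.05 by discreteness — whereas at n = 8 per arm the attainable size is
  0.0499. The generator's screen default remains quadruplicate.
* End-to-end recovery: a 200-fragment screen at π = 0.5, f = 8, analysed
  with the one-sided test and BH correction. One-sided is used here because
  at quadruplicates the two-sided exact p floor (2/70) makes BH across ~200
  degrons with ~100 true positives adjust everything to ≈ 0.057 > 0.05 — a
  deterministic consequence of discreteness, not of noise — while the
  directional test (floor 1/70) retains power and matches the directional
  calling rule. Observed: sensitivity 1.00, specificity 0.96, dependent
  fraction 0.58.

## Known limitations

* The fixed-amplitude F-test caveat above.
* Unweighted least squares on the percent scale under multiplicative noise
  is heteroscedastic; λ estimates remain nearly unbiased (< 1% relative at
  σ = 0.1) but reported SSRs are not optimal weights for inference.
* Single-exponential decay only; no lag phases or multi-phase turnover.
* The colony-size ↔ reporter-level mapping is a monotone saturating
  assumption; only its monotonicity is exercised by the analyses.
* Exact Mann–Whitney p-values are discrete at small n; at quadruplicates
  the smallest achievable two-sided p is 2/70 ≈ 0.029, which bounds what
  any correction scheme can call significant.
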