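# Methods

## Scope and model

The package analyzes ¹³C tracing experiments measured on nominal-mass GC-MS
instruments. The measurement model is: a metabolite pool with an unknown
tracer-labeling state is derivatized (MOX/TBDMS), a fragment of known
elemental composition is monitored at masses M+0..M+n (n =
tracer-accessible carbons of the parent metabolite), and the observed ion
areas mix three things — the labeling state, the natural isotope abundance
of *every* atom in the fragment, and detector noise. The analysis inverts
that mixing and summarizes the result per study design.

Assumptions:

* Unit (nominal) mass resolution. Fine isotope structure (¹³C vs ¹⁵N vs
  ²⁹Si at the same nominal shift) is collapsed, as on a quadrupole
  instrument scanning 100–650 a.m.u. High-resolution correction is out of
  scope.
* One tracer element (carbon). Multi-tracer correction is out of scope.
* Isotope abundances are the standard terrestrial values for C, H, N, O,
  Si and S, shipped as `tracermet/data/isotopes.tsv` and overridable; the
  fragment library (`fragments_example.tsv`) is a documented example set of
  common MOX/TBDMS fragments and is user-editable, since published fragment
  choices vary between laboratories.

## Correction matrix and solver

Column j of the correction matrix is the exact isotopologue distribution of
the fragment with j carbons removed from the natural pool (computed by
per-element multinomial expansion combined by discrete convolution),
convolved with Binomial(j, p) for tracer purity p. Purity correction is
**off** unless the sample sheet declares a purity (the natural-abundance
step alone is the classic published method; substrate purities such as 99%
glucose / 98% glutamine are only corrected when stated). Both modes are
tested.

The matrix is square by default — n+1 measured masses, which is what most
instrument methods acquire. Extra measured masses above M+n can be ingested
as additional rows (`extra_rows`), making the system overdetermined.

The solve is non-negative least squares (exact solution of the constrained
normal equations via an active-set method), not plain inversion: with noisy
data inversion produces negative fractions. Unconstrained inversion is
available as `method="ols"` for oracle comparisons. After solving, the MID
is renormalized to sum to 1 so downstream statistics always see proper
fractions; the residual norm and the probability mass removed by the
constraint are recorded per sample × metabolite, and residuals above 0.05
(configurable) flag the row in the QC table without aborting.

Distributions are truncated at n_carbons + 4 shifts internally where a cap
is needed; tail mass above 1e-6 is logged.

## Peak integration

The baseline model is a straight line through the trace values at the two
integration-bound endpoints — the minimal auditable choice given that only
"baseline correction" is ever specified for such pipelines; the functional
form is logged per peak. Integration is trapezoidal with interpolated
endpoint values, so results do not depend on whether a sample lands exactly
on a bound. Bounds are defined once per metabolite and applied to every ion
and every sample (consistency is structural, not per-sample). Negative
integrals clip to zero with a warning. Instrument exports that already
contain areas bypass this stage (pre-integrated mode).

## Quantities

* **Total contribution** TC = Σ i·mᵢ / (n·Σ mᵢ), dimensionless in [0, 1].
* **Level** = area / internal-standard area / biomass (mg); the denominator
  kind (protein vs tissue) travels with every value and cannot be mixed in
  a ratio.
* **Exchange rate** = (fresh − spent) µM · ml / (mg · h) in
  nmol·mg⁻¹·h⁻¹, uptake positive. The denominator is end-point biomass;
  time-averaged biomass integration is a documented alternative not
  implemented here because no growth model is part of the inputs.
* **Enrichment QC**: coefficient of variation of a reference compartment's
  TC across subjects (e.g. blood glucose enrichment across infused
  animals); default pass threshold 10%.

## Statistics

* The gate is a two-sided F-test on the variance ratio at the same α as
  the main test (default 0.05): below the gate → Welch, otherwise
  pooled-variance Student, both two-tailed. Degenerate inputs (zero
  variance in both groups) return p = 1 for equal means and p = 0, flagged,
  otherwise.
* Grubbs' test uses the t-quantile critical value
  G_crit = (N−1)/√N · √(t²/(N−2+t²)) with t = t₁₋α/(2N),N−2; at most one
  outlier is flagged per call and removal is always logged. At n = 6 even a
  genuine 6-s.d. point is not always detectable (the statistic is bounded
  by (N−1)/√N ≈ 2.04), which the measured detection rate reflects.
* The depiction filter retains a metabolite when the **relative change of
  the group mean** exceeds the threshold (25% for carbon contribution, 27%
  for levels) and p ≤ 0.05. The alternative reading — percentage-point
  difference — is available via `change_definition="absolute"`. No
  multiple-testing correction is applied, matching the replicated
  procedure; a Benjamini–Hochberg column is emitted as clearly labeled
  supplementary output only.
* ΔΔCt folds assume amplification efficiency 2 (perfect doubling),
  configurable; the reference gene defaults to RPL19.

## Synthetic data

The generator emulates: per-metabolite labeling states (binomial-mixture —
each carbon independently labeled with probability f — or two-pool), the
forward convolution of the true MID with the fragment's correction matrix,
multiplicative log-normal noise on ion areas (the standard MS intensity
noise model; additive drift available for chromatogram rendering), sample
sheets with jittered internal-standard areas and biomass, media fresh/spent
tables, and Ct tables with 0.15-cycle technical spread. The default study
mirrors a 2D-vs-3D contrast: two conditions × 3 replicates, ¹³C₆-glucose at
99% purity, 1% area noise, one proline-like metabolite whose contribution
and level are halved in 3D, a PRODH-like transcript 4-fold up in 3D
(ΔΔCt = −2), proline secretion in 2D turning to uptake in 3D, and five
planted nulls. A single master seed is fanned out per output section via
seed sequences, so regenerating one file never perturbs another.

What it does **not** emulate: chromatographic co-elution, retention-time
drift, detector saturation, missing values, batch effects, or biological
covariance between metabolites. Passing tests therefore demonstrate the
correctness of the computations and decision rules under the stated noise
model — not robustness to every pathology of real chromatography.

## Problem sizes and numerical choices

Validation uses 100 random MIDs for noise-free round trips (tolerance
1e-9), 1,000 simulated samples at σ = 1% for contribution recovery (mean
absolute error < 0.01), 10,000 null replicates for type-I calibration of
the gated test (empirical rate ≈ 0.05 at n = 5/group), 500 simulations for
filter sensitivity/specificity with ±50% planted effects at σ = 5%
(n = 3/group), and 1,000 draws for Grubbs rates. These sizes give binomial
standard errors comfortably below the decision margins while keeping the
whole validation in seconds. Exact enumeration (per-atom isotope
assignment) and simplex grid search serve as independent oracles for the
matrix and the solver at small sizes.

Ties and degenerate inputs: all-zero area vectors are rejected (undefined
MID); zero baseline means are skipped by the filter with a warning; the
Grubbs zero-spread case flags nothing.

## Known limitations

* No absolute quantitation (no calibration curves) — levels are relative.
* End-point biomass in exchange rates underestimates rates for fast-growing
  cultures.
* The square-matrix default discards information in masses above M+n when
  the instrument did acquire them; enable `extra_rows` in that case.
* The CLI's `analyze` recomputes levels from raw areas, so it requires the
  area table even when corrected MIDs are supplied.
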