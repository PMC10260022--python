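# Methods

This note documents the models behind each `tifmkit` module, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter.

## Medium formulation

A component enters the recipe iff it is commercially available at high
purity, stable in aqueous solution, and present in interstitial fluid (IF)
strictly above a threshold (default 0.5 µM; the comparison is strict, so a
metabolite at exactly 0.5 µM is excluded). Filtering is idempotent and
order-preserving; duplicate names are rejected by name. Pool membership
(ten separately compounded powder pools) is input metadata: the module
validates the ten-pool layout but does not optimize membership, since no
assignment rule exists to optimize against.

Electrolyte balancing is per-ion mass balance: for each tracked ion
(Na⁺, K⁺, Cl⁻, Ca²⁺, Mg²⁺, phosphate, sulfate), added salt equals the
RPMI-1640 reference total minus contributions from component counter-ions
(supplied as a data table of mmol ion per mmol component, because salt
forms vary by vendor and are not derivable from the metabolite itself) and
from serum. A requirement that goes negative cannot be compounded; the ion
and deficit magnitude are reported and the adjustment clamps at zero.
Feasible ions close the balance within 1e-9 mM. The result is expressed as
per-ion deltas, not specific salts: when several salt choices could realize
the same totals there is no basis for preferring one, so the module reports
the ion requirement and leaves the salt choice to the compounder.

Batch verification correlates measured against expected concentrations
(Pearson, on raw concentrations by default to match how such verifications
are conventionally plotted; log-scale is a flag) and reports per-metabolite
fold errors sorted by |log fold error|, worst first. At least three shared
metabolites are required for a meaningful correlation.

The packaged recipe table (`data/tifm_formulation_synthetic.tsv`) is a
**synthetic stand-in** for a complete published recipe: the component count
(115), the ten-pool structure, and anchor concentrations (citrulline 67 µM,
arginine 2 µM, glucose 1.9 mM) are faithful; the remaining entries are
representative IF-scale values, all above the selection threshold. Salts
and bicarbonate are tracked separately from the 115 metabolite components,
so totals with or without them are both computable.

## Absolute quantitation

Both quantitation routes assume a linear detector and that labeled and
unlabeled species of the same metabolite share a response factor (the
isotope-dilution assumption). Internal standards are themselves calibrated
against external standard dilutions: across the dilution runs the spike is
constant while the analyte steps through known concentrations c_i, so the
area ratio a_i/b_i = c_i/C. The default estimator regresses the ratio on
c_i through the origin (r² < 0.95 rejects the calibration); a single-point
mode averages c_i·b_i/a_i. Regression is the default because it uses all
levels and is robust to a single bad injection.

External curves are unweighted ordinary least squares of area against
concentration over ≥ 4 levels (1/x weighting is available as an option for
heteroscedastic detectors); a curve is usable iff r² ≥ 0.95, and inverse
predictions outside the calibrated range are returned flagged as
extrapolated rather than refused. Elution matching picks the internal
standard with minimum |Δretention time|, ties broken lexicographically by
standard name.

The extraction dilution (default 5 µL sample + 45 µL solvent, 10×) is
modeled explicitly on both the sample and the calibration side and cancels
symbolically when they share a protocol; asymmetric protocols scale by the
ratio of dilution factors.

## Consumption/release fluxes

Cell counts at two timepoints determine the exact exponential fit
k = ln(n₂/n₁)/Δt (three or more timepoints switch to log-linear least
squares, which reduces to the same answer at two points). The growth
integral is analytic, ∫N dt = (N₂−N₁)/k; for |k·Δt| < 1e-8 the
second-order series N₁Δt(1 + kΔt/2 + (kΔt)²/6) avoids cancellation and
makes the constant-population limit exact. The rate is
ΔC · V · 1000 / cell·days (1 µM·mL = 1000 pmol), **negative for
consumption** — a documented convention with a CLI flag to flip it.

Error propagation uses the first-order quotient formula
sem = |rate|·√((σ_ΔC/ΔC)² + (σ_cd/cd)²); at ΔC = 0 the concentration term
alone survives (sem = V·σ_ΔC/cd). A Monte-Carlo resampling oracle in the
test-suite confirms the formula within 5% at 10% CVs. Replicate experiments
average unspent and spent concentrations separately (their SEMs combine in
quadrature for ΔC) and average per-replicate growth integrals.

Metabolites below detection are carried as an explicit ND marker (NaN) and
refused by the rate calculation — never coerced to zero, since a
not-detected metabolite and an absent one are different claims. Media
volume is assumed constant over the 24 h window (media are replaced daily
in the emulated design); evaporation is not modeled. The glucose QC flags
cultures whose glucose availability dropped by more than 30% (strictly) of
the unspent level; apparent release always passes.

## Natural-abundance correction

For a formula with N tracer-element atoms and isotopologue window M+0..M+n,
column j of the correction matrix is the mass-shift spectrum of the species
with exactly j tracer atoms: the (N−j) unlabeled tracer-element atoms and,
by default, all non-tracer atoms draw from their natural isotope
distributions (per-element self-convolution, truncated at n); labeled
positions are excluded from the draw. A `tracer_only` switch restricts the
convolution to the tracer element. The matrix is lower-triangular (natural
abundance only shifts mass up) with column sums ≤ 1 (truncation).

Measured vectors are deconvolved by nonnegative least squares rather than
unconstrained inversion so that noisy data cannot produce negative
fractions (an unconstrained solve is available for diagnostics), then
normalized to sum to one. Round-trip identity correct(M·x) = x holds to
1e-9 across C₁–C₂₀ and N₁–N₄ tracer configurations; monoisotopic
abundances give exactly the identity matrix. Isotope abundances ship as a
versioned data table (IUPAC CIAAW 2021 representative values) and the
version is recorded in output metadata; the table is overridable.

Labeled fraction (1 − M+0) and synthesis fraction (the MID value at the
tracer-diagnostic shift, e.g. +5 for a 5-carbon labeled precursor) require
a corrected MID — uncorrected input is refused so the correction step is
always explicit. The synthesis-fraction read equals the de novo fraction
only at isotopic steady state with a fully labeled precursor; for
non-steady-state (bolus) designs the call is refused and only enrichment
*comparisons* are offered: per-isotopologue paired tissue-minus-plasma
differences with a one-tailed paired t statistic (n−1 df). A zero-variance
positive difference reports the smallest positive float rather than p = 0.

## Intratumoral concentrations

Tumor volume is the ellipsoid V = 4/3·π·A·B·C from caliper semi-axes (a
flag halves caliper diameters), density is mass/V, and concentration is
amount-per-mass × density (pmol/mg × mg/mm³ = pmol/µL = µM). The
denominator is whole-tissue volume — water plus solids, with no
intracellular/extracellular partitioning — which understates the aqueous
concentration; outputs carry this caveat. Density can be applied per-tumor
(default) or cohort-averaged. Tumor-vs-IF comparison reports per-metabolite
ratios with a two-tailed two-sample t test; with fewer than two replicates
in a group the ratio is reported and the statistic withheld (no degrees of
freedom).

## Assay scores

The IHC score weights positive pixels 1/2/3 by low/medium/high intensity,
normalizes by all pixels in the region (range [0, 3]), and averages regions
unweighted — each annotated region counts equally regardless of size, with
a pixel-weighted pooled variant as an option. Absolute scores depend on the
upstream classifier's intensity thresholds, which are consumed as given
class counts. ΔΔCt follows Livak: ΔCt = target − reference per sample,
ΔΔCt against the arithmetic-mean control ΔCt, expression = 2^(−ΔΔCt); the
control condition's geometric-mean expression is exactly 1 by construction.

## Synthetic data

Generators emulate the statistical structure each analysis assumes, with
defaults at the emulated study's scales: cultures seeded at 1e5 cells grow
at ln 2 /day in 2 mL, sampled at days 1 and 2; media anchors are citrulline
67 µM, arginine 2 µM and glucose 1.9 mM, with twenty generic metabolites at
0.8–2 mM carrying fluxes spanning [−5, +5] pmol/cell/day; anchor fluxes are
sized so that no nutrient depletes within the sampling window and glucose
stays inside its 30% QC margin. Dilution series span 5 mM → 1 µM in eight
log-spaced levels. Measurement noise is multiplicative lognormal with unit
median (concentrations and areas are positive; CV is the natural LC-MS
error scale); isotopologue channels use additive Gaussian noise clipped at
zero. Spent media follow the exact mass balance
spent = unspent + flux·cell·days/(V·1000), clipped at zero with a depletion
report. All randomness flows through one seeded generator; the seed is
recorded in the ground-truth sidecar and identical seeds reproduce outputs
bit-exactly.

At zero noise every generator/analysis pair is an exact inverse — that is
what the recovery tests demonstrate. What they do **not** demonstrate:
real chromatographic peak integration, retention-time drift, matrix
effects, detector saturation, metabolite degradation in blank media, or
biological replicate variability beyond the stated noise models. Passing
tests certify the computations, not the chemistry.

Test and acceptance problem sizes (20 metabolites, 6 replicates, 200
seeded repetitions for SEM coverage; ~1,000 random MIDs across nine
formulas for the round-trip identity) were chosen as the smallest sets
that exercise the full dynamic range of the emulated designs while keeping
the whole suite fast enough to run on every commit.

## Known limitations

- Electrolyte balancing reports ion deltas, not named salts; osmolarity
  beyond the tracked ions is out of scope.
- The correction matrix assumes nominal mass resolution (isotopologues
  indexed by integer mass shift); resolution-dependent fine structure is
  not modeled.
- No kinetic flux modeling: labeling timecourses are not fit to ODEs, and
  bolus-labeling data only support enrichment comparisons.
- Co/Re assumes constant per-cell flux and constant volume across the
  sampling window; intracellular pools are not modeled.
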