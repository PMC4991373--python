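# Methods

## Quantification model

qPCR reports expression as a threshold cycle Ct, inversely proportional to
log template abundance with slope −1/log(E), where E ∈ (1, 2] is the
per-cycle amplification base. Throughout the package efficiency is
expressed as a *percentage of perfect doubling*, percent = 100·E/2, so that
E = 1.7 ↔ 85% and E = 1.75 ↔ 87.5% (≈88%). This is not the more common
E = 1 + e convention; it is adopted because it is the convention the
80%-efficiency exclusion cutoff is stated in, and the two conventions
disagree exactly in the range (1.6–1.8) where miRNA assays live.

The quantification chain per sample i and target miRNA is

    Ct0(i)  = Σ_j w_j Ct_j(i)
    ΔCt(i)  = Ct_miR(i) − Ct0(i)
    ΔΔCt(i) = ΔCt(i) − mean{ΔCt over control samples}
    FC(i)   = E^(−ΔΔCt(i)),  log2FC(i) = log2 FC(i),
    centered_log2FC(i) = log2FC(i) − mean{control log2FC}.

ΔΔCt is computed per sample against the control-group *mean* ΔCt (not group
mean vs group mean), so that per-patient fold changes exist for t-tests,
outlier testing, ratio biomarkers and ROC analysis.

### Weighted-mean reference

Vitreous humour has no established housekeeping miRNA, so the reference is
a weighted mean of several panel miRNAs (default members miR-16, miR-106b,
miR-146a, miR-152), with weights inversely proportional to each member's
across-sample Ct standard deviation raised to the weighted-mean power wmp:

    w_j = (1/SD_j)^wmp / Σ_k (1/SD_k)^wmp,  default wmp = 1.

The normalization (weights summing to 1) is the only reading of the
weighted-mean formula that reduces to the plain arithmetic mean at equal
SDs and at wmp = 0; both reductions are property-tested. Samples in which
any member is undetected cannot anchor the reference and are excluded with
a logged reason. Plasma uses the single-reference mode (Ct0 = Ct of
miR-16), which is the degenerate weighted mean with one member.

Note a structural consequence: because the reference set contains
disease-regulated members, the reference itself shifts between groups, and
miRNAs that are truly null (e.g. miR-16) acquire an apparent fold change.
This is a property of the normalization scheme, not a bug; the round-trip
parameter-recovery tests therefore invert the generator through the
single-miR-16 reference, while the ratio biomarker is unaffected either way
(Ct0 cancels in the ratio of two fold changes of the same sample).

### Centering

The log2 fold changes are centered by subtracting the control-group
arithmetic mean per miRNA (so the centered control mean is exactly 0).
A median-centering option exists behind `center="median"`; the mean is the
default because it is the operational formula stated with the procedure,
even where the surrounding prose says "median-centered".

## Amplification curves

`simulate_curves` uses a saturating-exponential model
F(c) = Fmax·F0·E^c/(Fmax + F0·E^c) + baseline + noise with F0 set so the
pure-exponential phase crosses the detection threshold at the recorded Ct.
Defaults (threshold 1.0, Fmax 10, baseline 0.05, Gaussian noise off) give
realistic-looking traces; `fmax=inf, baseline=0` is the exact exponential
limit used in exactness tests.

### Ct calling

Baseline (median of the first 5 cycles) is subtracted and the fractional
crossing cycle is interpolated *linearly in log fluorescence* between the
bracketing cycles, consistent with exponential growth; a crossing exactly at
an integer cycle returns that integer. Traces that never cross within the
40-cycle detection limit are UNDETECTED (NaN); a trace that crosses without
any rising stretch leading into the crossing (no discernible exponential
phase) raises a QC error. The saturating model crosses slightly later than
its pure-exponential asymptote (≈0.1–0.2 cycles at the default Fmax), which
is within the tolerance used everywhere Ct values are compared.

### Efficiency estimation (window of linearity)

The per-reaction base is 10^slope of a least-squares line over a sliding
window (default 6 cycles, minimum 4) on transformed log10 fluorescence. Two
nuisance parameters are profiled out by maximizing window linearity:

- **Baseline.** A constant offset b is chosen to maximize the best-window
  R² of log10(F − b), searched on a grid bracketed by [0, min(F)] and
  refined with bounded scalar minimization. A fixed early-cycle median
  leaves a residual (the growing exponential leaks into the median) that
  visibly biases the slope on clean traces; the optimized offset recovers a
  noise-free exponential's base to ~1e-8.
- **Plateau.** Candidate plateau levels Fmax ∈ {∞} ∪ peak/{0.999 … 0.6}
  are tried with the transform y = log10(F) − log10(1 − F/Fmax), which
  back-extrapolates the exponential component of a saturating trace. The
  plain-log candidate (Fmax = ∞) wins on unsaturated traces; on saturating
  traces the correction removes the downward slope bias that otherwise
  reaches ~0.1 on the base.

Window selection: among windows within 0.005 R² of the maximum, the one
with the *steepest* slope is taken. Pure max-R² selection drifts into the
saturating phase (smooth, hence linear-looking, but flattened); the true
exponential phase is the steepest log-linear stretch. A best-window R²
below the configurable floor (default 0.98) defines a "weak amplification
curve" and flags the reaction for exclusion; the floor is a design constant
because no numeric criterion for weakness is established.

`plate_efficiency` aggregates per-reaction bases by mean or median into one
base per plate/assay (the default, mirroring the single global base per
assay type) or per miRNA (`per_mir`).

## Quality control

Exclusion order is fixed and every exclusion carries one machine-readable
reason code: (1) undetected reactions (Ct past 40 cycles); (2) efficiency
below the cutoff (default 80% of perfect doubling, i.e. base 1.6);
(3) plasma samples with hemolysis index strictly above 1 (index exactly 1
is retained; a missing plasma index is excluded conservatively; vitreous
samples are untouched); (4) samples whose clinical flags intersect a
configurable blocklist (default: glaucoma, eye medical treatment);
(5) a Grubbs single-outlier pass on per-group centered log2 fold changes.

The Grubbs test uses G = max|x − mean|/s (sample SD) against
G_crit = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) Student-t quantile
on n−2 df — the classic two-sided single-outlier calculator. It is
non-iterative by default (one outlier per pass); an iterative mode repeats
on the reduced set. Flagging removes that miRNA's fold change for the
sample, not the whole sample.

## Group statistics and the ratio biomarker

The group test is a pooled-variance two-sided Student t on centered log2
fold changes (Welch behind a flag; which variant produced any given
published p is usually unstated, so both are supported). Zero-variance
degenerate inputs return p = 1 (equal means) or p = 0 with a warning.
Summaries report both mean-of-linear-FC ± SEM and mean-of-log2 ± SEM; the
two are mutually inconsistent under averaging (log of a mean ≠ mean of
logs) and no attempt is made to force agreement. Age confounding is
assessed as Pearson r² between age and per-sample fold change.

The ratio biomarker is the per-sample ratio of *linear* fold changes
(numerator default miR-146a, denominator miR-106b); higher ratio = more
case-like, and an AUC below 0.5 is reported as-is, never auto-flipped
(silent flipping masks sign errors). AUC is computed by midrank
Mann–Whitney pair counting (ties count ½), which equals the trapezoidal
area under the empirical ROC exactly (property-tested, and cross-checked
against an independent implementation). The CI is Hanley–McNeil
(Q1 = A/(2−A), Q2 = 2A²/(1+A)) with a plain normal interval *not truncated
at 1* — at AUC 0.977 with 13 vs 13 the upper bound is ≈1.04, the signature
of this estimator at high AUC and small n; DeLong is intentionally not the
default. The p-value against AUC = 0.5 uses the normal approximation to U.

## miRSNP filtering

Coordinates are 1-based inclusive internally; BED input (0-based half-open)
is converted at the parsing boundary, avoiding off-by-one at interval ends.
Motif overlap is point-in-interval containment with chromosome-name
normalization ("chr6" ≡ "6", warned when mixed), backed by an interval
tree and verified against a brute-force double loop. Strand is ignored (a
point variant against an interval). Prediction-score thresholds
(microT-CDS > 0.70, miRDB Target Score > 80) are input filters applied
upstream or at load, not recomputed.

- **Phase 1** enumerates motif regions and their resident SNPs.
- **Phase 2** tests motif-resident SNPs at α = 0.05/√N per motif-encoding
  region. The √N adjustment is neither Bonferroni nor Šidák; it is applied
  exactly as stated, with a conventional 0.05/N mode behind
  `phase2_mode="bonferroni"`.
- **Phase 3** widens to all SNPs in each miRNA's target-gene set, flags
  p < 0.005, and reports Bonferroni-adjusted p and Storey q-values computed
  *within that miRNA's gene-set SNP pool* (the pooling choice is ambiguous
  in general; per-miRNA pools are documented as this package's choice).

LD proxies (r² strictly > 0.80; 0.80 exactly is not a proxy) are attached
single-hop with provenance; a proxy of a proxy is never chained. Proxies
inherit the source SNP's p-value and need explicit coordinates to enter
overlap.

Storey q-values use the step-up sweep q_(i) = min_{j≥i} π0·m·p_(j)/j; with
π0 = 1 they coincide with Benjamini–Hochberg to machine precision (tested
against statsmodels). π0 is estimated on the λ-grid 0.05…0.95 with a cubic
polynomial smoother evaluated at λ = 0.95 (a polynomial stands in for the
df-3 smoothing spline of the reference q-value implementation; on uniform
or near-uniform p-value panels the two agree to well within the precision
that matters for q < 0.05 calls), clamped into (0, 1] with a warning.

## Synthetic cohorts

`simulate_cohort` draws Ct = base_ct − log_E(abundance) + ε, ε ~ N(0, σ),
with abundance multiplied by the configured fold effect for cases. Noise is
additive Gaussian on the cycle (log-abundance) scale, matching the
multiplicative error structure of qPCR and making t-tests on log2 fold
changes well-specified. Ct values past 40 cycles are recorded as
undetected by truncation — no separate dropout process. Defaults encode
the study conditions the package is exercised under: 13 + 13 samples, panel
{miR-146a, miR-106b, miR-152, miR-16, miR-205, miR-548a}, fold effects
3.02 / 0.23 / 0.33 for the three disease miRNAs and 1.0 for the rest, base
1.75, three replicates per reaction, and σ = 1 cycle. The within-group Ct
SD of real cohorts is not established; 1 cycle is a realistic figure for
patient-to-patient biological plus technical variation in body-fluid miRNA
qPCR and is the package's default, not a measured value. The hemolysis
index is a lognormal covariate independent of group (σ = 0.5, location set
so the configured fraction exceeds 1), because it functions purely as an
exclusion criterion. Base Ct levels (20–32 by miRNA) keep all default
reactions detected; pushing base_ct near 40 exercises the truncation path.

What the generator does *not* emulate: plate/batch effects, replicate-level
efficiency drift (available but off by default), hemolysis-correlated
miRNA contamination, non-Gaussian heavy-tailed noise, and array-stage raw
data (the array stage is represented only as a Ct table). Passing tests
therefore demonstrate correctness of the analysis chain under the stated
error model, not robustness to every artifact of real instruments.

Under σ = 1 cycle the mean of per-sample *linear* fold changes is biased
upward by the lognormal factor exp(σ_ΔΔCt²·ln²E/2) ≈ 1.1; recovery checks
on the linear-mean scale use a 20% band for this reason, while noise-free
recovery is exact to machine precision.

## Problem sizes used in the standard checks

Parameter-recovery and AUC calibration run 200 replicate cohorts of
13 + 13 samples; type-I calibration runs 1000 null cohorts on a reduced
two-miRNA panel with one replicate (the t-test's calibration does not
depend on the panel width). The acceptance script reruns the same
computations from scratch with the caller's seed; all randomness flows
through numpy Generators seeded from that one integer.

## Known limitations

- The weighted reference with disease-regulated members biases absolute
  fold changes (see above); reference-free quantities (ratios) or a
  validated single reference are preferred for effect-size estimates.
- Hanley–McNeil intervals at high AUC/small n exceed 1 by construction.
- The efficiency estimator assumes a single smooth saturating phase; it has
  no multi-component dye correction, ROX normalization or melt analysis.
- The hemolysis index is an opaque input; the package does not compute it
  from absorbance or miR-451/miR-23a ratios.
- Phase 2's √N adjustment does not control FWER at 0.05 for N > 1; it is
  reproduced for fidelity, with the conventional adjustment available.
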