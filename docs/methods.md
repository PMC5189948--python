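# Methods

## Scope and data model

`stresscycle` implements the downstream quantitative analysis of a bacterial
stress-response study design: (1) comparing stress transcriptomes by the
overlap of their directional fold-change gene sets, (2) estimating protein
half-lives from translation shut-off immunoblot time courses, and
(3) comparative-Ct qRT-PCR and ChIP-qPCR quantification. The pipeline starts
from per-gene fold-change (or paired expression) tables, band-intensity time
courses, and Ct tables; read alignment, count normalization and
densitometry are upstream of it and out of scope.

## Directional gene sets and the overlap z-score

A comparison (stress vs non-stress) is reduced to an up-set
{g : FC(g) > 2} and a down-set {g : FC(g) < 0.5}. Both inequalities are
strict, so genes exactly at a cutoff are left unclassified; the cutoffs are
tunable but must satisfy up > 1 > down > 0. Genes with missing or
non-positive expression/ratios are excluded before classification and the
exclusion count is carried on the table.

Similarity between two comparisons is the intersection of like-directed
sets measured against a random-intersection null: draw a uniform random
subset of size n1 and, independently, one of size n2 from the N-gene
universe, record |A ∩ B|, repeat `n_mc` times (default 10,000), and report

    z = (k_observed − null_mean) / null_sd,

with the sample mean and n−1 sample standard deviation of the Monte-Carlo
draws. Both sets are redrawn every iteration; conditioning one set fixed
would give the identical marginal null, which makes the choice auditable
against the closed form. That closed form is the hypergeometric law of the
intersection of independent uniform subsets:

    E[k] = n1 n2 / N,
    Var[k] = n1 n2 (N − n1)(N − n2) / (N² (N − 1)),

exposed as `analytic_intersection_zscore` and used throughout the tests as
the independent oracle for the Monte-Carlo path (and itself checked against
exact rational enumeration of the pmf). A degenerate null (sd = 0, e.g. an
empty set or a saturated universe) is reported with an explicit flag rather
than a NaN or infinite z. z is signed: depleted overlaps come out negative
even though published similarity analyses typically only show enrichments.

The default null universe for a pair of data sets is the genes measured in
*both* (so RNA-seq can be compared fairly against microarray data);
`universe="union"` is available. The down-direction Monte-Carlo stream uses
seed + 1 so one integer seed reproduces a whole two-direction run.

## Half-life estimation

Each replicate trace is normalized to its own t0 band, replicates are
averaged pointwise (mean ± sample sd), and ln(mean) is regressed on time by
OLS with a free intercept; k = −slope and t1/2 = ln 2 / k. The free
intercept absorbs loading error at t0. A non-negative slope is reported as
k = 0, t1/2 = ∞ with a `stable` flag — the behaviour expected for a
stabilized protein (e.g. under carbon starvation) — never as a negative
rate. `per_replicate=True` instead fits each trace and reports the mean
half-life with the replicate spread in a flag; for noiseless input both
modes coincide.

Numerical choices: zero intensities at t > 0 (bands below blot background)
are floored to 1e−6 of t0 rather than dropped, keeping the log defined
while preserving the time grid; a fit in which more than 30% of points were
floored is flagged `low_confidence`. At least 3 time points are required.
Unequal grids (every-10-min or the dense 0,3,6,9,12,20,30-min schedule) are
supported without interpolation. No plateau term is fitted: the model is a
two-parameter single exponential.

## qPCR arithmetic

All formulas assume perfect amplification efficiency (factor 2 per cycle).

* Relative expression: ΔCt = Ct(target) − Ct(reference) per condition,
  ΔΔCt = ΔCt(treated) − ΔCt(control), fold-change 2^(−ΔΔCt). The reference
  is an endogenous control such as 16S rRNA.
* Percent of input (ChIP): only a fraction f of the input chromatin is
  assayed (default f = 0.05), so the input Ct is adjusted by
  −log2(1/f) cycles to represent 100% of the chromatin; recovery is
  100 · 2^(adjusted_input − Ct_IP). This subtraction is the unique
  base-2-consistent reading of the dilution adjustment.
* Relative occupancy: percent-of-input under a condition as a percentage of
  the baseline percent-of-input.

Technical triplicates are averaged to a mean Ct before any formula; their
spread is propagated (root-sum-square of the standard errors, still at
efficiency 2) to a multiplicative uncertainty band on the fold-change.

## Synthetic data: what it emulates, and what it does not

`simulate_regulon_pair` plants a shared regulon in two fold-change tables
over an N = 4000-gene universe (roughly a small bacterial genome). Planted
genes get ratio 2^x with x ~ Normal(±2.0, 0.3) in log2 units; background
genes get x ~ Normal(0, 0.3). Defaults (350 shared up + 120 specific,
200 shared down + 80 specific) put ≈470 genes in each up-set and ≈280 in
each down-set — the magnitudes seen when two membrane stresses shut down a
master-regulator regulon — and yield overlap z-scores in the 40s. Shared
genes occupy the same positions in both tables; condition-specific genes
are drawn independently per condition, so setting the shared counts to zero
produces exactly the hypergeometric null and is how the z-score is
calibrated (mean ≈ 0, sd ≈ 1 across seeds). Log-normal effects were chosen
because fold-changes are ratios. The generator does not emulate count
noise, replicate structure, or correlated operon expression, so passing
tests say nothing about differential-expression calling upstream.

`simulate_decay` draws intensity(r, t) = exp(−ln2·t/t1/2)·ε with ε
log-normal, mean 1, CV given (default 0.10), independent per replicate and
time point including t = 0. Bands below a detection limit (default 1e−5 of
the initial signal) are recorded as 0, reflecting the finite dynamic range
of blot densitometry; on a sparse 10-min grid this censors the tail of a
2-min half-life and flags the fit low-confidence, which is why short
half-lives require the dense early schedule. The generator does not model
loading-control error or band-overlap artifacts.

`simulate_ct_table` produces treated/control Ct triplicates from known
template ratios at Ct = base − log2(template) plus Normal(0, sd) cycle
noise, with a unit-template reference amplicon.

Problem sizes used by the test suite and the acceptance script (50,000
Monte-Carlo draws × 20 seeds for oracle agreement; 500 seeds × 500 draws
for null calibration; 200 simulations per half-life) were chosen to keep
Monte-Carlo error well below each assertion's tolerance.

## Known limitations

* The overlap null treats genes as exchangeable; operon and regulon
  structure in real genomes makes random-set nulls anti-conservative, which
  is a property of the method being implemented, not corrected here.
* Amplification efficiency is fixed at 2; no standard-curve correction.
* The half-life fit is unweighted on the log scale, so late, noisy,
  near-background points carry disproportionate leverage; the flooring flag
  marks the worst cases but does not reweight.
* Signed z-scores are only asymptotically normal; for very small universes
  use the analytic method and the exact hypergeometric moments.
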