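# Methods

This note records the modelling decisions behind `symptomnet`: what
each stage assumes, which tunables matter, what the synthetic generator
does and does not emulate, and where the numerics required a choice.

## Input contract

The raw input is a complete person × item table of integer ratings in
1–5. Missing cells are a hard error: the pipeline is a complete-case
analysis and performs no imputation, so any missingness handling must
happen upstream and explicitly. Estimation entry points additionally
require `n ≥ p + 1` rows. Categorical covariates are reference-coded
into indicator columns at read time (e.g. treatment contrasts against
medication), so regression output and covariate nodes align with the
contrasts a clinical reader expects.

## Association stage

Spearman rank correlation with average ranks is used for every pairwise
association, including binary and continuous covariate columns.
Severity ratings are heavily skewed and ordinal, so a rank-based
measure is the defensible default; with 5 categories, ties are
universal, which is why the average-rank convention is fixed rather
than configurable. A Spearman matrix of discretized data can be
indefinite; the repair clips negative eigenvalues at zero and rescales
to unit diagonal. The repair is a no-op (bitwise) on matrices that are
already PSD. Shrinkage-based repairs were considered and rejected:
clipping is the smallest intervention and the repaired matrix is only
ever used as the loss input of a penalized estimator.

## Network estimation

The estimator is the graphical lasso with the **off-diagonal-only**
penalty (the diagonal of the working covariance stays at `diag(S)`);
this matches the convention of the reference implementations and makes
the two-variable case reduce exactly to the marginal correlation as the
penalty vanishes. The solver is a numba-compiled block coordinate
descent (one lasso per column of the working covariance), warm-started
along the penalty path; its solutions satisfy the KKT conditions of the
convex program to ~1e−13 on test problems and are cross-checked in the
suite against an independent ADMM solver (to 1e−5) and sklearn's
implementation.

EBIC selection uses γ = 0.5 (the conventional default; γ = 0 reduces
to BIC) over 100 log-spaced penalties with min-ratio 0.01. The
likelihood inside EBIC is measured relative to the saturated model,
`ℓ = (n/2)(log det Θ − tr(SΘ) + p)`; the additive constant cancels in
model comparison and makes the empty-model value exactly zero. An edge
"exists" when its partial correlation exceeds 1e−8 in magnitude — a
pure solver-noise threshold, not a substantive cutoff — and that count
defines both the EBIC penalty and the reported density. Ties on EBIC
resolve to the larger penalty (sparser model). Estimation is fully
deterministic: randomness exists only upstream (data) and downstream
(resampling, layout seeds).

Covariate adjustment appends the screened covariates as nodes rather
than residualizing the items, so the adjusted network's symptom–symptom
edges are partial correlations conditioning on the covariates, and the
adjusted density is reported over all `(p+c)(p+c−1)/2` pairs.
Centralities in the adjusted network are computed on the full graph and
reported for the symptom nodes.

### A known operating characteristic of EBIC selection

On data with weak true edges near the resolution limit, EBIC lowers the
selected penalty to capture them and thereby admits small spurious
edges; the false-positive rate of the selected support *grows* with n
in that regime. This is a property of the selection rule, not of the
solver — sklearn's graphical lasso run over the same path with the same
criterion selects the identical penalty. The support-recovery checks in
the test suite therefore use a block-structured sparse truth whose
edges are comfortably above the resolution limit; with weak
between-cluster "bridge" edges present, expect extra tiny
false-positive edges at large n.

## Centrality and layout

Strength and expected influence are simple (absolute vs signed) row
sums. Closeness and betweenness need a path metric: edge length is
`1/|w|`, the standard convention in network psychometrics, and
closeness is `(m−1)/Σ_j d(i,j)` over reachable pairs (an unreachable
pair contributes nothing; the disconnection is flagged). Betweenness
follows the Brandes convention of fractional shares over equal-length
shortest paths rather than raw counts — equal-weight ties would
otherwise be double-counted. Core symptoms are ranked by raw strength,
descending, with lexicographic tie-breaks (flagged); the multi-index
view (closeness, betweenness, expected influence) is always computed
alongside, since strength alone can be blind to bridging roles.
Z-standardization uses the n−1 divisor, and a zero-variance index
yields all-zero z-scores with a flag instead of NaNs.

The Fruchterman–Reingold layout delegates to networkx's seeded
spring layout with attraction proportional to `|w|`, rescaled to the
[−1,1] square. Coordinates are deterministic given (network, seed).

## Resampling

Edge accuracy uses the nonparametric bootstrap (resample rows with
replacement, re-estimate everything including the penalty, take the
2.5%/97.5% quantiles). Stability uses case-dropping subsampling
*without* replacement over drop proportions 0.05–0.75 (step 0.05, 250
subsamples each by default): the CS coefficient is the largest drop
proportion at which ≥ 95% of subsamples still correlate ≥ 0.7
(Pearson, across nodes) with the full-sample index — the published
convention behind the 0.25/0.5 interpretation thresholds. When the
full-sample index is degenerate (e.g. an empty network on noise data),
no subsample can reach the correlation threshold, so CS is 0 and the
result is flagged degenerate/unstable.

Difference tests compare bootstrap distributions of pairwise
differences (edge–edge, or strength–strength); a pair is flagged when
the 95% quantile interval excludes zero, deliberately without
multiplicity correction (the convention for these descriptive panels).
Calibration on planted-equal edges runs at roughly the nominal rate
(measured ≈ 8–15% across seed batches at 300 bootstrap replicates —
percentile intervals on regularized estimates are mildly
anticonservative).

Per-replicate seeds derive from the root seed by counter
(`SeedSequence([seed, tag, replicate])`), so serial and parallel
execution, and re-runs, give bit-identical reports. Replicates whose
estimation fails (e.g. a resample makes an item constant) are skipped
and counted; more than 5% failures aborts the procedure.

## Predictability

Per node, the item is regressed (OLS, treating ratings as numeric,
consistent with the latent-metric view of Likert data) on its
estimated-network neighbors; `R² = 1 − RSS/TSS`, clipped to [0,1],
with categories ≤ 0.30 external-driven and ≥ 0.65 network-embedded.
Two deliberate simplifications: neighbors come from the already
estimated network rather than a separately penalized nodewise refit
(for all-numeric items the mixed-graphical-model nodewise regression
reduces to exactly this, and it keeps one network as the single source
of structure); and R² is in-sample by default (the usual convention of
nodewise-predictability tooling), with a 10-fold cross-validated
variant behind a flag —
at the sample sizes involved the optimism is small, and the suite
checks the two agree closely at n = 2000.

## Severity regression and power

The dependent variable is the **sum of the severity ratings** (range
p–5p) -- the natural total-severity score for an item set rated on a
common scale, documented here as the package's choice.
Standardized β is `B·sd_x/sd_y`; VIF_j is `1/(1−R²_j)` from regressing
predictor j on the others (cross-checked in the suite against explicit
auxiliary regressions). Diagnostics — slope of |residual| on fitted
values as a heteroscedasticity proxy, Jarque–Bera normality, max VIF —
are reported as flags, never hard failures, mirroring the visual checks
they stand in for. Screening defaults to the stringent α = 0.001 but
takes the threshold as explicit configuration, since published analyses
sometimes admit a covariate at a laxer level.

Post hoc power of the overall F test uses the noncentral F with
noncentrality λ = f²·N (the G*Power "fixed model, R² deviation from
zero" convention) and df (u, N−u−1). At u = 13, f² = 0.15, α = 0.001,
N = 324 this gives **0.9685** (Monte-Carlo-confirmed to four decimals
by the test suite).

## Synthetic data

The generator is a latent Gaussian copula: latent scores from a
zero-mean Gaussian with a known sparse precision matrix (standardized
to unit variances), optionally shifted additively by covariate effects,
then discretized through four strictly increasing per-item thresholds.
This is the simplest mechanism whose regularized partial-correlation
network has an exactly known target. Design choices:

- **Structure.** Five clusters sized (2, 6, 3, 3, 4) for the 18-item
  default, dense within clusters (precision off-diagonal −0.20, i.e.
  positive partials) and sparse between (−0.10 at 10% density).
  Positive-dominant weights by default; negatives via a flag.
- **PD repair.** If the assembled precision is not positive definite,
  the diagonal is inflated additively by 1.05× the spectral deficit —
  an additive (not multiplicative) shift because it preserves the
  off-diagonal support and values exactly; the inflation is recorded on
  the truth object.
- **Marginals.** Per-item floors (category-1 mass) spread over a range,
  with the remaining mass decaying geometrically, yielding means
  roughly 1.3–2.7 and floor-heavy distributions. For the study-like
  18-item truth, the floor ordering follows the prevalence ordering an
  IBD cohort reports (fatigue and disturbed sleep common, anal fissure
  rare), and floors are steepened to compensate for the rating mass the
  covariate shifts add.
- **Covariates.** Binary active stage (58%), log-normal years since
  diagnosis moment-matched to mean 5.36 / sd 5.77, 4-level treatment
  factor at the cohort shares, reference-coded against medication.
  Effect sizes are calibrated so the severity regression recovers
  standardized effects near 0.45/0.24/0.11 for stage, duration, and
  the untreated group — the study-sized signal the screening stage is
  meant to detect.

What the generator does **not** emulate: exact cohort item means or
regression coefficients (not reproducible and not targeted),
longitudinal structure, informative missingness (the pipeline is
complete-case by contract), differential item functioning, and any
non-Gaussian latent dependence (e.g. tail dependence between symptoms).
Passing tests therefore demonstrate correct recovery *under the copula
model*, not robustness to violations of it.

## Problem sizes in tests and the acceptance script

The resampling defaults (1000 bootstrap replicates, 250 subsamples per
drop proportion) are the recommended analysis settings. The test and
acceptance runs use scaled sizes chosen as adequate for the properties
they check — 40-penalty paths for resampled refits, 100–300 bootstrap
replicates, 100 subsamples per drop, p = 10 truths at n = 2000 for
recovery, 40 seed replicates for calibration — keeping each suite in
the minutes range on a single CPU while leaving every qualitative
conclusion unchanged at full size.

## Known limitations

- The EBIC false-positive behavior near the resolution limit (above).
- Bootstrap percentile CIs on regularized edges inherit the estimator's
  shrinkage bias; they quantify sampling variability, not unbiased
  coverage of the true partial correlation.
- The "distinctiveness" of a node beyond pairwise strength difference
  tests has no agreed formula and is not computed.
- Closeness on disconnected graphs uses the reachable-pairs convention
  and flags the disconnection; comparing closeness across networks with
  different connectivity is then not meaningful.
- Polychoric correlations (an alternative to Spearman for ordinal data)
  are out of scope.
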