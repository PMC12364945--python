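# symptomnet

Regularized partial-correlation **symptom networks** for ordinal
severity ratings, with the full inferential toolkit used in clinical
symptom-network studies: covariate screening, centrality-based
core-symptom identification, bootstrap accuracy/stability checks, and
node predictability. The package was built around the contemporaneous
symptom-network analysis of inflammatory bowel disease (IBD) cohorts
rated on the 18-item SCS-IBD (5-point Likert severity), but every stage
is generic over any person × item table of 1–5 ratings.

## Who this is for

Researchers analysing co-occurring symptoms (or any ordinal item set)
who want to know *which symptoms sit at the core of the network* — the
ones whose severity is most entangled with everything else — rather
than merely which are most frequent, and who need the standard
robustness evidence (bootstrap CIs, correlation-stability coefficients,
difference tests) to report alongside.

## The model

Given ratings `X ∈ {1..5}^{n×p}`:

1. **Association.** Pairwise Spearman ρ (average ranks for ties, since
   5-point data guarantees ties), repaired to positive semidefinite by
   eigenvalue clipping when needed.
2. **Network estimation.** Graphical lasso over the correlation matrix
   `S`:

   `Θ̂(λ) = argmax  log det Θ − tr(SΘ) − λ Σ_{i≠j} |θ_ij|`

   solved by block coordinate descent over a path of 100 log-spaced
   penalties from `λ_max = max_{i<j}|S_ij|` down to `0.01·λ_max`.  The
   penalty is selected by the extended Bayesian information criterion

   `EBIC(λ) = −2ℓ(Θ̂) + E log n + 4 E γ log p`,  γ = 0.5,

   where `E` is the number of nonzero edges. Edge weights are the
   partial correlations `w_ij = −θ̂_ij / √(θ̂_ii θ̂_jj)`; network
   density is `E / (m(m−1)/2)`.
3. **Covariate adjustment.** Covariates passing a multivariable
   regression screen of total severity (default α = 0.001, with VIF and
   residual diagnostics) enter the network as **extra nodes**, so the
   symptom–symptom edges condition on them.
4. **Centrality.** Strength `Σ_j |w_ij|`, expected influence
   `Σ_j w_ij`, and closeness/betweenness on shortest paths with edge
   length `1/|w|`. The highest-strength symptoms are the core symptoms.
5. **Resampling.** Nonparametric bootstrap edge CIs; case-dropping
   correlation-stability (CS) coefficients (≥ 0.25 minimal, ≥ 0.5
   strong stability); uncorrected bootstrapped difference tests for
   edges and node strengths.
6. **Predictability.** Per node, the variance share `R²` explained by
   its neighbors (≥ 0.65 network-embedded, ≤ 0.30 externally driven).

A synthetic-data module generates ordinal cohorts from a latent
Gaussian copula with a *known* sparse precision matrix (5-cluster
SCS-IBD-like structure, floor-heavy marginals, covariate effects on
severity), so every stage is testable against ground truth without any
external data.

## Worked example

The `analysis/` scripts run the whole study-shaped analysis on a
simulated cohort (n = 324, 18 items, seed 7):

```
python analysis/01_simulate_cohort.py
python analysis/02_screen_covariates.py
python analysis/03_estimate_networks.py
python analysis/04_bootstrap_stability.py
python analysis/05_support_recovery.py
```

Step 02 prints the covariate screen — active disease stage and disease
duration carry the severity signal and pass the stringent α:

```
severity model R^2 = 0.317 (n=324)
                            B   beta      p  ...    vif
active_stage           18.377  0.474  0.000  ...  1.007
years_since_diagnosis   1.272  0.287  0.000  ...  1.002
...
selected at p < 0.001: ['active_stage', 'years_since_diagnosis']
post hoc power (u=13, f^2=0.15, alpha=0.001, N=324): 0.9685
```

Step 03 estimates both networks and names the core symptoms:

```
unadjusted network: 18 nodes, 85/153 edges (density 55.56%), lambda=0.0201
  core symptoms by strength: abdominal_distension (1.329), bloody_purulent_stool (1.294), ...
  strongest edge: abdominal_distension--bloody_purulent_stool (w=0.545)
adjusted network: 20 nodes, 109/190 edges (density 57.37%), lambda=0.0201
```

(the density fraction is the share of possible edges surviving the
EBIC-selected penalty; the core symptoms are this simulated truth's
densest-cluster members, and they persist under covariate adjustment).

Step 04 qualifies the result:

```
CS(strength) = 0.70 -> strong stability
CS(expected_influence) = 0.75 -> strong stability
top-strength node 'abdominal_distension' differs significantly from 71% of other nodes
```

and step 05 verifies the estimator against ground truth at n = 2000:
sensitivity 1.000, false-positive rate 0.000, planted hub recovered as
the top-strength node.

## Layout

- `src/symptomnet/` — the library: `core`/`io` (types, readers,
  writers), `synthetic` (copula generator), `association`, `glasso`
  (estimation + EBIC selection), `centrality`, `resampling`,
  `predictability`, `regression`, `pipeline` (orchestration + JSON
  report).
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — modelling assumptions, parameter choices, and
  known limitations.
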