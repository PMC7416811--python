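# Methods

This note documents the statistical models in `survstrat`, the choices made
where the design was genuinely open, and what the synthetic validation
scenario does and does not demonstrate.

## Cox proportional-hazards engine

Per-biomarker models are fitted by Newton–Raphson maximisation of the Cox
partial likelihood. Tied event times use Efron's correction by default
(`ties="breslow"` available); with no ties the two are identical, which the
tests assert to 1e-10. Convergence is declared when the gradient
infinity-norm falls below 1e-8 (at most 50 iterations, with step-halving on
non-increase); the covariance is the inverse observed information.
Coefficients above 500 in absolute value are treated as monotone-likelihood
divergence and reported as `converged=False`.

Categorical covariates are reference-coded against the first level in sorted
order (stable and documented, e.g. `gender[male]` with `female` as
reference). Interaction terms `a:b` multiply the expanded columns of their
parents. Constant design columns are dropped (they carry no
partial-likelihood information); a rank-deficient design raises an error
naming the collinear columns. Missingness is handled per model by
complete-case analysis, erroring when more than 20% of patients would drop.

**Stepwise AIC.** Selection starts from the full scope (biomarker,
confounders, interactions) and takes, at each step, the single add-or-drop
move with the largest AIC decrease, stopping at a local minimum. The
biomarker main effect is forced: each risk-profile column must carry its
biomarker's information, otherwise the column would merely duplicate
confounder effects shared by all columns. Hierarchy is respected — an
interaction can only be present together with both main effects.

**Proportional-hazards diagnostics.** The Grambsch–Therneau score test
regresses Schoenfeld residuals on a transform g(t) of event time. With d
events, residuals s_k, centred transform c_k = g_k − ḡ and fit covariance
V = I⁻¹, the global statistic is `d · uᵀ V u / Σc²` with `u = Σ c_k s_k`
(χ² on p df), and per-column `d · (Vu)_j² / (V_jj Σc²)` (1 df). This uses
the standard average-information approximation; simulation under exact
proportional hazards (n=300, 500 replicates) puts the global type-I error at
≈0.035–0.05 at α=0.05, asserted as a calibration test. The default time
transform is `1 − KM(t)` ("km"); `identity` and `rank` are available.
Residuals at tied times share the full risk set (Breslow-style), which is
immaterial for the continuous-time simulations used here.

## Kaplan–Meier and log-rank

The product-limit estimator uses the convention that subjects censored at an
event time remain at risk at that time. The G-group log-rank test
accumulates hypergeometric (O − E) terms and their covariance over distinct
event times; the statistic uses the first G−1 groups with a pseudo-inverse
for near-singular covariance, df = G−1.

## Risk profiles

Linear predictors are centred to cohort mean zero (profiles are
location-free; the baseline hazard absorbs any intercept) and, by default,
z-scored per column before clustering: columns from different models have
arbitrary relative scales, and without a common scale the clustering metric
would implicitly weight biomarkers by the magnitude of their fitted
coefficients. Scaling can be disabled. A zero-variance column is a hard
error rather than a silent constant: it signals a misconfigured scope (e.g.
a biomarker reduced to intercept-only), and z-scoring it would amplify pure
noise.

## Consensus clustering

The inner and final clusterings use hand-rolled agglomerative hierarchical
clustering (Lance–Williams updates for average/complete/Ward linkage) with a
deterministic tie-break — among tied minimum distances the lexicographically
smallest index pair merges first — so results are bit-reproducible; the
partitions agree with `scipy.cluster.hierarchy` on tie-free data, which the
tests assert for all three linkages.

Each of `n_resamples` (default 100) draws ⌈0.8·n⌉ items without
replacement, clusters them at every k in (2,3,4,5), and the consensus
matrix entry M(i,j) is the fraction of co-clustering runs among co-sampling
runs. Pairs never co-sampled get consensus 0 with a warning (and a flag when
they exceed 1% of pairs — at the default 100×0.8 design the probability of
any such pair is negligible). The final assignment at each k cuts the same
agglomeration applied to 1 − M. Distances on profiles are Euclidean by
default (z-scored columns); Pearson-correlation distance is available.
Average linkage is the default for both inner and final clustering.

**Choice of k.** The empirical CDF of the n(n−1)/2 upper-triangular
consensus entries is evaluated on a fixed 101-point grid (bit-reproducible
areas); A(k) is its trapezoidal area and Δ(2) = A(2),
Δ(k) = (A(k) − A(k−1))/A(k−1) for k > 2. The selected k is the k ≥ 3
maximising Δ(k) if that maximum exceeds τ = 0.1, else 2, ties to the smaller
k. The τ floor operationalises "strongest increase in area" as a rule: a
relative area gain below 10% is treated as no evidence for more than two
clusters. The rule and τ are recorded in every result. Cluster stability is
reported as cluster consensus (mean within-cluster pairwise consensus;
undefined for singletons, reported as NaN with a warning) and item consensus
(mean consensus of an item with each cluster's members).

## Characterization

Clusters are relabelled in ascending order of Kaplan–Meier median survival
(ties broken by mean follow-up), so label G is always the best-surviving
cluster regardless of seed. Association with categorical confounders uses
the Pearson χ² test without continuity correction (a warning is emitted when
expected counts fall below 5; with n≈108 over 3 clusters and 5 diagnosis
levels this is routine); age uses one-way ANOVA. Pairwise biomarker
differences use the two-sided Wilcoxon rank-sum test — exact permutation
distribution when both groups have <8 observations and no ties, otherwise
the tie- and continuity-corrected normal approximation — and one
Benjamini–Hochberg step-up correction applied jointly across all
cluster-pairs × biomarkers (36 tests for 3 clusters and 12 biomarkers; a
per-biomarker family is available as an option). Biomarker values are
min-max normalised to [0,1] per column for pattern summaries; constant
columns map to 0 with a warning.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with defaults
fixed once as the package's validation scenario:

- **n = 108** patients, **3 latent subgroups** drawn uniformly.
- **Biomarkers.** The four comet classes are a joint Dirichlet draw per
  patient (proportions summing to 1) with subgroup-specific expectations
  (class I mean 0.25/0.45/0.65 from worst to best subgroup) and total
  concentration 60 — comet fractions aggregate many scored cells, so their
  sampling noise is small. The eight protein/activity markers are Gaussian
  (SD 1) around subgroup means stepped by 3 SD per adjacent subgroup, in
  mixed directions. Every marker therefore separates the subgroups by ≥3×
  its noise SD.
- **Survival.** Latent event times are inverse-transform samples from a
  Weibull-baseline Cox model, `T = scale · (−log U / exp(η))^(1/shape)`
  (shape 1.2, scale 24 months) — proportional hazards holds exactly by
  construction, making the PH test's null simulable. The hazard acts through
  six designated markers (comet I negatively, comet III/IV positively,
  calgranulin A, SOD-2, profilin) with an extreme-subgroup log-HR spread of
  ≈1.8, plus small age (0.01/year) and therapy (0.1 for TACE) effects.
- **Censoring.** An exponential dropout time whose rate is calibrated by
  bisection against the realised latent times so the expected censored
  fraction equals `censoring_rate` (default 0.3), plus administrative
  censoring at 60 months (a five-year observation window).
- **Confounders** (age, gender, therapy, diagnosis, comorbidities) are drawn
  independently of the subgroup by default; `confounded_mode` ties therapy
  allocation to the subgroup for robustness experiments.

Everything is driven by one `numpy` Generator seeded from the config, so an
identical config yields a bit-identical cohort.

**What the scenario does not emulate.** Real biomarker distributions
(unpublished), assay measurement-error structure, missing data, correlated
confounders, and non-proportional hazards. Passing tests therefore
demonstrate that the workflow recovers planted structure under its own
assumptions — not that it would find three clusters in any particular
clinical cohort.

## Known limitations

- With many uninformative biomarkers in the panel, the z-scored linear
  predictors of null markers are dominated by whatever confounder terms the
  stepwise search happened to retain; because all per-biomarker models share
  the same cohort, a chance confounder–survival association enters many
  columns simultaneously and the clustering can partially track that
  confounder. In the validation scenario every marker is informative, which
  keeps this effect small, but on real data the cluster–confounder
  association tests should be read with this selection pathway in mind.
- The stepwise search is greedy (single best move per step) and AIC is known
  to over-select: a spurious interaction survives in roughly the χ²
  tail-probability fraction of datasets (asserted ≤20% in tests).
- The delta-area rule cannot distinguish k choices whose consensus CDFs are
  nearly identical; τ = 0.1 is a reporting convention, not an inference.
- Problem sizes in the test-suite simulations (50-seed sweeps, 500 PH
  replicates at n = 300, 100-seed power checks at n = 108) were chosen as
  the smallest designs at which the asserted rates are stable; all are
  package choices recorded in the tests themselves.
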