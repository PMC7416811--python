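# survstrat

Survival-based stratification of palliative-care cancer cohorts from
liquid-biopsy biomarker panels.

## The problem

In palliative settings (here: non-resectable liver malignancies treated with
SIRT or TACE), clinicians want to know whether blood-derived biomarkers —
DNA-damage patterns of circulating leucocytes ("comet assay" class fractions
I–IV), stress/remodelling proteins (calgranulin A/S100, catalase, profilin,
RhoA, SOD-2, thioredoxin) and serum gelatinase activities (MMP-2, MMP-9) —
carry enough prognostic signal to split patients into survival strata.
`survstrat` implements an unsupervised workflow for exactly this question:

1. **Per-biomarker Cox models.** For each biomarker *j*, a proportional-
   hazards model `h(t | x) = h0(t) · exp(η_j)` is fitted by Newton–Raphson
   maximisation of the partial likelihood (Efron ties), with the confounders
   age, gender, therapy and primary tumour, and biomarker × therapy /
   biomarker × primary-tumour interactions in scope; terms are selected by
   bidirectional stepwise search on the Akaike Information Criterion, and
   the proportional-hazards assumption is checked with the
   Grambsch–Therneau scaled-Schoenfeld score test.
2. **Risk profiles.** The centred linear predictors η_j = x·β̂_j are
   concatenated into a patients × biomarkers matrix: each patient's
   confounder-corrected risk profile.
3. **Consensus clustering.** The profiles are clustered by agglomerative
   hierarchical clustering under item subsampling (default: 100 resamples,
   80% of patients, k = 2…5). The consensus matrix M(i,j) — the fraction of
   co-sampling resamples in which i and j co-cluster — yields the consensus
   CDF, its area A(k), and the relative gain Δ(k) = (A(k) − A(k−1))/A(k−1);
   the number of clusters is the k ≥ 3 maximising Δ(k) when that gain
   exceeds τ = 0.1, else 2.
4. **Characterization.** Kaplan–Meier curves and the log-rank test across
   clusters; χ²/ANOVA cluster–confounder association tests; pairwise
   Wilcoxon rank-sum tests of every biomarker between every cluster pair
   with a joint Benjamini–Hochberg correction; 0–1 biomarker normalisation
   and per-cluster/subgroup median–IQR summaries.

Because clinical cohorts of this kind are rarely public, the package ships a
first-class synthetic-cohort generator (`survstrat.simulate`) producing
seeded cohorts with latent prognostic subgroups, subgroup-shifted
biomarkers, Weibull-baseline proportional-hazards survival and calibrated
right censoring — every stage is testable end to end.

## Worked example

```bash
survstrat simulate --seed 1 --out cohort.csv
survstrat run --cohort cohort.csv --seed 1 --out results/
```

which prints

```
wrote 108 patients to cohort.csv
selected k = 3; log-rank p = 2.14e-10; artifacts in results/
```

The synthetic cohort has three planted prognostic subgroups; the delta-area
rule recovers `k = 3`, and the log-rank test confirms that the three
clusters have sharply different overall survival. `results/` contains the
risk-profile matrix and fitted models (`profiles/`), per-k consensus
matrices, assignments and the area/delta-area summary (`consensus/`), the
characterization report as JSON and Markdown (`report/`), and a
`manifest.json` recording config, seed and warnings. Cluster labels are
ordered by survival: the highest label is the best-surviving cluster.

The same run from Python:

```python
import survstrat as ss

cohort = ss.generate_cohort(ss.default_simulation_config(seed=1))
profiles, consensus, report = ss.run_pipeline(cohort, ss.PipelineConfig(seed=1))
print(consensus.selected_k)                  # 3
print(f"{report.logrank['p']:.3g}")          # 9.76e-12  (in-memory cohort;
                                             # the CLI round-trips through CSV)
```

Estimators compose with scikit-learn:
`RiskProfileBuilder` (a transformer: cohort table → risk-profile matrix) and
`ConsensusClustering` (a clusterer with `fit_predict`, `labels_`,
`selected_k_`) both support `get_params`/`set_params`.

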