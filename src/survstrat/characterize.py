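"""Statistical characterization of patient clusters.

Covers survival separation (log-rank), cluster-confounder association tests
(chi-square for categoricals, one-way ANOVA for age), pairwise biomarker
comparisons between clusters (Wilcoxon rank-sum with a joint
Benjamini-Hochberg correction), 0-1 biomarker normalisation, per-cluster
summaries, and filtered subgroup summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survival import kaplan_meier, logrank_test

__all__ = [
    "CharacterizationReport",
    "test_confounder_association",
    "wilcoxon_rank_test",
    "benjamini_hochberg",
    "minmax_normalize",
    "subgroup_summary",
    "relabel_by_survival",
    "characterize",
]

#: Per-group size above which the Wilcoxon test switches from the exact
#: rank-sum distribution to the tie- and continuity-corrected normal
#: approximation.
WILCOXON_EXACT_MAX_N = 7


def wilcoxon_rank_test(x, y, method: str = "auto"):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    With ``method='auto'`` the exact permutation distribution is used when
    both groups have fewer than 8 observations and there are no ties;
    otherwise the normal approximation with tie correction and continuity
    correction.  ``method='exact'``/``'asymptotic'`` force a branch.
    Returns ``(W, p)`` with W the Mann-Whitney U statistic of the first
    sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; Wilcoxon p set to 1")
        return float(x.size * y.size / 2.0), 1.0
    if method == "auto":
        has_ties = np.unique(pooled).size < pooled.size
        method = ("exact" if x.size <= WILCOXON_EXACT_MAX_N
                  and y.size <= WILCOXON_EXACT_MAX_N and not has_ties
                  else "asymptotic")
    elif method not in ("exact", "asymptotic"):
        raise ValueError("method must be 'auto', 'exact' or 'asymptotic'")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def benjamini_hochberg(p_values):
    """Benjamini-Hochberg step-up FDR adjustment.

    With p(1) <= ... <= p(m), the adjusted value is
    ``q(i) = min_{j >= i} (m * p(j) / j)`` capped at 1, returned in the input
    order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_confounder_association(cohort: pd.DataFrame, assignment,
                                categorical=("gender", "therapy", "diagnosis", "comorbidities"),
                                continuous=("age",)):
    """Cluster-confounder association tests.

    Categorical confounders: Pearson chi-square (no Yates correction) on the
    cluster x category contingency table, with a warning when any expected
    count is below 5.  Continuous confounders (age): one-way ANOVA F across
    clusters.  Single-level confounders are skipped with a warning.

    Returns a list of dicts (confounder, test, statistic, df, p).
    """
    labels = np.asarray(assignment)
    if np.unique(labels).size < 2:
        raise ValueError("at least 2 clusters are required")
    out = []
    for conf in categorical:
        if conf not in cohort.columns:
            continue
        table = pd.crosstab(cohort[conf].astype(str), labels)
        if table.shape[0] < 2:
            warnings.warn(f"confounder '{conf}' has a single level; skipped")
            continue
        chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
        if np.any(expected < 5):
            warnings.warn(f"chi-square for '{conf}': some expected counts < 5")
        out.append({"confounder": conf, "test": "chi2", "statistic": float(chi2),
                    "df": int(dof), "p": float(p)})
    for conf in continuous:
        if conf not in cohort.columns:
            continue
        groups = [cohort.loc[labels == c, conf].to_numpy(float)
                  for c in np.unique(labels)]
        if all(np.all(g == groups[0][0]) for g in groups if g.size):
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*groups)
        out.append({"confounder": conf, "test": "anova_f", "statistic": float(f_stat),
                    "df": int(np.unique(labels).size - 1), "p": float(p)})
    return out


def minmax_normalize(cohort: pd.DataFrame, columns):
    """Per-column (x - min) / (max - min) normalisation to [0, 1].

    A constant column maps to all zeros with a warning.
    """
    out = {}
    for col in columns:
        x = cohort[col].to_numpy(float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi == lo:
            warnings.warn(f"column '{col}' is constant; normalised to 0")
            out[col] = np.zeros_like(x)
        else:
            out[col] = (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=cohort.index)


def subgroup_summary(cohort: pd.DataFrame, mask, columns):
    """Median and IQR of ``columns`` inside a patient subset vs the cohort.

    ``mask`` is a boolean selector (e.g. cluster-3 patients with HCC under
    TACE).  Returns a DataFrame with subgroup/cohort medians, IQRs and the
    sign of the median difference.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no patients")
    rows = []
    for col in columns:
        sub = cohort.loc[mask, col].to_numpy(float)
        full = cohort[col].to_numpy(float)
        med_s, med_f = float(np.median(sub)), float(np.median(full))
        rows.append({
            "biomarker": col,
            "subgroup_median": med_s,
            "subgroup_iqr": float(np.percentile(sub, 75) - np.percentile(sub, 25)),
            "cohort_median": med_f,
            "cohort_iqr": float(np.percentile(full, 75) - np.percentile(full, 25)),
            "median_difference_sign": int(np.sign(med_s - med_f)),
        })
    return pd.DataFrame(rows).set_index("biomarker")


def relabel_by_survival(times, events, assignment):
    """Relabel clusters 1..G in ascending order of Kaplan-Meier median
    survival, so the highest label is the best-surviving cluster (stable
    across seeds; raw clustering labels are arbitrary)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    labels = np.asarray(assignment)
    keys = []
    for c in np.unique(labels):
        idx = labels == c
        curve = kaplan_meier(times[idx], events[idx])
        med = curve.median
        keys.append((med if np.isfinite(med) else np.inf, float(times[idx].mean()), c))
    order = sorted(keys)
    mapping = {c: rank + 1 for rank, (_, _, c) in enumerate(order)}
    return np.array([mapping[c] for c in labels]), mapping


@dataclass
class CharacterizationReport:
    """Cluster characterization: survival, confounders, biomarkers."""

    logrank: dict
    confounder_tests: list
    biomarker_tests: pd.DataFrame
    normalized_biomarkers: pd.DataFrame
    cluster_summaries: pd.DataFrame
    cluster_sizes: dict
    bh_family: str
    subgroup_summaries: pd.DataFrame | None = None
    label_mapping: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "logrank": self.logrank,
            "confounder_tests": self.confounder_tests,
            "biomarker_tests": self.biomarker_tests.reset_index(drop=True).to_dict("records"),
            "cluster_sizes": {str(k): int(v) for k, v in self.cluster_sizes.items()},
            "bh_family": self.bh_family,
            "label_mapping": {str(k): int(v) for k, v in self.label_mapping.items()},
        }

    def to_markdown(self) -> str:
        lines = ["# Cluster characterization", ""]
        lr = self.logrank
        lines += [
            "## Survival separation (log-rank)",
            f"chi2 = {lr['chi2']:.4g}, df = {lr['df']}, p = {lr['p']:.3g}",
            "",
            "## Cluster sizes",
        ]
        lines += [f"- cluster {c}: {n} patients" for c, n in sorted(self.cluster_sizes.items())]
        lines += ["", "## Confounder association"]
        for t in self.confounder_tests:
            lines.append(
                f"- {t['confounder']}: {t['test']} = {t['statistic']:.4g} "
                f"(df={t['df']}), p = {t['p']:.3g}"
            )
        lines += ["", f"## Pairwise biomarker tests (Wilcoxon, BH family: {self.bh_family})", ""]
        sig = self.biomarker_tests[self.biomarker_tests["p_adjusted"] < 0.05]
        lines.append(f"{len(sig)} of {len(self.biomarker_tests)} tests significant "
                     "after BH adjustment (q < 0.05):")
        for _, row in sig.iterrows():
            lines.append(
                f"- {row['biomarker']} (cluster {row['cluster_a']} vs {row['cluster_b']}): "
                f"W = {row['W']:.4g}, p = {row['p']:.3g}, q = {row['p_adjusted']:.3g}"
            )
        return "\n".join(lines) + "\n"


def characterize(cohort: pd.DataFrame, assignment, fits=None, biomarkers=None,
                 time_col: str = "time", event_col: str = "event",
                 bh_family: str = "joint", relabel: bool = True,
                 subgroup_mask=None) -> CharacterizationReport:
    """Full statistical characterization of a clustering.

    Runs the log-rank test across clusters, confounder-association tests,
    all cluster-pair x biomarker Wilcoxon comparisons with one BH correction
    (joint family by default; ``bh_family='per_biomarker'`` adjusts within
    each biomarker), 0-1 normalisation and per-cluster medians/IQRs.
    Clusters are relabelled so the highest label has the best survival.
    """
    labels = np.asarray(assignment)
    if len(labels) != len(cohort):
        raise ValueError("assignment must cover every cohort row")
    if biomarkers is None:
        if fits is None:
            raise ValueError("either biomarkers or fits must be given")
        biomarkers = list(fits)
    times = cohort[time_col].to_numpy(float)
    events = cohort[event_col].to_numpy(float)

    mapping = {}
    if relabel:
        labels, mapping = relabel_by_survival(times, events, labels)

    chi2, df, p = logrank_test(times, events, labels)
    logrank = {"chi2": float(chi2), "df": int(df), "p": float(p)}

    confounder_tests = test_confounder_association(cohort, labels)

    clusters = np.unique(labels)
    rows = []
    for b in biomarkers:
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, c = clusters[i], clusters[j]
                w, praw = wilcoxon_rank_test(
                    cohort.loc[labels == a, b].to_numpy(float),
                    cohort.loc[labels == c, b].to_numpy(float),
                )
                rows.append({"biomarker": b, "cluster_a": int(a), "cluster_b": int(c),
                             "W": w, "p": praw})
    tests = pd.DataFrame(rows)
    if bh_family == "joint":
        tests["p_adjusted"] = benjamini_hochberg(tests["p"].to_numpy())
    elif bh_family == "per_biomarker":
        tests["p_adjusted"] = tests.groupby("biomarker")["p"].transform(
            lambda s: benjamini_hochberg(s.to_numpy())
        )
    else:
        raise ValueError("bh_family must be 'joint' or 'per_biomarker'")

    normalized = minmax_normalize(cohort, biomarkers)
    summaries = []
    for c in clusters:
        idx = labels == c
        for b in biomarkers:
            vals = cohort.loc[idx, b].to_numpy(float)
            summaries.append({
                "cluster": int(c), "biomarker": b,
                "median": float(np.median(vals)),
                "iqr": float(np.percentile(vals, 75) - np.percentile(vals, 25)),
            })
    cluster_summaries = pd.DataFrame(summaries)
    sizes = {int(c): int((labels == c).sum()) for c in clusters}

    sub = None
    if subgroup_mask is not None:
        sub = subgroup_summary(cohort, subgroup_mask, biomarkers)

    return CharacterizationReport(
        logrank=logrank,
        confounder_tests=confounder_tests,
        biomarker_tests=tests,
        normalized_biomarkers=normalized,
        cluster_summaries=cluster_summaries,
        cluster_sizes=sizes,
        bh_family=bh_family,
        subgroup_summaries=sub,
        label_mapping=mapping,
    )
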