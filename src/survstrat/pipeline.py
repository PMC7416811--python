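"""End-to-end stratification pipeline and artifact writing.

Stages: per-biomarker Cox risk profiles → consensus hierarchical clustering
→ delta-area choice of k → statistical characterization.  All artifacts are
written deterministically (fixed float formatting, sorted JSON keys, no
timestamps) so identical config + seed yields byte-identical output.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .characterize import characterize
from .config import PipelineConfig
from .consensus import consensus_cluster
from .profiles import build_risk_profiles, default_scopes

logger = logging.getLogger("survstrat")

__all__ = ["run_pipeline"]

FLOAT_FMT = "%.10g"


def run_pipeline(cohort: pd.DataFrame, config: PipelineConfig, out_dir=None):
    """Run all pipeline stages; optionally write artifacts to ``out_dir``.

    Returns ``(profiles, consensus_result, report)``.  The output layout is
    fixed: ``profiles/``, ``consensus/``, ``report/`` and ``manifest.json``.
    """
    config.validate()
    caught = []

    def _stage(name, fn, *args, **kwargs):
        logger.info("stage: %s", name)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        for w in wlist:
            caught.append(f"{name}: {w.message}")
            logger.warning("%s: %s", name, w.message)
        return result

    scopes = default_scopes(config.biomarkers, config.confounders,
                            config.interaction_confounders)
    profiles, fits = _stage(
        "risk_profiles", build_risk_profiles, cohort, scopes,
        scaling=config.scaling, stepwise=config.stepwise, ties=config.ties,
        time_col=config.time_col, event_col=config.event_col,
    )
    result = _stage(
        "consensus_clustering", consensus_cluster, profiles,
        k_values=config.k_values, n_resamples=config.n_resamples,
        subsample_fraction=config.subsample_fraction, linkage=config.linkage,
        distance=config.distance, tau=config.tau, seed=config.seed,
    )
    report = _stage(
        "characterization", characterize, cohort, result.assignment,
        fits=fits, time_col=config.time_col, event_col=config.event_col,
    )

    if out_dir is not None:
        _write_artifacts(Path(out_dir), cohort, config, profiles, fits,
                         result, report, caught)
    return profiles, result, report


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_artifacts(out, cohort, config, profiles, fits, result, report, warnings_log):
    for sub in ("profiles", "consensus", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    profiles.to_csv(out / "profiles" / "risk_profiles.csv", float_format=FLOAT_FMT)
    _json_dump({b: f.to_dict() for b, f in fits.items()},
               out / "profiles" / "cox_models.json")

    ids = cohort[config.id_col].astype(str).to_numpy()
    for k in result.k_values:
        pd.DataFrame(result.consensus_matrices[k], index=ids, columns=ids).to_csv(
            out / "consensus" / f"consensus_k{k}.csv", float_format=FLOAT_FMT
        )
    assign = pd.DataFrame({"patient_id": ids})
    for k in result.k_values:  # per-k assignments = the cluster-tracking data
        assign[f"k{k}"] = result.assignments[k]
    mapping = report.label_mapping or {}
    assign["selected"] = [mapping.get(int(c), int(c)) for c in result.assignment]
    assign.to_csv(out / "consensus" / "assignments.csv", index=False)
    _json_dump(result.summary(), out / "consensus" / "summary.json")

    _json_dump(report.to_dict(), out / "report" / "characterization.json")
    (out / "report" / "characterization.md").write_text(report.to_markdown())
    report.normalized_biomarkers.assign(patient_id=ids).set_index("patient_id").to_csv(
        out / "report" / "normalized_biomarkers.csv", float_format=FLOAT_FMT
    )
    report.cluster_summaries.to_csv(
        out / "report" / "cluster_summaries.csv", index=False, float_format=FLOAT_FMT
    )

    manifest = {
        "package": "survstrat",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "n_patients": int(len(cohort)),
        "selected_k": int(result.selected_k),
        "warnings": warnings_log,
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
            and p.name != "manifest.json"
        ),
    }
    _json_dump(manifest, out / "manifest.json")
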