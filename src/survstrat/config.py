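"""Configuration objects for simulation and for the stratification pipeline.

Both configs are plain dataclasses that can be round-tripped through JSON or
YAML.  Validation raises :class:`ConfigError` naming the offending field.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "PipelineConfig",
    "COMET_CLASSES",
    "DEFAULT_BIOMARKERS",
    "default_simulation_config",
]


class ConfigError(ValueError):
    """Raised when a configuration violates one of its invariants."""


#: Comet-assay DNA-migration classes, stored per patient as fractions of
#: scored cells; when all four are present they are generated jointly as
#: proportions summing to one.
COMET_CLASSES = ("comet_class_i", "comet_class_ii", "comet_class_iii", "comet_class_iv")

#: Default 12-biomarker panel: four comet classes, six leucocyte/serum
#: proteins, two gelatinase activities.
DEFAULT_BIOMARKERS = COMET_CLASSES + (
    "calgranulin_a",
    "catalase",
    "profilin",
    "rhoa",
    "sod2",
    "thioredoxin",
    "mmp2_activity",
    "mmp9_activity",
)

CONFOUNDERS = ("age", "gender", "therapy", "diagnosis", "comorbidities")

# Categorical confounder levels and sampling probabilities.  The "risk level"
# (second entry of each coefficient mapping below) is the level whose
# indicator a confounder hazard coefficient multiplies.
CONFOUNDER_LEVELS = {
    "gender": (("female", "male"), (0.4, 0.6)),
    "therapy": (("SIRT", "TACE"), (0.55, 0.45)),
    "diagnosis": (("CCC", "HCC", "breast", "colorectal", "other"), (0.2, 0.3, 0.1, 0.3, 0.1)),
    "comorbidities": (("none", "single", "multiple"), (0.4, 0.4, 0.2)),
}
CONFOUNDER_RISK_LEVEL = {
    "gender": "male",
    "therapy": "TACE",
    "diagnosis": "HCC",
    "comorbidities": "multiple",
}


@dataclass
class SimulationConfig:
    """Generative model for a synthetic palliative liver-malignancy cohort.

    Patients fall into ``n_subgroups`` latent subgroups drawn uniformly.
    Non-comet biomarkers are Gaussian around subgroup-specific means
    (standardised units, common ``biomarker_noise_sd``); the four comet
    classes, when present together, are a Dirichlet draw whose expectation is
    the subgroup's mean row (concentration ``comet_concentration``).  Survival
    times follow a Weibull-baseline proportional-hazards model driven by
    ``hazard_coefficients`` (log hazard ratio per biomarker unit) and
    ``confounder_coefficients``; censoring combines an exponential dropout
    time calibrated to ``censoring_rate`` with administrative censoring at
    ``admin_censor_time`` months.
    """

    n_patients: int = 108
    n_subgroups: int = 3
    biomarker_names: tuple = DEFAULT_BIOMARKERS
    subgroup_biomarker_means: tuple = ()  # n_subgroups x n_biomarkers
    biomarker_noise_sd: float = 1.0
    hazard_coefficients: dict = field(default_factory=dict)
    confounder_coefficients: dict = field(default_factory=dict)
    baseline_shape: float = 1.2
    baseline_scale: float = 24.0
    censoring_rate: float = 0.3
    admin_censor_time: float = 60.0
    comet_concentration: float = 60.0
    confounded_mode: bool = False
    seed: int = 0

    def __post_init__(self):
        self.biomarker_names = tuple(self.biomarker_names)
        self.subgroup_biomarker_means = tuple(
            tuple(float(x) for x in row) for row in self.subgroup_biomarker_means
        )
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if not (isinstance(self.n_patients, int) and self.n_patients > 0):
            raise ConfigError("n_patients must be a positive integer")
        if not (isinstance(self.n_subgroups, int) and self.n_subgroups > 0):
            raise ConfigError("n_subgroups must be a positive integer")
        if len(set(self.biomarker_names)) != len(self.biomarker_names):
            raise ConfigError("biomarker_names must be unique")
        if len(self.subgroup_biomarker_means) != self.n_subgroups:
            raise ConfigError(
                "subgroup_biomarker_means must have exactly n_subgroups rows"
            )
        for row in self.subgroup_biomarker_means:
            if len(row) != len(self.biomarker_names):
                raise ConfigError(
                    "subgroup_biomarker_means rows must have one column per biomarker_name"
                )
        if not self.biomarker_noise_sd > 0:
            raise ConfigError("biomarker_noise_sd must be positive")
        if not (0.0 <= self.censoring_rate <= 1.0):
            raise ConfigError("censoring_rate must lie in [0, 1]")
        if not self.baseline_shape > 0:
            raise ConfigError("baseline_shape must be positive")
        if not self.baseline_scale > 0:
            raise ConfigError("baseline_scale must be positive")
        if not self.admin_censor_time > 0:
            raise ConfigError("admin_censor_time must be positive")
        if not self.comet_concentration > 0:
            raise ConfigError("comet_concentration must be positive")
        unknown = set(self.hazard_coefficients) - set(self.biomarker_names)
        if unknown:
            raise ConfigError(f"hazard_coefficients for unknown biomarkers: {sorted(unknown)}")
        unknown = set(self.confounder_coefficients) - set(CONFOUNDERS)
        if unknown:
            raise ConfigError(
                f"confounder_coefficients for unknown confounders: {sorted(unknown)}"
            )
        # comet classes present as a full group must have means that are
        # proportions summing to one within every subgroup
        comet_idx = self.comet_indices()
        if comet_idx:
            for g, row in enumerate(self.subgroup_biomarker_means):
                vals = [row[i] for i in comet_idx]
                if any(v < 0 or v > 1 for v in vals) or not math.isclose(
                    sum(vals), 1.0, abs_tol=1e-9
                ):
                    raise ConfigError(
                        "subgroup_biomarker_means: comet-class means of subgroup "
                        f"{g} must be proportions summing to 1"
                    )

    def comet_indices(self) -> list:
        """Indices of the comet classes if the full group is in the panel."""
        if all(c in self.biomarker_names for c in COMET_CLASSES):
            return [self.biomarker_names.index(c) for c in COMET_CLASSES]
        return []

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["biomarker_names"] = list(self.biomarker_names)
        d["subgroup_biomarker_means"] = [list(r) for r in self.subgroup_biomarker_means]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimulationConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        return cls.from_dict(_load_structured(path))


def default_simulation_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default validation scenario: n=108, three latent subgroups.

    Every panel biomarker carries subgroup structure: the comet classes via
    subgroup-specific Dirichlet expectations (high intact-DNA class I and low
    damaged classes III/IV in the best-prognosis subgroup), the Gaussian
    markers via adjacent-subgroup mean shifts of 3x the noise SD (mixed
    directions).  Subgroup 0 is the worst-prognosis stratum.  Hazard
    coefficients act through six designated markers (comet I/III/IV,
    calgranulin A, SOD-2, profilin) and give an extreme-subgroup log
    hazard-ratio spread of about 1.8; the remaining markers are prognostic
    only through their correlation with the latent subgroup.
    """
    names = DEFAULT_BIOMARKERS
    # rows: subgroup 0 = worst prognosis ... subgroup 2 = best prognosis
    comet_means = [
        (0.25, 0.30, 0.25, 0.20),
        (0.45, 0.30, 0.15, 0.10),
        (0.65, 0.25, 0.06, 0.04),
    ]
    shifted = {
        "calgranulin_a": (6.0, 3.0, 0.0),
        "sod2": (6.0, 3.0, 0.0),
        "profilin": (6.0, 3.0, 0.0),
        "rhoa": (6.0, 3.0, 0.0),
        "mmp9_activity": (6.0, 3.0, 0.0),
        "catalase": (0.0, 3.0, 6.0),
        "thioredoxin": (0.0, 3.0, 6.0),
        "mmp2_activity": (0.0, 3.0, 6.0),
    }
    means = []
    for g in range(3):
        row = []
        for name in names:
            if name in COMET_CLASSES:
                row.append(comet_means[g][COMET_CLASSES.index(name)])
            else:
                row.append(shifted[name][g])
        means.append(tuple(row))
    params = dict(
        n_patients=108,
        n_subgroups=3,
        biomarker_names=names,
        subgroup_biomarker_means=tuple(means),
        biomarker_noise_sd=1.0,
        hazard_coefficients={
            "comet_class_i": -0.8,
            "comet_class_iii": 0.8,
            "comet_class_iv": 0.8,
            "calgranulin_a": 0.08,
            "sod2": 0.06,
            "profilin": 0.06,
        },
        confounder_coefficients={"age": 0.01, "therapy": 0.1},
        baseline_shape=1.2,
        baseline_scale=24.0,
        censoring_rate=0.3,
        admin_censor_time=60.0,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    Defaults follow the study design: per-biomarker Cox models corrected for
    age, gender, therapy and diagnosis with biomarker x therapy and
    biomarker x diagnosis interactions, stepwise AIC selection, consensus
    hierarchical clustering with 100 resamples over k = 2..5.
    """

    biomarkers: tuple = DEFAULT_BIOMARKERS
    confounders: tuple = ("age", "gender", "therapy", "diagnosis")
    interaction_confounders: tuple = ("therapy", "diagnosis")
    time_col: str = "time"
    event_col: str = "event"
    id_col: str = "patient_id"
    stepwise: bool = True
    ties: str = "efron"
    scaling: str = "zscore"
    k_values: tuple = (2, 3, 4, 5)
    n_resamples: int = 100
    subsample_fraction: float = 0.8
    linkage: str = "average"
    distance: str = "euclidean"
    tau: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.biomarkers = tuple(self.biomarkers)
        self.confounders = tuple(self.confounders)
        self.interaction_confounders = tuple(self.interaction_confounders)
        self.k_values = tuple(int(k) for k in self.k_values)
        self.validate()

    def validate(self) -> None:
        cols = list(self.biomarkers) + list(self.confounders) + [
            self.time_col, self.event_col, self.id_col,
        ]
        if len(set(cols)) != len(cols):
            raise ConfigError("biomarker/confounder/time/event/id columns must be distinct")
        if not set(self.interaction_confounders) <= set(self.confounders):
            raise ConfigError("interaction_confounders must be a subset of confounders")
        if list(self.k_values) != sorted(self.k_values) or self.k_values[0] != 2:
            raise ConfigError("k_values must be ascending and start at 2")
        if self.ties not in ("efron", "breslow"):
            raise ConfigError("ties must be 'efron' or 'breslow'")
        if self.scaling not in ("none", "zscore"):
            raise ConfigError("scaling must be 'none' or 'zscore'")
        if self.linkage not in ("average", "complete", "ward"):
            raise ConfigError("linkage must be average, complete or ward")
        if self.distance not in ("euclidean", "pearson"):
            raise ConfigError("distance must be euclidean or pearson")
        if not (0 < self.subsample_fraction <= 1):
            raise ConfigError("subsample_fraction must lie in (0, 1]")
        if self.n_resamples < 2:
            raise ConfigError("n_resamples must be at least 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("biomarkers", "confounders", "interaction_confounders", "k_values"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown PipelineConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_dict(_load_structured(path))


def _load_structured(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
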