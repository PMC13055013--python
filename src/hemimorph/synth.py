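"""Synthetic cohort generation.

Generates participants and morphometric tables under the same linear model
the downstream analysis assumes: per feature, value = intercept
+ age*slope + gender*offset + group*beta + scanner_additive
+ scanner_multiplicative * noise, with positivity enforced by resampling
the noise (not truncation). Also ships the fixed 32-patient study roster
used by the cohort-matching statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import vocab
from .types import MorphometricTable, Participant

FeatureKey = tuple[str, str]  # (measure, region)

#: study-shape constants (two-scanner, two patient groups + controls)
STUDY_N_PATIENTS_RH = 13  # left surgery, preserved RH
STUDY_N_PATIENTS_LH = 19  # right surgery, preserved LH
STUDY_N_CONTROLS = 51
CONTROL_FEMALES = 24  # printed control cohort composition


def feature_list() -> list[FeatureKey]:
    """All 114 (measure, region) features in canonical order."""
    out: list[FeatureKey] = [(vocab.GROSS_VOL, r) for r in vocab.GROSS_3]
    for m in vocab.CORTICAL_MEASURES:
        out.extend((m, r) for r in vocab.CORTICAL_34)
    out.extend((vocab.SUBCORTICAL_VOL, r) for r in vocab.SUBCORTICAL_9)
    return out


_DEFAULT_INTERCEPTS = {
    vocab.CXT: 2.5,
    vocab.CSA: 2500.0,
    vocab.CV: 4500.0,
    vocab.SUBCORTICAL_VOL: 4000.0,
    vocab.GROSS_VOL: {"GM": 250_000.0, "WM": 200_000.0, "LV": 12_000.0},
}

_DEFAULT_SD = {
    vocab.CXT: 0.15,
    vocab.CSA: 250.0,
    vocab.CV: 450.0,
    vocab.SUBCORTICAL_VOL: 400.0,
    vocab.GROSS_VOL: 9000.0,
}

Param = float | Mapping[str, float]


def _resolve(param: Param, measure: str, region: str, default: float = 0.0) -> float:
    if isinstance(param, Mapping):
        inner = param.get(measure, param.get("default", default))
        if isinstance(inner, Mapping):
            return float(inner.get(region, inner.get("default", default)))
        return float(inner)
    return float(param)


@dataclass
class CohortConfig:
    """Generative specification for a synthetic cohort.

    Scalar parameters apply to every feature; mappings may key by measure
    (and, nested, by region). ``overrides`` patches individual features.
    """

    n_patients_LH: int = STUDY_N_PATIENTS_LH
    n_patients_RH: int = STUDY_N_PATIENTS_RH
    n_controls: int = STUDY_N_CONTROLS
    scanners: tuple[tuple[str, float], ...] = (("scannerA", 0.6), ("scannerB", 0.4))
    intercept: Param = field(default_factory=lambda: dict(_DEFAULT_INTERCEPTS))
    age_slope: Param = 0.0
    gender_offset: Param = 0.0
    group_effect: Param = 0.0
    lh_asymmetry: float = 1.0
    scanner_additive: Mapping[str, Param] = field(default_factory=dict)
    scanner_multiplicative: Mapping[str, Param] = field(default_factory=dict)
    residual_sd: Param = field(default_factory=lambda: dict(_DEFAULT_SD))
    ablation_fraction: float = 0.25
    ilae_high_fraction: float = 0.3
    age_range: tuple[float, float] = (7.0, 22.0)
    seed: int = 0
    overrides: Mapping[FeatureKey, Mapping[str, float]] = field(default_factory=dict)

    def validate(self) -> "CohortConfig":
        if min(self.n_patients_LH, self.n_patients_RH, self.n_controls) < 0:
            raise ValueError("counts must be >= 0")
        probs = [p for _, p in self.scanners]
        if not probs or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise ValueError("scanner probabilities must be >= 0 and sum to 1")
        for frac in (self.ablation_fraction, self.ilae_high_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        for measure, region in feature_list():
            if self._param("residual_sd", measure, region) <= 0:
                raise ValueError("residual_sd must be > 0")
            for label, _ in self.scanners:
                if self._scanner_param("scanner_multiplicative", label, measure, region) <= 0:
                    raise ValueError("scanner_multiplicative must be > 0")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] <= 0:
            raise ValueError("bad age_range")
        return self

    def _param(self, name: str, measure: str, region: str) -> float:
        override = self.overrides.get((measure, region), {})
        if name in override:
            return float(override[name])
        base = getattr(self, name)
        defaults = {"scanner_multiplicative": 1.0}
        return _resolve(base, measure, region, defaults.get(name, 0.0))

    def _scanner_param(self, name: str, label: str, measure: str, region: str) -> float:
        override = self.overrides.get((measure, region), {})
        key = f"{name}:{label}"
        if key in override:
            return float(override[key])
        table = getattr(self, name)
        default = 1.0 if name == "scanner_multiplicative" else 0.0
        if label not in table:
            return default
        return _resolve(table[label], measure, region, default)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        raw = yaml.safe_load(open(path)) or {}
        if "scanners" in raw:
            raw["scanners"] = tuple((str(k), float(v)) for k, v in raw["scanners"].items())
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        if "overrides" in raw:
            raw["overrides"] = {
                (str(m), str(r)): dict(v)
                for (m, r), v in ((k.split("/", 1), v) for k, v in raw["overrides"].items())
            }
        return cls(**raw).validate()


def simulate_feature_matrix(
    rng: np.random.Generator,
    group: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    scanner_idx: np.ndarray,
    intercept: np.ndarray,
    age_slope: np.ndarray,
    gender_offset: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    delta: np.ndarray,
    sigma: np.ndarray,
    positive: bool = True,
    max_resample: int = 200,
) -> np.ndarray:
    """Draw the (n_rows, n_features) value matrix of the generative model.

    ``gamma``/``delta`` have shape (n_scanners, n_features); the remaining
    per-feature parameters are length n_features; ``group`` is the per-row
    effect multiplier (0 for controls). Negative draws are resampled.
    """
    n, f = len(age), len(intercept)
    mean = (
        intercept[None, :]
        + np.outer(age, age_slope)
        + np.outer(gender, gender_offset)
        + np.outer(group, beta)
        + gamma[scanner_idx, :]
    )
    scale = delta[scanner_idx, :] * sigma[None, :]
    values = mean + scale * rng.standard_normal((n, f))
    if positive:
        for _ in range(max_resample):
            bad = values <= 0
            if not bad.any():
                break
            values[bad] = (mean + scale * rng.standard_normal((n, f)))[bad]
        else:
            raise RuntimeError("could not achieve positivity by resampling")
    return values


def generate_cohort(config: CohortConfig) -> tuple[list[Participant], MorphometricTable]:
    """Generate participants and a raw morphometric table; reproducible by seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = [s for s, _ in config.scanners]
    probs = np.array([p for _, p in config.scanners])

    participants: list[Participant] = []

    def _draw_common():
        age = float(rng.uniform(*config.age_range))
        gender = "female" if rng.random() < 0.5 else "male"
        scanner = labels[int(rng.choice(len(labels), p=probs))]
        return age, gender, scanner

    for prefix, hemi, n in (
        ("patRH", "RH", config.n_patients_RH),
        ("patLH", "LH", config.n_patients_LH),
    ):
        for i in range(n):
            age, gender, scanner = _draw_common()
            kind = "ablation" if rng.random() < config.ablation_fraction else "resection"
            ilae = "high" if rng.random() < config.ilae_high_fraction else "low"
            age_surg = float(rng.uniform(0.5, age))
            onset = float(rng.uniform(0.0, age_surg))
            participants.append(
                Participant(
                    id=f"{prefix}{i + 1:03d}",
                    group="patient",
                    preserved_hemisphere=hemi,
                    age_at_test=age,
                    gender=gender,
                    scanner=scanner,
                    surgery_kind=kind,
                    age_at_surgery=age_surg,
                    seizure_onset_age=onset,
                    time_from_surgery=age - age_surg,
                    ilae_binned=ilae,
                )
            )
    for i in range(config.n_controls):
        age, gender, scanner = _draw_common()
        participants.append(
            Participant(
                id=f"ctrl{i + 1:03d}",
                group="control",
                preserved_hemisphere=None,
                age_at_test=age,
                gender=gender,
                scanner=scanner,
            )
        )

    # analysis rows: patients one hemisphere, controls both
    rows = [(p, h) for p in participants for h in p.hemispheres()]
    features = feature_list()
    group_mult = np.array(
        [
            0.0
            if p.group == "control"
            else (config.lh_asymmetry if p.preserved_hemisphere == "LH" else 1.0)
            for p, _ in rows
        ]
    )
    age_v = np.array([p.age_at_test for p, _ in rows])
    gender_v = np.array([p.gender_code for p, _ in rows], dtype=float)
    scan_idx = np.array([labels.index(p.scanner) for p, _ in rows])

    def col(name: str) -> np.ndarray:
        return np.array([config._param(name, m, r) for m, r in features])

    gamma = np.array(
        [[config._scanner_param("scanner_additive", s, m, r) for m, r in features] for s in labels]
    )
    delta = np.array(
        [
            [config._scanner_param("scanner_multiplicative", s, m, r) for m, r in features]
            for s in labels
        ]
    )
    values = simulate_feature_matrix(
        rng,
        group_mult,
        age_v,
        gender_v,
        scan_idx,
        intercept=col("intercept"),
        age_slope=col("age_slope"),
        gender_offset=col("gender_offset"),
        beta=col("group_effect"),
        gamma=gamma,
        delta=delta,
        sigma=col("residual_sd"),
    )

    records = []
    for i, (p, hemi) in enumerate(rows):
        for j, (measure, region) in enumerate(features):
            records.append((p.id, hemi, measure, region, values[i, j]))
    table = MorphometricTable(
        pd.DataFrame(
            records,
            columns=["participant_id", "hemisphere", "measure", "region", "value"],
        )
    )
    return participants, table.validate().sorted()


# ---------------------------------------------------------------------------
# Fixed 32-patient roster (printed study inputs)
# ---------------------------------------------------------------------------

# (age_at_test, gender, age_at_surgery, seizure_onset_age, time_from_surgery,
#  ilae_binned, surgery description); onset None = missing as printed.
_ROSTER_RH: list[tuple] = [  # left surgery, preserved RH
    (11.5, "male", 1, 0, 11, "low", "Hemispherectomy"),
    (12.5, "male", 0, None, 13, "low", "Evacuation of temporal hematoma"),
    (13.9, "female", 13, 6, 1, "low", "Occipital and parietal lobectomy"),
    (14.7, "male", 13, 12, 2, "low",
     "Temporal lobectomy with preservation of medial structures & gross total "
     "resection of enhancing medial temporal lobe tumor"),
    (15.1, "female", 14, 8, 1, "low", "Frontal lobe resection"),
    (15.6, "female", 13, 6, 3, "low", "Functional hemispherectomy"),
    (15.7, "male", 15, 7, 1, "low", "Frontal lesionectomy with corticectomy"),
    (16.1, "male", 10, 0, 6, "high", "Temporal lobectomy with amygdalohippocampectomy"),
    (16.7, "female", 16, 13, 1, "high",
     "Robot-assisted stereotactic laser ablation of mesial temporal lobe "
     "including amygdala and hippocampus (x2)"),
    (16.8, "male", 4, 0, 13, "low", "Functional hemispherectomy"),
    (19.8, "female", 4, 1, 16, "low", "Hemidecortication"),
    (20.5, "male", 18, 13, 3, "low", "Resection of T1 gyrus & Heschl gyrus seizure onset zone"),
    (22.2, "female", 17, 11, 5, "low",
     "Amygdalohippocampectomy, anterior temporal lobectomy, & resection of "
     "mesial temporal lobe tumor"),
]

_ROSTER_LH: list[tuple] = [  # right surgery, preserved LH
    (7.8, "female", 3, 2, 5, "low", "Hemispherotomy"),
    (7.8, "male", 6, 4, 2, "low",
     "Occipital lobectomy, posterior temporal lobectomy, & resection of medial "
     "inferior temporal lobe tumor"),
    (10.9, "female", 10, 4, 1, "high",
     "Robot-assisted stereotactic laser thermal ablation of frontal seizure onset zone"),
    (11.3, "male", 10, 6, 1, "high",
     "Robot-assisted stereotactic laser thermal ablation of amygdala & hippocampus"),
    (11.6, "female", 4, 4, 8, "high", "Temporal lobe lobectomy with amygdalohippocampectomy"),
    (13.1, "female", 12, 10, 1, "high",
     "Robot-assisted stereotactic laser thermal ablation of operculum"),
    (14.4, "female", 13, 3, 1, "high",
     "Robot-assisted stereotactic laser thermal ablation of amygdalar seizure onset zone"),
    (14.8, "female", 8, 0, 7, "low", "Functional hemispherectomy"),
    (15.0, "female", 10, 9, 5, "low",
     "Resection of frontal operculum, frontal pole, & inferior frontal lobe"),
    (15.4, "male", 15, 4, 0, "high",
     "Robot-assisted stereotactic laser thermal ablation of mesial temporal lesion"),
    (16.1, "female", 1, 0, 15, "low", "Hemispherotomy"),
    (16.6, "male", 16, 11, 1, "low",
     "Robot-assisted stereotactic laser ablation of occipito-temporal seizure onset zone (x2)"),
    (17.0, "female", 15, 13, 2, "low", "Anterior temporal lobectomy & hippocampectomy"),
    (17.4, "female", 15, 10, 2, "low",
     "Resection of parietal lobe, premotor, & supplementary motor area"),
    (17.8, "male", 17, 16, 1, "low", "Gross total resection of frontal brain tumor"),
    (18.3, "male", 12, 7, 6, "low", "Parietal lobectomy & posterior temporal lobectomy"),
    (18.7, "female", 9, 0, 10, "low", "Hemispherectomy"),
    (19.4, "male", 14, 6, 5, "high", "Partial resection of parietooccipital tumor (x2)"),
    (20.1, "male", 18, 10, 2, "low",
     "Robot-assisted stereotactic laser thermal ablation of insulo- opercular cortex"),
]


def classify_surgery(description: str) -> str:
    """Classify a surgery description: contains 'ablation' -> ablation, else resection."""
    return "ablation" if "ablation" in description.lower() else "resection"


def generate_table1_roster(scanner: str = "unspecified") -> list[Participant]:
    """The fixed 32-patient roster, exactly as printed."""
    out: list[Participant] = []
    for hemi, block in (("RH", _ROSTER_RH), ("LH", _ROSTER_LH)):
        for i, (age, gender, surg, onset, tfs, ilae, desc) in enumerate(block, start=1):
            out.append(
                Participant(
                    id=f"{hemi}{i:02d}",
                    group="patient",
                    preserved_hemisphere=hemi,
                    age_at_test=float(age),
                    gender=gender,
                    scanner=scanner,
                    surgery_kind=classify_surgery(desc),
                    age_at_surgery=float(surg),
                    seizure_onset_age=None if onset is None else float(onset),
                    time_from_surgery=float(tfs),
                    ilae_binned=ilae,
                )
            )
    return out


def table1_frame() -> pd.DataFrame:
    """The roster as a DataFrame including the surgery descriptions."""
    rows = []
    for hemi, block in (("RH", _ROSTER_RH), ("LH", _ROSTER_LH)):
        for age, gender, surg, onset, tfs, ilae, desc in block:
            rows.append(
                dict(
                    preserved_hemisphere=hemi,
                    age_at_test=age,
                    gender=gender,
                    age_at_surgery=surg,
                    seizure_onset_age=onset,
                    time_from_surgery=tfs,
                    ilae_binned=ilae,
                    surgery=desc,
                    surgery_kind=classify_surgery(desc),
                )
            )
    return pd.DataFrame(rows)
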