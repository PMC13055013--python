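"""Shared data model: participants, the tidy morphometric table, contrasts."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import vocab

HEMISPHERES = ("LH", "RH")
GROUPS = ("patient", "control")
SURGERY_KINDS = ("resection", "ablation", "none")
ILAE_BINS = ("low", "high", "none")
GENDERS = ("female", "male")

CONTRASTS = ("LHpat_vs_LHctrl", "RHpat_vs_RHctrl", "RHpat_vs_LHpat")

KEY_COLUMNS = ["participant_id", "hemisphere", "measure", "region"]
TABLE_COLUMNS = KEY_COLUMNS + ["value"]


class ValidationError(ValueError):
    """A table or participant violates a model invariant."""


@dataclass(frozen=True)
class Participant:
    """One study participant with cohort metadata.

    ``preserved_hemisphere`` is None for controls (both hemispheres
    present); for patients it names the single analyzed hemisphere.
    Clinical ages may be missing (None) and are never imputed.
    """

    id: str
    group: str
    preserved_hemisphere: str | None
    age_at_test: float
    gender: str
    scanner: str
    surgery_kind: str = "none"
    age_at_surgery: float | None = None
    seizure_onset_age: float | None = None
    time_from_surgery: float | None = None
    ilae_binned: str = "none"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"bad group {self.group!r}")
        if self.gender not in GENDERS:
            raise ValidationError(f"bad gender {self.gender!r}")
        if self.surgery_kind not in SURGERY_KINDS:
            raise ValidationError(f"bad surgery_kind {self.surgery_kind!r}")
        if self.ilae_binned not in ILAE_BINS:
            raise ValidationError(f"bad ilae_binned {self.ilae_binned!r}")
        if not (self.age_at_test > 0) or not math.isfinite(self.age_at_test):
            raise ValidationError(f"age_at_test must be positive ({self.id})")
        if self.group == "control":
            if self.preserved_hemisphere is not None:
                raise ValidationError(f"control {self.id} must not fix a hemisphere")
            if self.surgery_kind != "none" or self.ilae_binned != "none":
                raise ValidationError(f"control {self.id} carries surgical fields")
        else:
            if self.preserved_hemisphere not in HEMISPHERES:
                raise ValidationError(f"patient {self.id} needs a preserved hemisphere")
            if self.surgery_kind == "none":
                raise ValidationError(f"patient {self.id} needs a surgery kind")

    @property
    def gender_code(self) -> int:
        # female=0, male=1 covariate coding
        return 0 if self.gender == "female" else 1

    def hemispheres(self) -> tuple[str, ...]:
        if self.group == "control":
            return HEMISPHERES
        return (self.preserved_hemisphere,)


def bin_ilae(ilae_class: int) -> str:
    """Bin raw ILAE outcome classes: 1-3 -> low, 4-6 -> high."""
    if ilae_class in (1, 2, 3):
        return "low"
    if ilae_class in (4, 5, 6):
        return "high"
    raise ValidationError(f"ILAE class must be 1..6, got {ilae_class}")


@dataclass
class MorphometricTable:
    """Tidy per-participant, per-region, per-measure values.

    ``data`` has columns participant_id, hemisphere, measure, region, value;
    keys are unique; regions are canonical for their measure; raw (i.e.
    ``normalized=False``) values are strictly positive.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = self.data.loc[:, TABLE_COLUMNS].reset_index(drop=True)

    def validate(self) -> "MorphometricTable":
        df = self.data
        bad_hemi = set(df["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValidationError(f"unknown hemispheres: {sorted(bad_hemi)}")
        bad_measure = set(df["measure"]) - set(vocab.MEASURES)
        if bad_measure:
            raise ValidationError(f"unknown measures: {sorted(bad_measure)}")
        for measure, grp in df.groupby("measure", sort=False):
            allowed = set(vocab.vocabulary_for(measure))
            bad = sorted(set(grp["region"]) - allowed)
            if bad:
                raise ValidationError(
                    f"regions not in the {measure} vocabulary: {bad}"
                )
        dupes = df[df.duplicated(KEY_COLUMNS, keep=False)]
        if len(dupes):
            keys = dupes[KEY_COLUMNS].drop_duplicates().to_records(index=False)
            raise ValidationError(f"duplicate keys: {list(keys)[:10]}")
        values = df["value"].to_numpy(float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite values present")
        if not self.normalized and not np.all(values > 0):
            raise ValidationError("raw values must be strictly positive")
        return self

    def sorted(self) -> "MorphometricTable":
        df = self.data.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)
        return replace(self, data=df)

    def subset(self, **criteria) -> "MorphometricTable":
        df = self.data
        for col, val in criteria.items():
            allowed = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
            df = df[df[col].isin(list(allowed))]
        return replace(self, data=df.reset_index(drop=True))

    def equals(self, other: "MorphometricTable") -> bool:
        a, b = self.sorted().data, other.sorted().data
        return a.equals(b) and self.normalized == other.normalized

    def __len__(self) -> int:
        return len(self.data)

    def concat(self, other: "MorphometricTable") -> "MorphometricTable":
        if self.normalized != other.normalized:
            raise ValidationError("cannot concatenate tables with mixed normalized flags")
        df = pd.concat([self.data, other.data], ignore_index=True)
        return replace(self, data=df)


def participants_by_id(participants: Iterable[Participant]) -> dict[str, Participant]:
    out: dict[str, Participant] = {}
    for p in participants:
        if p.id in out:
            raise ValidationError(f"duplicate participant id {p.id!r}")
        out[p.id] = p
    return out


def check_hemisphere_coverage(
    table: MorphometricTable, participants: Sequence[Participant]
) -> None:
    """Patients carry exactly their preserved hemisphere; controls carry both."""
    seen = (
        table.data.groupby("participant_id")["hemisphere"]
        .agg(lambda s: frozenset(s))
        .to_dict()
    )
    for p in participants:
        got = seen.get(p.id, frozenset())
        want = frozenset(p.hemispheres())
        if got and got != want:
            raise ValidationError(
                f"{p.id}: expected hemispheres {sorted(want)}, found {sorted(got)}"
            )


META_COLUMNS = [
    "participant_id",
    "hemisphere",
    "group",
    "pat_group",
    "scanner",
    "age",
    "gender",
    "surgery_kind",
    "ilae_binned",
]


def feature_name(measure: str, region: str) -> str:
    return f"{measure}/{region}"


def parse_feature(name: str) -> tuple[str, str]:
    measure, region = name.split("/", 1)
    return measure, region


def feature_columns(frame: pd.DataFrame) -> list[str]:
    return [c for c in frame.columns if "/" in c]


def analysis_frame(
    table: MorphometricTable, participants: Sequence[Participant]
) -> pd.DataFrame:
    """Wide per-(participant, hemisphere) frame with metadata + feature columns.

    Feature columns are named ``measure/region``; metadata columns (group,
    pat_group, scanner, age, gender, surgery_kind, ilae_binned) are plain.
    One row per analysis unit: patients one row, controls two.
    """
    pmap = participants_by_id(participants)
    df = table.data.assign(
        feature=[feature_name(m, r) for m, r in zip(table.data["measure"], table.data["region"])]
    )
    wide = df.pivot_table(
        index=["participant_id", "hemisphere"],
        columns="feature",
        values="value",
        aggfunc="first",
        sort=True,
    ).reset_index()
    part = [pmap[i] for i in wide["participant_id"]]
    meta = pd.DataFrame(index=wide.index)
    meta["participant_id"] = wide["participant_id"]
    meta["hemisphere"] = wide["hemisphere"]
    meta["group"] = [p.group for p in part]
    meta["pat_group"] = [
        "control" if p.group == "control" else f"pat_{p.preserved_hemisphere}"
        for p in part
    ]
    meta["scanner"] = [p.scanner for p in part]
    meta["age"] = [p.age_at_test for p in part]
    meta["gender"] = [p.gender_code for p in part]
    meta["surgery_kind"] = [p.surgery_kind for p in part]
    meta["ilae_binned"] = [p.ilae_binned for p in part]
    features = wide.drop(columns=["participant_id", "hemisphere"])
    return pd.concat([meta, features], axis=1)


def frame_to_table(frame: pd.DataFrame, normalized: bool = True) -> MorphometricTable:
    """Convert an analysis frame's feature columns back into a tidy table."""
    feats = feature_columns(frame)
    n, f = len(frame), len(feats)
    measures, regions = zip(*(parse_feature(c) for c in feats)) if feats else ((), ())
    long = pd.DataFrame(
        {
            "participant_id": np.repeat(frame["participant_id"].to_numpy(), f),
            "hemisphere": np.repeat(frame["hemisphere"].to_numpy(), f),
            "measure": np.tile(np.array(measures, dtype=object), n),
            "region": np.tile(np.array(regions, dtype=object), n),
            "value": frame[feats].to_numpy(float).ravel(),
        }
    ).dropna(subset=["value"])
    return MorphometricTable(long, normalized=normalized).sorted()


def contrast_masks(frame: pd.DataFrame, contrast: str) -> tuple[pd.Series, pd.Series]:
    """(group1, group0) row masks on an analysis frame for a named contrast.

    group1 is the 'patient'/'first' arm whose indicator is coded 1 in the
    GLM; controls contribute only the hemisphere matching the patients'.
    """
    if contrast == "LHpat_vs_LHctrl":
        g1 = (frame["pat_group"] == "pat_LH") & (frame["hemisphere"] == "LH")
        g0 = (frame["group"] == "control") & (frame["hemisphere"] == "LH")
    elif contrast == "RHpat_vs_RHctrl":
        g1 = (frame["pat_group"] == "pat_RH") & (frame["hemisphere"] == "RH")
        g0 = (frame["group"] == "control") & (frame["hemisphere"] == "RH")
    elif contrast == "RHpat_vs_LHpat":
        g1 = (frame["pat_group"] == "pat_RH") & (frame["hemisphere"] == "RH")
        g0 = (frame["pat_group"] == "pat_LH") & (frame["hemisphere"] == "LH")
    else:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    return g1, g0
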