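"""Readers/writers: long CSV/TSV tables, roster CSV, FreeSurfer-dialect stats."""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import vocab
from .types import (
    KEY_COLUMNS,
    MorphometricTable,
    Participant,
    ValidationError,
    participants_by_id,
)

log = logging.getLogger(__name__)

LONG_COLUMNS = [
    "participant_id",
    "group",
    "hemisphere",
    "scanner",
    "age",
    "gender",
    "surgery_kind",
    "ilae_binned",
    "measure",
    "region",
    "value",
]

ROSTER_COLUMNS = [
    "participant_id",
    "group",
    "preserved_hemisphere",
    "age_at_test",
    "gender",
    "scanner",
    "surgery_kind",
    "age_at_surgery",
    "seizure_onset_age",
    "time_from_surgery",
    "ilae_binned",
]


class SchemaError(ValueError):
    """Input file does not carry the required columns."""


class FormatError(ValueError):
    """Input file does not follow the expected dialect."""


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_long_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> tuple[MorphometricTable, list[Participant]]:
    """Read a long-format morphometry CSV/TSV.

    ``schema`` optionally maps canonical column names to the file's column
    names. Returns the validated table plus the reconstructed participants.
    """
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if schema:
        rename = {src: dst for dst, src in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")

    # canonicalize regions up-front so the error names the offending region
    regions = []
    for measure, region in zip(df["measure"], df["region"]):
        regions.append(vocab.canonical_region(str(region), str(measure)))
    df = df.assign(region=regions)

    table = MorphometricTable(df[KEY_COLUMNS + ["value"]].copy()).validate().sorted()

    participants = []
    for pid, grp in df.groupby("participant_id", sort=True):
        row = grp.iloc[0]
        group = str(row["group"])
        hemis = sorted(set(grp["hemisphere"]))
        preserved = None if group == "control" else hemis[0]
        if group == "patient" and len(hemis) != 1:
            raise ValidationError(f"patient {pid} carries both hemispheres")
        participants.append(
            Participant(
                id=str(pid),
                group=group,
                preserved_hemisphere=preserved,
                age_at_test=float(row["age"]),
                gender=str(row["gender"]),
                scanner=str(row["scanner"]),
                surgery_kind=str(row["surgery_kind"]),
                ilae_binned=str(row["ilae_binned"]),
            )
        )
    return table, participants


def write_long_table(
    table: MorphometricTable,
    participants: Sequence[Participant],
    path: str | Path,
) -> None:
    """Write the long CSV/TSV with deterministic column and row order."""
    table.validate()
    pmap = participants_by_id(participants)
    df = table.sorted().data.copy()
    part = [pmap[i] for i in df["participant_id"]]
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "group": [p.group for p in part],
            "hemisphere": df["hemisphere"],
            "scanner": [p.scanner for p in part],
            "age": [p.age_at_test for p in part],
            "gender": [p.gender for p in part],
            "surgery_kind": [p.surgery_kind for p in part],
            "ilae_binned": [p.ilae_binned for p in part],
            "measure": df["measure"],
            "region": df["region"],
            # repr() is the shortest round-trippable decimal form
            "value": [repr(float(v)) for v in df["value"]],
        }
    )
    out.to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n")


def write_roster(participants: Sequence[Participant], path: str | Path) -> None:
    rows = []
    for p in participants:
        rows.append(
            {
                "participant_id": p.id,
                "group": p.group,
                "preserved_hemisphere": p.preserved_hemisphere or "",
                "age_at_test": p.age_at_test,
                "gender": p.gender,
                "scanner": p.scanner,
                "surgery_kind": p.surgery_kind,
                "age_at_surgery": p.age_at_surgery,
                "seizure_onset_age": p.seizure_onset_age,
                "time_from_surgery": p.time_from_surgery,
                "ilae_binned": p.ilae_binned,
            }
        )
    pd.DataFrame(rows, columns=ROSTER_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False, lineterminator="\n"
    )


def read_roster(path: str | Path) -> list[Participant]:
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing roster columns: {missing}")

    def _opt(v):
        return None if pd.isna(v) else float(v)

    out = []
    for _, r in df.iterrows():
        preserved = r["preserved_hemisphere"]
        out.append(
            Participant(
                id=str(r["participant_id"]),
                group=str(r["group"]),
                preserved_hemisphere=None if pd.isna(preserved) or preserved == "" else str(preserved),
                age_at_test=float(r["age_at_test"]),
                gender=str(r["gender"]),
                scanner=str(r["scanner"]),
                surgery_kind=str(r["surgery_kind"]),
                age_at_surgery=_opt(r["age_at_surgery"]),
                seizure_onset_age=_opt(r["seizure_onset_age"]),
                time_from_surgery=_opt(r["time_from_surgery"]),
                ilae_binned=str(r["ilae_binned"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# FreeSurfer stats dialect
# ---------------------------------------------------------------------------

APARC_REQUIRED = ("StructName", "SurfArea", "GrayVol", "ThickAvg")
ASEG_REQUIRED = ("StructName", "Volume_mm3")


def _parse_stats(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    headers = None
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.startswith("ColHeaders"):
                headers = stripped.split()[1:]
            continue
        if line.strip():
            rows.append(line.split())
    if headers is None:
        raise FormatError(f"{path}: no '# ColHeaders' line")
    missing = [c for c in required if c not in headers]
    if missing:
        raise FormatError(f"{path}: ColHeaders lacks {missing}")
    df = pd.DataFrame(rows, columns=headers)
    for col in required:
        if col != "StructName":
            df[col] = df[col].astype(float)
    return df


def read_freesurfer_stats(
    aparc_path: str | Path,
    aseg_path: str | Path,
    hemisphere: str,
    participant_id: str = "subject",
    cerebellum_source: str = "Cerebellum-Cortex",
) -> MorphometricTable:
    """Read one hemisphere's aparc- and aseg-style stats tables.

    Produces one CxT/CSA/CV record per recognized cortical parcel, plus
    subcortical and gross (LV/GM/WM) volume records from the aseg table.
    Unrecognized structure rows are skipped and logged; a parcel count other
    than 34 triggers a coverage warning naming the missing parcels.
    """
    if hemisphere not in ("LH", "RH"):
        raise ValueError("hemisphere must be 'LH' or 'RH'")
    aparc = _parse_stats(aparc_path, APARC_REQUIRED)
    aseg = _parse_stats(aseg_path, ASEG_REQUIRED)

    records = []
    seen = set()
    for _, r in aparc.iterrows():
        region = vocab.try_canonical_region(r["StructName"])
        if region is None or region not in vocab.CORTICAL_34:
            log.warning("skipping unrecognized parcel %r", r["StructName"])
            continue
        seen.add(region)
        for measure, col in ((vocab.CXT, "ThickAvg"), (vocab.CSA, "SurfArea"), (vocab.CV, "GrayVol")):
            records.append((participant_id, hemisphere, measure, region, r[col]))
    if len(seen) != 34:
        missing = sorted(set(vocab.CORTICAL_34) - seen)
        warnings.warn(f"aparc coverage is {len(seen)}/34; missing: {missing}")

    cereb_flat = vocab.flatten_name(cerebellum_source)
    for _, r in aseg.iterrows():
        flat = vocab.flatten_name(r["StructName"])
        if flat.startswith("cerebellum"):
            if flat != cereb_flat:
                continue
            region, measure = "cerebellum", vocab.SUBCORTICAL_VOL
        else:
            region = vocab.try_canonical_region(r["StructName"])
            if region in vocab.SUBCORTICAL_9:
                measure = vocab.SUBCORTICAL_VOL
            elif region in vocab.GROSS_3:
                measure = vocab.GROSS_VOL
            else:
                log.warning("skipping unrecognized structure %r", r["StructName"])
                continue
        records.append((participant_id, hemisphere, measure, region, r["Volume_mm3"]))

    df = pd.DataFrame(
        records, columns=["participant_id", "hemisphere", "measure", "region", "value"]
    )
    return MorphometricTable(df).validate().sorted()


def write_aparc_stats(
    path: str | Path,
    rows: Mapping[str, tuple[float, float, float]],
    hemisphere: str = "LH",
) -> None:
    """Write an aparc-dialect stats file; rows map parcel -> (area, vol, thick)."""
    lines = [
        "# Table of FreeSurfer cortical parcellation anatomical statistics",
        f"# hemi {'lh' if hemisphere == 'LH' else 'rh'}",
        "# ColHeaders StructName SurfArea GrayVol ThickAvg",
    ]
    for name, (area, volume, thick) in rows.items():
        lines.append(f"{name} {float(area)!r} {float(volume)!r} {float(thick)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_aseg_stats(path: str | Path, rows: Mapping[str, float]) -> None:
    """Write an aseg-dialect stats file; rows map structure -> volume mm3."""
    lines = [
        "# Table of FreeSurfer segmentation volume statistics",
        "# ColHeaders Index StructName Volume_mm3",
    ]
    for i, (name, volume) in enumerate(rows.items(), start=1):
        lines.append(f"{i} {name} {float(volume)!r}")
    Path(path).write_text("\n".join(lines) + "\n")
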