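"""Measure-specific normalization and stratified winsorization."""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import vocab
from .types import MorphometricTable, Participant, ValidationError, participants_by_id

log = logging.getLogger(__name__)

DEFAULT_DENOMINATOR = ("GM", "WM", "LV")


class NormalizationError(ValidationError):
    pass


def normalize(
    table: MorphometricTable,
    denominator: Sequence[str] = DEFAULT_DENOMINATOR,
) -> MorphometricTable:
    """Apply the per-measure normalization rules.

    CxT and gross volumes pass through unchanged; CSA is divided by the
    within participant-hemisphere mean of the 34 regional areas; CV is
    divided by the total hemisphere volume (sum of ``denominator`` gross
    volumes); subcortical volumes become percentages of that total.
    Participant-hemispheres lacking the gross volumes are dropped with a
    log entry; an incomplete CSA set is an error (the mean would be biased).
    """
    if table.normalized:
        raise NormalizationError("table is already normalized")
    table.validate()
    df = table.data.copy()
    unit = ["participant_id", "hemisphere"]

    gross = df[df["measure"] == vocab.GROSS_VOL]
    gross_wide = gross.pivot_table(index=unit, columns="region", values="value", aggfunc="first")
    have_all = gross_wide.reindex(columns=list(denominator)).notna().all(axis=1)
    total = gross_wide.reindex(columns=list(denominator)).sum(axis=1)
    total = total[have_all]

    needs_total = df["measure"].isin([vocab.CV, vocab.SUBCORTICAL_VOL])
    keyed = pd.MultiIndex.from_frame(df[unit])
    missing_units = sorted(set(keyed[needs_total]) - set(total.index))
    if missing_units:
        log.warning(
            "excluding %d participant-hemispheres lacking gross volumes: %s",
            len(missing_units),
            missing_units,
        )
        df = df[~(keyed.isin(missing_units))]
        keyed = pd.MultiIndex.from_frame(df[unit])

    csa = df[df["measure"] == vocab.CSA]
    counts = csa.groupby(unit)["region"].nunique()
    bad = counts[counts != 34]
    if len(bad):
        raise NormalizationError(
            f"CSA normalization needs all 34 regions; incomplete: {list(bad.index)}"
        )

    out = df.copy()
    values = out["value"].to_numpy(float).copy()

    csa_mask = (out["measure"] == vocab.CSA).to_numpy()
    if csa_mask.any():
        csa_mean = csa.groupby(unit)["value"].mean()
        values[csa_mask] = values[csa_mask] / csa_mean.loc[keyed[csa_mask]].to_numpy()

    cv_mask = (out["measure"] == vocab.CV).to_numpy()
    if cv_mask.any():
        values[cv_mask] = values[cv_mask] / total.loc[keyed[cv_mask]].to_numpy()

    sub_mask = (out["measure"] == vocab.SUBCORTICAL_VOL).to_numpy()
    if sub_mask.any():
        values[sub_mask] = 100.0 * values[sub_mask] / total.loc[keyed[sub_mask]].to_numpy()

    out = out.assign(value=values)
    return replace(table, data=out.reset_index(drop=True), normalized=True)


def percentile(values: np.ndarray, q: float, method: str = "linear") -> float:
    """Percentile estimate; 'linear' is sorted linear interpolation (type 7),
    'lower' returns an order statistic (and makes winsorization idempotent)."""
    return float(np.percentile(values, q, method=method))


def winsorize(
    values: np.ndarray,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
    method: str = "linear",
) -> np.ndarray:
    """Clip values below/above the estimated percentiles to those estimates."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if arr.size < 2 or not np.all(np.isfinite(arr)):
        raise ValueError("need >= 2 finite values")
    lo = percentile(arr, lower_pct, method)
    hi = percentile(arr, upper_pct, method)
    return np.clip(arr, lo, hi)


def _stratum_of(p: Participant, hemisphere: str) -> str:
    # patients stratified by patient group (which fixes their hemisphere),
    # controls by hemisphere
    if p.group == "control":
        return f"control_{hemisphere}"
    return f"pat_{p.preserved_hemisphere}"


def winsorize_stratified(
    table: MorphometricTable,
    participants: Sequence[Participant],
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
    method: str = "linear",
    min_stratum: int = 3,
) -> MorphometricTable:
    """Winsorize each (measure, region) independently within each
    group-by-hemisphere stratum; strata smaller than ``min_stratum`` pass
    through unchanged (logged). Record count is always preserved."""
    pmap = participants_by_id(participants)
    df = table.data.copy()
    strata = np.array(
        [_stratum_of(pmap[i], h) for i, h in zip(df["participant_id"], df["hemisphere"])]
    )
    values = df["value"].to_numpy(float).copy()
    for (_, _, _), idx in df.groupby(["measure", "region", strata], sort=False).indices.items():
        if len(idx) < min_stratum:
            log.info("stratum with %d obs left unwinsorized", len(idx))
            continue
        values[idx] = winsorize(values[idx], lower_pct, upper_pct, method)
    out = df.assign(value=values)
    return replace(table, data=out)
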