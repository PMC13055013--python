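"""Demographic matching statistics and the gross-vs-regional correlation screen."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import vocab
from .types import MorphometricTable, Participant, analysis_frame, feature_name

log = logging.getLogger(__name__)


def _clean(values) -> np.ndarray:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    return arr[np.isfinite(arr)]


def anova_f(values_a, values_b) -> tuple[float, tuple[int, int], float]:
    """One-way two-group ANOVA; missing values dropped. Returns F, (df1, df2), p."""
    a, b = _clean(values_a), _clean(values_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    f, p = stats.f_oneway(a, b)
    return float(f), (1, len(a) + len(b) - 2), float(p)


def two_prop_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z with a two-sided normal p."""
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n <= 0:
            raise ValueError("need 0 <= k <= n and n > 0")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("pooled proportion is degenerate; z defined as 0")
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def median_mad(values, scaled: bool = False) -> tuple[float, float]:
    """Sample median and median absolute deviation (x1.4826 when scaled)."""
    arr = _clean(values)
    if len(arr) == 0:
        raise ValueError("empty input")
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    if scaled:
        mad *= 1.4826
    return med, mad


@dataclass
class MatchReport:
    """Cohort matching statistics between the two patient groups (and, when
    control composition is supplied, patients vs controls in aggregate)."""

    comparisons: list[dict] = field(default_factory=list)

    def add(self, name: str, kind: str, **fields) -> None:
        self.comparisons.append({"comparison": name, "kind": kind, **fields})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.comparisons)

    def lookup(self, name: str) -> dict:
        for c in self.comparisons:
            if c["comparison"] == name:
                return c
        raise KeyError(name)


def match_report(
    patients: Sequence[Participant],
    control_females: int | None = None,
    control_n: int | None = None,
) -> MatchReport:
    """Between-patient-group matching tests on the roster fields.

    Missing clinical values are dropped pairwise (reflected in df).
    """
    rh = [p for p in patients if p.preserved_hemisphere == "RH"]
    lh = [p for p in patients if p.preserved_hemisphere == "LH"]
    rep = MatchReport()

    for name, attr in (
        ("age_at_test", "age_at_test"),
        ("age_at_surgery", "age_at_surgery"),
        ("seizure_onset_age", "seizure_onset_age"),
    ):
        f, (d1, d2), p = anova_f(
            [getattr(x, attr) for x in rh], [getattr(x, attr) for x in lh]
        )
        rep.add(name, "anova_F", value=f, df1=d1, df2=d2, p=p)

    k_rh = sum(1 for x in rh if x.gender == "female")
    k_lh = sum(1 for x in lh if x.gender == "female")
    z, p = two_prop_z(k_rh, len(rh), k_lh, len(lh))
    rep.add("gender_patients", "two_prop_z", value=z, df=len(rh) + len(lh) - 2, p=p)

    h_rh = sum(1 for x in rh if x.ilae_binned == "high")
    h_lh = sum(1 for x in lh if x.ilae_binned == "high")
    z, p = two_prop_z(h_rh, len(rh), h_lh, len(lh))
    rep.add("ilae_binned", "two_prop_z", value=z, df=len(rh) + len(lh) - 2, p=p)

    for name, attr in (("age_at_test", "age_at_test"), ("time_from_surgery", "time_from_surgery")):
        for label, grp in (("RH", rh), ("LH", lh)):
            med, mad = median_mad([getattr(x, attr) for x in grp])
            rep.add(f"median_{name}_{label}", "median", value=med, mad=mad)

    if control_females is not None and control_n is not None:
        k_pat = k_rh + k_lh
        z, p = two_prop_z(k_pat, len(rh) + len(lh), control_females, control_n)
        rep.add(
            "gender_aggregate",
            "two_prop_z",
            value=z,
            df=len(rh) + len(lh) + control_n - 2,
            p=p,
        )
    return rep


def cross_correlation_screen(
    table: MorphometricTable,
    participants: Sequence[Participant],
    subset: str = "all",
    alpha: float = 0.0002,
) -> pd.DataFrame:
    """Pearson correlations of each gross measure against every cortical
    (CxT/CSA/CV x 34) and subcortical feature within a patient subset
    ('all', 'lh', 'rh'); ``survives`` marks p < alpha."""
    frame = analysis_frame(table, participants)
    if subset == "all":
        rows = frame[frame["group"] == "patient"]
    elif subset.lower() in ("lh", "rh"):
        rows = frame[frame["pat_group"] == f"pat_{subset.upper()}"]
    else:
        raise ValueError("subset must be 'all', 'lh', or 'rh'")

    regional = [
        (m, r) for m in vocab.CORTICAL_MEASURES for r in vocab.CORTICAL_34
    ] + [(vocab.SUBCORTICAL_VOL, r) for r in vocab.SUBCORTICAL_9]

    records = []
    for g in vocab.GROSS_3:
        gcol = rows[feature_name(vocab.GROSS_VOL, g)].to_numpy(float)
        for measure, region in regional:
            x = rows[feature_name(measure, region)].to_numpy(float)
            ok = np.isfinite(gcol) & np.isfinite(x)
            if ok.sum() < 3:
                log.warning("skipping pair %s ~ %s/%s: <3 paired obs", g, measure, region)
                continue
            r, p = stats.pearsonr(gcol[ok], x[ok])
            records.append(
                {
                    "gross": g,
                    "measure": measure,
                    "region": region,
                    "r": float(r),
                    "p": float(p),
                    "n": int(ok.sum()),
                    "survives": bool(p < alpha),
                }
            )
    return pd.DataFrame(records)
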