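"""Per-feature inference: permutation-null GLM, BH correction, Bayes factors.

The group coefficient of an OLS fit (group + age + gender) is compared
against a null distribution built by shuffling the group label; the
two-sided p-value is the exceedance fraction of |beta|. Per measure family,
p-values are Benjamini-Hochberg adjusted across regions, and a BIC-based
Bayes factor adjudicates the group term against the covariate-only model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from . import vocab
from .types import (
    MorphometricTable,
    Participant,
    analysis_frame,
    contrast_masks,
    feature_name,
)

EVIDENCE_ALTERNATIVE = "alternative"
EVIDENCE_NULL = "null"
EVIDENCE_INCONCLUSIVE = "inconclusive"

#: Bayes-factor interpretation thresholds (BF01 scale)
BF_LOWER, BF_UPPER = 0.33, 3.0


@dataclass
class GlmDesign:
    """Response + group indicator + age/gender covariates for one feature."""

    y: np.ndarray
    group: np.ndarray  # 0/1 indicator, 1 = first-named arm
    age: np.ndarray
    gender: np.ndarray  # 0/1
    contrast: str | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.group = np.asarray(self.group, float)
        self.age = np.asarray(self.age, float)
        self.gender = np.asarray(self.gender, float)
        n = len(self.y)
        if not (len(self.group) == len(self.age) == len(self.gender) == n):
            raise ValueError("design vectors must share a length")
        if not (0 < self.group.sum() < n):
            raise ValueError("both groups must be non-empty")

    @property
    def n(self) -> int:
        return len(self.y)

    def matrix(self, with_group: bool = True) -> np.ndarray:
        cols = [np.ones(self.n)]
        if with_group:
            cols.append(self.group)
        cols += [self.age, self.gender]
        return np.column_stack(cols)


@dataclass
class PermutationTestResult:
    contrast: str | None
    measure: str | None
    region: str | None
    beta_obs: float
    null_betas: np.ndarray
    p_raw: float
    n_perm: int
    seed: int | None
    p_bh: float | None = None
    bf01: float | None = None
    evidence_label: str | None = None
    exhaustive: bool = False


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")


def fit_group_glm(design: GlmDesign) -> tuple[float, np.ndarray]:
    """OLS coefficients [intercept, group, age, gender]; returns (beta_group, all)."""
    X = design.matrix()
    _check_rank(X)
    coefs, *_ = np.linalg.lstsq(X, design.y, rcond=None)
    return float(coefs[1]), coefs


def _residualizer(design: GlmDesign) -> np.ndarray:
    """Orthonormal basis Q of the covariate-only design (intercept, age, gender)."""
    Z = design.matrix(with_group=False)
    Q, _ = np.linalg.qr(Z)
    return Q


def _fwl_betas(G: np.ndarray, y: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Group betas for each row of G (shuffled indicators) via FWL residualization.

    Identical to refitting the full OLS per shuffle (unit-tested equality)."""
    Gt = G - (G @ Q) @ Q.T
    yt = y - Q @ (Q.T @ y)
    denom = np.einsum("ij,ij->i", Gt, Gt)
    with np.errstate(invalid="ignore", divide="ignore"):
        betas = (Gt @ yt) / denom
    return np.where(denom > 1e-12, betas, 0.0)


def permutation_p(
    design: GlmDesign,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
    counting: str = "strict",
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Permutation-null p for the group coefficient.

    ``counting='strict'`` implements p = #{|beta_perm| > |beta_obs|}/n_perm;
    ``'plus-one'`` the (b+1)/(n+1) variant. ``exhaustive=True`` enumerates
    every distinct label assignment instead of sampling.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if counting not in ("strict", "plus-one"):
        raise ValueError("counting must be 'strict' or 'plus-one'")
    X = design.matrix()
    _check_rank(X)
    beta_obs, _ = fit_group_glm(design)
    Q = _residualizer(design)

    n1 = int(design.group.sum())
    n_distinct = comb(design.n, n1)
    if exhaustive:
        G = np.zeros((n_distinct, design.n))
        for i, pos in enumerate(combinations(range(design.n), n1)):
            G[i, list(pos)] = 1.0
        n_used = n_distinct
    else:
        if n_perm > n_distinct:
            warnings.warn(
                f"n_perm={n_perm} exceeds the {n_distinct} distinct assignments; "
                "consider exhaustive=True"
            )
        rng = np.random.default_rng(seed)
        G = rng.permuted(np.tile(design.group, (n_perm, 1)), axis=1)
        n_used = n_perm

    null_betas = _fwl_betas(G, design.y, Q)
    # ties at |beta_obs| (e.g. the identity and sign-flipped assignments under
    # exhaustive enumeration) are excluded up to float noise
    tie_tol = 1e-12 * (1.0 + np.abs(beta_obs))
    exceed = int(np.sum(np.abs(null_betas) > np.abs(beta_obs) + tie_tol))
    if counting == "strict":
        tiny = 1e-10 * (np.abs(design.y).max() + 1.0)
        if abs(beta_obs) < tiny and np.all(np.abs(null_betas) < tiny):
            p_raw = 1.0  # degenerate (near-)constant response guard
        else:
            p_raw = exceed / n_used
    else:
        p_raw = (exceed + 1) / (n_used + 1)

    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return PermutationTestResult(
        contrast=design.contrast,
        measure=None,
        region=None,
        beta_obs=beta_obs,
        null_betas=null_betas,
        p_raw=float(p_raw),
        n_perm=n_used,
        seed=seed_int,
        exhaustive=exhaustive,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _ols_bic(X: np.ndarray, y: np.ndarray) -> float:
    coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    n = len(y)
    rss = float(resid @ resid)
    if rss <= 0:
        rss = np.finfo(float).tiny
    return n * np.log(rss / n) + X.shape[1] * np.log(n)


def bayes_factor_01(design: GlmDesign) -> tuple[float, str]:
    """BF01 via the BIC approximation: exp((BIC_full - BIC_null)/2).

    Small BF01 (< 0.33) is evidence for the alternative (group matters);
    large (> 3) for the null.
    """
    X_full = design.matrix(with_group=True)
    X_null = design.matrix(with_group=False)
    if design.n <= X_full.shape[1]:
        raise ValueError("need more observations than parameters")
    _check_rank(X_full)
    bf01 = float(np.exp((_ols_bic(X_full, design.y) - _ols_bic(X_null, design.y)) / 2.0))
    if bf01 < BF_LOWER:
        label = EVIDENCE_ALTERNATIVE
    elif bf01 > BF_UPPER:
        label = EVIDENCE_NULL
    else:
        label = EVIDENCE_INCONCLUSIVE
    return bf01, label


_MEASURE_INDEX = {m: i for i, m in enumerate(vocab.MEASURES)}


def feature_seed(master_seed: int, measure: str, region: str) -> np.random.SeedSequence:
    """Per-feature RNG stream, independent of evaluation order."""
    ri = list(vocab.vocabulary_for(measure)).index(region)
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(_MEASURE_INDEX[measure], ri))


def run_univariate_family(
    table: MorphometricTable,
    participants: Sequence[Participant],
    contrast: str,
    measure: str,
    n_perm: int = 1000,
    seed: int = 0,
    counting: str = "strict",
    bh: bool = True,
) -> list[PermutationTestResult]:
    """Permutation GLM for every region of one measure under one contrast,
    with BH correction across the family and BF adjudication per region."""
    frame = analysis_frame(table, participants)
    g1, g0 = contrast_masks(frame, contrast)
    rows = frame[g1 | g0]
    group = g1[g1 | g0].to_numpy(float)
    results = []
    for region in vocab.vocabulary_for(measure):
        col = feature_name(measure, region)
        if col not in rows.columns:
            raise ValueError(f"feature {col} absent from the table")
        design = GlmDesign(
            y=rows[col].to_numpy(float),
            group=group,
            age=rows["age"].to_numpy(float),
            gender=rows["gender"].to_numpy(float),
            contrast=contrast,
        )
        res = permutation_p(
            design, n_perm=n_perm, seed=feature_seed(seed, measure, region), counting=counting
        )
        res.measure, res.region, res.seed = measure, region, seed
        res.bf01, res.evidence_label = bayes_factor_01(design)
        results.append(res)
    p_adj = bh_adjust([r.p_raw for r in results]) if bh else [r.p_raw for r in results]
    for r, adj in zip(results, p_adj):
        r.p_bh = float(adj)
    return results


def results_frame(results: Sequence[PermutationTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contrast": r.contrast,
                "measure": r.measure,
                "region": r.region,
                "beta": r.beta_obs,
                "p_raw": r.p_raw,
                "p_bh": r.p_bh,
                "bf01": r.bf01,
                "evidence_label": r.evidence_label,
                "n_perm": r.n_perm,
            }
            for r in results
        ]
    )
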