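"""Forward binary logistic regression with Nagelkerke R² banding.

Candidates enter by Rao score test (smallest entry p below the threshold);
the procedure is pure-forward. Fits are Newton/IRLS with step-halving and
a separation flag; separated candidates are skipped, not selected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import vocab
from .types import (
    MorphometricTable,
    Participant,
    analysis_frame,
    contrast_masks,
    feature_name,
)

log = logging.getLogger(__name__)

FAMILIES = {
    "gross": vocab.GROSS_VOL,
    "cxt": vocab.CXT,
    "csa": vocab.CSA,
    "cv": vocab.CV,
    "subcortical": vocab.SUBCORTICAL_VOL,
}

OUTCOMES = ("LHpat_vs_LHctrl", "RHpat_vs_RHctrl", "RHpat_vs_LHpat", "ilae_high_vs_low")

STRENGTH_NOT_REPORTED = "not_reported"


class SeparationError(RuntimeError):
    pass


@dataclass
class LogisticFit:
    coef: np.ndarray  # [intercept, slopes...]
    loglik: float
    converged: bool
    separated: bool
    n_iter: int


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable sum y*eta - log(1+exp(eta))
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    add_intercept: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by Newton/IRLS.

    Converges on an absolute log-likelihood change below ``tol``. Complete
    or quasi-complete separation is flagged (diverging coefficients /
    saturated probabilities at the iteration cap) rather than raised.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.ndim == 2 and X.shape[0] == 1 and len(y) > 1:
        X = X.T
    y = np.asarray(y, float)
    n = len(y)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
    p_params = X.shape[1]
    if n <= p_params:
        raise ValueError("need n > number of parameters")
    if np.any(np.ptp(X[:, 1:], axis=0) == 0) if p_params > 1 else False:
        raise ValueError("constant predictor column")

    beta = np.zeros(p_params)
    ll = _loglik(X @ beta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p_params), grad)
        except np.linalg.LinAlgError:
            break
        # step-halving to guarantee likelihood ascent
        new_ll, scale = ll, 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_ll = _loglik(X @ cand, y)
            if cand_ll >= ll - 1e-14:
                beta, new_ll = cand, cand_ll
                break
            scale *= 0.5
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    eta = X @ beta
    perfectly_classified = bool(np.all((2.0 * y - 1.0) * eta > 0)) and p_params > 1
    separated = (
        (perfectly_classified and np.abs(eta).max() > 10)
        or (not converged and np.abs(beta).max() > 50)
        or np.abs(beta).max() > 1e3
    )
    return LogisticFit(coef=beta, loglik=ll, converged=converged, separated=separated, n_iter=it)


def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    """Rescaled likelihood-ratio pseudo-R² in [0, 1]."""
    if n == 0:
        raise ValueError("n must be > 0")
    if loglik_full < loglik_null - 1e-10:
        raise ValueError("loglik_full must be >= loglik_null")
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    max_cs = 1.0 - np.exp(2.0 * loglik_null / n)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def strength_band(r2: float) -> str:
    """Bands: < 0.2 weak, [0.2, 0.4) moderate, >= 0.4 strong; r² <= 0.25 is
    additionally below the reporting floor -> 'not_reported'."""
    if r2 <= 0.25:
        return STRENGTH_NOT_REPORTED
    return "moderate" if r2 < 0.4 else "strong"


def score_test(
    X_current: np.ndarray, fit: LogisticFit, x_new: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Rao score test for adding ``x_new`` to a fitted logistic model."""
    n = len(y)
    Xc = np.column_stack([np.ones(n), np.atleast_2d(X_current).reshape(n, -1)]) \
        if X_current is not None and np.size(X_current) else np.ones((n, 1))
    eta = Xc @ fit.coef
    mu = expit(eta)
    w = mu * (1.0 - mu)
    U = float(x_new @ (y - mu))
    A = float((x_new * w) @ x_new)
    B = (x_new * w) @ Xc
    C = (Xc * w[:, None]).T @ Xc
    var = A - float(B @ np.linalg.solve(C, B))
    if var <= 1e-12:
        return 0.0, 1.0
    stat = U * U / var
    return stat, float(stats.chi2.sf(stat, df=1))


@dataclass
class SelectionResult:
    outcome: str
    candidates: list[str]
    selected: list[str] = field(default_factory=list)
    entry_p: list[float] = field(default_factory=list)
    coefficients: dict[str, float] = field(default_factory=dict)
    loglik_full: float = 0.0
    loglik_null: float = 0.0
    nagelkerke_r2: float = 0.0
    strength: str = STRENGTH_NOT_REPORTED
    alpha_entry: float = 0.05
    skipped_separated: list[str] = field(default_factory=list)
    viable: bool = False

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "candidates": self.candidates,
            "selected": self.selected,
            "entry_p": self.entry_p,
            "coefficients": self.coefficients,
            "loglik_full": self.loglik_full,
            "loglik_null": self.loglik_null,
            "nagelkerke_r2": self.nagelkerke_r2,
            "strength": self.strength,
            "alpha_entry": self.alpha_entry,
            "skipped_separated": self.skipped_separated,
            "viable": self.viable,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def forward_select(
    candidates: pd.DataFrame,
    y: np.ndarray,
    alpha_entry: float = 0.05,
    outcome: str = "outcome",
    forced: pd.DataFrame | None = None,
) -> SelectionResult:
    """Pure-forward selection with Rao score entry tests.

    At each step the candidate with the smallest score-test p enters while
    that p < ``alpha_entry`` (ties broken by column order). Candidates whose
    inclusion produces a separated fit are skipped with a warning. ``forced``
    columns are always in the model but never counted as selections.
    """
    y = np.asarray(y, float)
    if len(set(np.unique(y))) != 2:
        raise ValueError("y must contain both classes")
    names = list(candidates.columns)
    result = SelectionResult(outcome=outcome, candidates=names, alpha_entry=alpha_entry)

    forced_X = forced.to_numpy(float) if forced is not None else np.empty((len(y), 0))
    in_model: list[str] = []
    excluded: set[str] = set()

    def model_matrix(cols: list[str]) -> np.ndarray:
        parts = [forced_X] + [candidates[c].to_numpy(float)[:, None] for c in cols]
        return np.hstack(parts)

    current = logistic_fit(model_matrix([]), y) if forced_X.size else logistic_fit(
        np.empty((len(y), 0)), y, add_intercept=True
    )
    null_fit = logistic_fit(np.empty((len(y), 0)), y, add_intercept=True)

    while True:
        pool = [c for c in names if c not in in_model and c not in excluded]
        if not pool:
            break
        Xc = model_matrix(in_model)
        best_name, best_p = None, np.inf
        for c in pool:  # column order breaks ties
            _, p = score_test(Xc, current, candidates[c].to_numpy(float), y)
            if p < best_p - 1e-15:
                best_name, best_p = c, p
        if best_name is None or best_p >= alpha_entry:
            break
        trial = logistic_fit(model_matrix(in_model + [best_name]), y)
        if trial.separated:
            log.warning("candidate %s causes separation; skipped", best_name)
            result.skipped_separated.append(best_name)
            excluded.add(best_name)
            continue
        in_model.append(best_name)
        result.entry_p.append(float(best_p))
        current = trial

    result.selected = in_model
    result.loglik_null = null_fit.loglik
    if in_model:
        result.viable = True
        final = logistic_fit(model_matrix(in_model), y)
        coef_names = (
            ["intercept"]
            + (list(forced.columns) if forced is not None else [])
            + in_model
        )
        result.coefficients = dict(zip(coef_names, map(float, final.coef)))
        result.loglik_full = final.loglik
        result.nagelkerke_r2 = nagelkerke_r2(final.loglik, null_fit.loglik, len(y))
        result.strength = strength_band(result.nagelkerke_r2)
    else:
        result.loglik_full = null_fit.loglik
    return result


def run_multivariate(
    table: MorphometricTable,
    participants: Sequence[Participant],
    outcome: str,
    family: str,
    alpha_entry: float = 0.05,
    force_covariates: bool = False,
) -> SelectionResult:
    """Forward logistic classification of one outcome from one feature family."""
    measure = FAMILIES[family.lower()]
    frame = analysis_frame(table, participants)
    if outcome == "ilae_high_vs_low":
        rows = frame[frame["group"] == "patient"]
        y = (rows["ilae_binned"] == "high").to_numpy(float)
        if y.sum() in (0, len(y)):
            raise ValueError("both ILAE classes must be present")
    elif outcome in OUTCOMES:
        g1, g0 = contrast_masks(frame, outcome)
        rows = frame[g1 | g0]
        y = g1[g1 | g0].to_numpy(float)
    else:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")

    cols = [feature_name(measure, r) for r in vocab.vocabulary_for(measure)]
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")
    candidates = rows[cols]
    forced = rows[["age", "gender"]].astype(float) if force_covariates else None
    result = forward_select(
        candidates, y, alpha_entry=alpha_entry, outcome=f"{outcome}:{family}", forced=forced
    )
    return result
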