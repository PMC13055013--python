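"""Empirical-Bayes location/scale batch harmonization across scanners.

Per feature, values are modeled as intercept + covariates (group, age,
gender) + additive scanner effect, with a multiplicative scanner effect on
the residual scale. Scanner effects are shrunk across features with
parametric empirical-Bayes priors (normal for location, inverse-gamma for
scale) and removed, while covariate structure is restored.

The estimator follows the standard parametric procedure: per-feature least
squares under a zero-weighted-mean constraint on the batch effects,
standardization by the pooled residual scale, method-of-moments
hyperparameters across features within batch, and iterated conditional
posterior updates to convergence. Per-batch scale estimates use the
population (1/n_b) variance so that a single-batch fit is an exact
identity transform (see the project ledger for the convention note).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    MorphometricTable,
    Participant,
    analysis_frame,
    feature_columns,
    frame_to_table,
)


class HarmonizationError(RuntimeError):
    pass


@dataclass
class HarmonizationModel:
    """Fitted per-feature location/scale model with per-scanner EB effects."""

    features: list[str]  # "measure/region" names
    batches: list[str]
    covariate_names: list[str]
    alpha: np.ndarray  # (f,) grand intercept
    beta: np.ndarray  # (p, f) covariate coefficients
    var_pooled: np.ndarray  # (f,)
    gamma_hat: np.ndarray  # (b, f) raw additive effects
    delta_sq_hat: np.ndarray  # (b, f) raw multiplicative effects (variance scale)
    gamma_star: np.ndarray  # (b, f) EB-shrunk
    delta_sq_star: np.ndarray  # (b, f) EB-shrunk, > 0
    gamma_bar: np.ndarray  # (b,) prior means
    tau_sq: np.ndarray  # (b,) prior variances
    a_prior: np.ndarray  # (b,) inverse-gamma shape
    b_prior: np.ndarray  # (b,) inverse-gamma scale
    n_iter: list[int] = field(default_factory=list)
    tolerance: float = 1e-4

    def to_json(self, path) -> None:
        payload = {
            "features": list(self.features),
            "batches": self.batches,
            "covariate_names": self.covariate_names,
            "tolerance": self.tolerance,
            "n_iter": self.n_iter,
        }
        for name in (
            "alpha", "beta", "var_pooled", "gamma_hat", "delta_sq_hat",
            "gamma_star", "delta_sq_star", "gamma_bar", "tau_sq",
            "a_prior", "b_prior",
        ):
            payload[name] = np.asarray(getattr(self, name)).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HarmonizationModel":
        with open(path) as fh:
            payload = json.load(fh)
        kwargs = dict(
            features=list(payload["features"]),
            batches=payload["batches"],
            covariate_names=payload["covariate_names"],
            tolerance=payload["tolerance"],
            n_iter=payload["n_iter"],
        )
        for name in (
            "alpha", "beta", "var_pooled", "gamma_hat", "delta_sq_hat",
            "gamma_star", "delta_sq_star", "gamma_bar", "tau_sq",
            "a_prior", "b_prior",
        ):
            kwargs[name] = np.asarray(payload[name], dtype=float)
        return cls(**kwargs)


def _covariate_design(frame: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Covariate columns (no intercept). 'group' expands to patient-group dummies."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov == "group":
            groups = sorted(set(frame["pat_group"]) - {"control"})
            for g in groups:
                cols.append((frame["pat_group"] == g).to_numpy(float))
                names.append(f"group[{g}]")
        else:
            cols.append(frame[cov].to_numpy(float))
            names.append(cov)
    X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    return X, names


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (n * t2 * g_hat + d_star * g_bar) / (n * t2 + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _it_sol(z_batch, g_hat, d_hat_sq, g_bar, t2, a, b, tol, max_iter=200):
    """Iterated conditional posteriors for one batch; returns (gamma*, delta*^2, iters)."""
    n = z_batch.shape[0]
    g_old, d_old = g_hat.copy(), d_hat_sq.copy()
    for it in range(1, max_iter + 1):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum_sq = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum_sq, n, a, b)
        change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
        g_old, d_old = g_new, d_new
        if change < tol:
            return g_old, d_old, it
    raise HarmonizationError(
        f"EB posterior updates did not converge in {max_iter} iterations "
        f"(last change {change:.3g}, tol {tol:.3g})"
    )


def fit_harmonization(
    table: MorphometricTable,
    participants: Sequence[Participant],
    covariates: Sequence[str] = ("group", "age", "gender"),
    tolerance: float = 1e-4,
    max_iter: int = 200,
) -> HarmonizationModel:
    """Fit the location/scale batch model on every (measure, region) feature."""
    frame = analysis_frame(table, participants)
    feats = feature_columns(frame)
    Y = frame[feats].to_numpy(float)
    if np.isnan(Y).any():
        raise HarmonizationError("incomplete feature matrix (missing values)")
    batches = sorted(set(frame["scanner"]))
    batch_idx = np.array([batches.index(s) for s in frame["scanner"]])
    counts = np.bincount(batch_idx, minlength=len(batches))
    singletons = [b for b, c in zip(batches, counts) if c < 2]
    if singletons:
        raise HarmonizationError(f"scanners with <2 observations: {singletons}")

    n, f = Y.shape
    B = np.zeros((n, len(batches)))
    B[np.arange(n), batch_idx] = 1.0
    X, cov_names = _covariate_design(frame, covariates)
    D = np.hstack([B, X])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise HarmonizationError("design matrix is rank deficient")

    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    batch_coef = coef[: len(batches), :]
    beta = coef[len(batches):, :]
    weights = counts / n
    alpha = weights @ batch_coef  # grand intercept; enforces sum n_b*gamma_b = 0

    resid = Y - D @ coef
    var_pooled = (resid**2).mean(axis=0)
    if np.any(var_pooled <= 0):
        raise HarmonizationError("zero pooled residual variance")

    stand_mean = alpha[None, :] + X @ beta
    Z = (Y - stand_mean) / np.sqrt(var_pooled)[None, :]

    nb = len(batches)
    gamma_hat = np.zeros((nb, f))
    delta_sq_hat = np.zeros((nb, f))
    for b in range(nb):
        zb = Z[batch_idx == b]
        gamma_hat[b] = zb.mean(axis=0)
        delta_sq_hat[b] = zb.var(axis=0, ddof=0)  # 1/n_b, matches var_pooled convention

    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    m = delta_sq_hat.mean(axis=1)
    s2 = delta_sq_hat.var(axis=1, ddof=1)

    gamma_star = np.zeros_like(gamma_hat)
    delta_sq_star = np.zeros_like(delta_sq_hat)
    iters: list[int] = []
    for b in range(nb):
        zb = Z[batch_idx == b]
        if s2[b] < 1e-12 or tau_sq[b] < 1e-12:
            # degenerate prior (e.g. single batch): no shrinkage
            gamma_star[b], delta_sq_star[b] = gamma_hat[b], delta_sq_hat[b]
            iters.append(0)
            continue
        a_b = (2.0 * s2[b] + m[b] ** 2) / s2[b]
        b_b = (m[b] * s2[b] + m[b] ** 3) / s2[b]
        g, d, it = _it_sol(
            zb, gamma_hat[b], delta_sq_hat[b], gamma_bar[b], tau_sq[b], a_b, b_b,
            tol=tolerance, max_iter=max_iter,
        )
        gamma_star[b], delta_sq_star[b] = g, d
        iters.append(it)

    a_prior = np.where(s2 > 1e-12, (2.0 * s2 + m**2) / np.where(s2 > 1e-12, s2, 1.0), np.nan)
    b_prior = np.where(s2 > 1e-12, (m * s2 + m**3) / np.where(s2 > 1e-12, s2, 1.0), np.nan)

    if np.any(delta_sq_star <= 0):
        raise HarmonizationError("non-positive shrunken scale estimate")

    return HarmonizationModel(
        features=feats,
        batches=batches,
        covariate_names=cov_names,
        alpha=alpha,
        beta=beta,
        var_pooled=var_pooled,
        gamma_hat=gamma_hat,
        delta_sq_hat=delta_sq_hat,
        gamma_star=gamma_star,
        delta_sq_star=delta_sq_star,
        gamma_bar=gamma_bar,
        tau_sq=tau_sq,
        a_prior=a_prior,
        b_prior=b_prior,
        n_iter=iters,
        tolerance=tolerance,
    )


def apply_harmonization(
    table: MorphometricTable,
    participants: Sequence[Participant],
    model: HarmonizationModel,
    covariates: Sequence[str] | None = None,
) -> MorphometricTable:
    """Remove scanner effects: y* = sigma/delta* (z - gamma*) + alpha + X beta."""
    frame = analysis_frame(table, participants)
    feats = feature_columns(frame)
    if feats != model.features:
        raise HarmonizationError("feature set differs from the fitted model")
    unseen = sorted(set(frame["scanner"]) - set(model.batches))
    if unseen:
        raise HarmonizationError(f"unseen scanner labels: {unseen}")

    Y = frame[feats].to_numpy(float)
    batch_idx = np.array([model.batches.index(s) for s in frame["scanner"]])
    covs = covariates or ["group" if n.startswith("group[") else n for n in model.covariate_names]
    # rebuild with the same dummy expansion
    X, names = _covariate_design(frame, list(dict.fromkeys(covs)))
    if names != model.covariate_names:
        raise HarmonizationError(
            f"covariate design {names} differs from fitted {model.covariate_names}"
        )
    stand_mean = model.alpha[None, :] + X @ model.beta
    sigma = np.sqrt(model.var_pooled)[None, :]
    Z = (Y - stand_mean) / sigma
    Z_adj = (Z - model.gamma_star[batch_idx, :]) / np.sqrt(model.delta_sq_star)[batch_idx, :]
    Y_star = Z_adj * sigma + stand_mean

    out = frame.copy()
    out[feats] = Y_star
    return frame_to_table(out, normalized=table.normalized)
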