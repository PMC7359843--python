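"""Redundancy analysis (RDA) of genotype matrices on environmental
predictors, partial RDA with conditioning covariates, permutation tests,
and standard-deviation loading outliers.

RDA regresses the centred dosage matrix Y (samples x SNPs) on standardised
predictors X by multivariate least squares; the SVD of the fitted values
gives the constrained ordination axes.  Global significance uses a
pseudo-F permutation test over rows of X; marginal predictor tests permute
one predictor's residuals given the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RdaResult:
    sample_scores: np.ndarray      # n x k site scores on constrained axes
    snp_loadings: np.ndarray       # p x k SNP loadings
    eigenvalues: np.ndarray        # k, non-increasing
    var_explained: np.ndarray      # k, proportion of total Y variance
    predictor_correlations: pd.DataFrame  # predictor x axis correlations
    p_global: float | None
    p_marginal: dict | None
    total_variance: float
    constrained_variance: float
    residual_variance: float


def _prepare_Y(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, float)
    if np.isnan(Y).any():
        col_mean = np.nanmean(Y, axis=0)
        Y = np.where(np.isnan(Y), col_mean, Y)
    return Y - Y.mean(axis=0)


def _prepare_X(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(float)
    else:
        Xm = np.asarray(X, float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{i}" for i in range(Xm.shape[1])]
    sd = Xm.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("dropping constant predictor column(s)")
        keep = sd > 0
        Xm, names = Xm[:, keep], [n for n, k in zip(names, keep) if k]
        sd = sd[keep]
    Xs = (Xm - Xm.mean(axis=0)) / sd
    # drop collinear columns by rank-revealing QR
    q, r = np.linalg.qr(Xs)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-8 * max(diag.max(), 1.0)
    if not keep.all():
        warnings.warn("dropping collinear predictor column(s)")
        Xs = Xs[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return Xs, names


def _fit_core(Yc: np.ndarray, Xs: np.ndarray):
    """Least-squares fit + SVD of fitted values; returns scores, loadings,
    eigenvalues and the constrained sum of squares."""
    n = Yc.shape[0]
    B, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    Yhat = Xs @ B
    u, s, vt = np.linalg.svd(Yhat, full_matrices=False)
    k = min(Xs.shape[1], np.sum(s > 1e-10 * max(s.max(), 1.0)))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    eig = s**2 / (n - 1)
    scores = u * s                      # site scores (scaling 1 flavour)
    loadings = vt.T                     # unit-norm SNP loadings per axis
    ss_constrained = float(np.sum(Yhat**2))
    return scores, loadings, eig, ss_constrained


def rda_fit(Y, X, n_perm: int = 1000, rng=None, marginal: bool = True) -> RdaResult:
    """Redundancy analysis of Y (samples x SNPs) on predictors X.

    Missing dosages are mean-imputed per SNP and Y columns centred;
    predictors are standardised.  Permutation p-values use the pseudo-F
    statistic with rows of X permuted.
    """
    rng = np.random.default_rng(rng)
    Yc = _prepare_Y(Y)
    Xs, names = _prepare_X(X)
    n, q = Xs.shape
    ss_total = float(np.sum(Yc**2))
    scores, loadings, eig, ss_con = _fit_core(Yc, Xs)
    ss_res = ss_total - ss_con

    def pseudo_f(ss_c, ss_r, q_):
        return (ss_c / q_) / (ss_r / (n - 1 - q_))

    f_obs = pseudo_f(ss_con, ss_res, q)
    p_global = None
    if n_perm > 0:
        hits = 1
        for _ in range(n_perm):
            perm = rng.permutation(n)
            ss_c = _constrained_ss(Yc, Xs[perm])
            if pseudo_f(ss_c, ss_total - ss_c, q) >= f_obs:
                hits += 1
        p_global = hits / (n_perm + 1)

    p_marginal = None
    if marginal and n_perm > 0 and q > 1:
        p_marginal = {}
        for j, nm in enumerate(names):
            others = np.delete(Xs, j, axis=1)
            ss_red = _constrained_ss(Yc, others)
            extra_obs = ss_con - ss_red
            # permute the focal predictor's residuals given the others
            bj, *_ = np.linalg.lstsq(others, Xs[:, j], rcond=None)
            fitted_j = others @ bj
            resid_j = Xs[:, j] - fitted_j
            hits = 1
            for _ in range(n_perm):
                xj = fitted_j + resid_j[rng.permutation(n)]
                ss_c = _constrained_ss(Yc, np.column_stack([others, xj]))
                if ss_c - ss_red >= extra_obs:
                    hits += 1
            p_marginal[nm] = hits / (n_perm + 1)

    with np.errstate(invalid="ignore"):
        cors = np.zeros((len(names), scores.shape[1]))
        for j in range(len(names)):
            for ax in range(scores.shape[1]):
                if scores[:, ax].std() > 0:
                    cors[j, ax] = np.corrcoef(Xs[:, j], scores[:, ax])[0, 1]
    cor_df = pd.DataFrame(
        cors, index=names, columns=[f"RDA{i+1}" for i in range(scores.shape[1])]
    )
    return RdaResult(
        sample_scores=scores,
        snp_loadings=loadings,
        eigenvalues=eig,
        var_explained=eig * (Y.shape[0] - 1) / ss_total if ss_total > 0 else eig * 0,
        predictor_correlations=cor_df,
        p_global=p_global,
        p_marginal=p_marginal,
        total_variance=ss_total,
        constrained_variance=ss_con,
        residual_variance=ss_res,
    )


def _constrained_ss(Yc, Xs):
    B, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    return float(np.sum((Xs @ B) ** 2))


def partial_rda(Y, X, Z, n_perm: int = 1000, rng=None) -> RdaResult:
    """Partial RDA: the effect of X on Y conditioned on covariates Z.

    Both Y and X are replaced by their residuals from least squares on the
    standardised conditioning matrix, then analysed with rda_fit.  An empty
    Z reduces to plain RDA.
    """
    if Z is None or (hasattr(Z, "shape") and np.size(Z) == 0) or (
        isinstance(Z, pd.DataFrame) and Z.shape[1] == 0
    ):
        return rda_fit(Y, X, n_perm=n_perm, rng=rng)
    Yc = _prepare_Y(Y)
    Zs, _ = _prepare_X(Z)
    Zi = np.column_stack([np.ones(Zs.shape[0]), Zs])
    By, *_ = np.linalg.lstsq(Zi, Yc, rcond=None)
    Yr = Yc - Zi @ By
    Xs, names = _prepare_X(X)
    Bx, *_ = np.linalg.lstsq(Zi, Xs, rcond=None)
    Xr = Xs - Zi @ Bx
    Xr_df = pd.DataFrame(Xr, columns=names)
    # Xr columns may be near-constant if X lies in span(Z)
    if np.all(Xr.std(axis=0) < 1e-12):
        zero = RdaResult(
            sample_scores=np.zeros((Y.shape[0], 1)),
            snp_loadings=np.zeros((Y.shape[1], 1)),
            eigenvalues=np.zeros(1),
            var_explained=np.zeros(1),
            predictor_correlations=pd.DataFrame(
                np.zeros((len(names), 1)), index=names, columns=["RDA1"]
            ),
            p_global=1.0,
            p_marginal=None,
            total_variance=float(np.sum(Yr**2)),
            constrained_variance=0.0,
            residual_variance=float(np.sum(Yr**2)),
        )
        return zero
    return rda_fit(Yr, Xr_df, n_perm=n_perm, rng=rng)


def loading_outliers(
    result: RdaResult, n_axes: int = 1, sd_cutoff: float = 3.0
) -> np.ndarray:
    """Indices of SNPs whose loading on any of the first n_axes deviates from
    the axis mean by more than sd_cutoff standard deviations (deduplicated,
    sorted)."""
    if result.snp_loadings.shape[1] < n_axes:
        raise ValueError(
            f"result has {result.snp_loadings.shape[1]} axes, need {n_axes}"
        )
    hits = set()
    for ax in range(n_axes):
        load = result.snp_loadings[:, ax]
        if sd_cutoff == 0:
            hits.update(range(len(load)))
            continue
        mu, sd = load.mean(), load.std()
        if sd == 0:
            continue
        hits.update(np.flatnonzero(np.abs(load - mu) > sd_cutoff * sd).tolist())
    return np.array(sorted(hits), dtype=int)
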