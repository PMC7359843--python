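"""Approximate Bayesian computation: model choice, parameter estimation,
posterior diagnostics, and the unit conversions used to report results.

The reference table is a DataFrame produced by
:func:`popgenpipe.demography.simulate_summary_table` (one simulated dataset
per row: model name, drawn parameters, summary statistics).  Distances are
Euclidean on summary statistics standardised by their table-wide median
absolute deviation; model probabilities come from multinomial logistic
regression on the accepted rows (falling back to rejection proportions),
and parameter posteriors from rejection with a local-linear regression
adjustment of accepted draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import SUMMARY_STAT_NAMES


@dataclass
class ModelPosterior:
    probabilities: dict
    winner: str
    tolerance: float

    def renormalized(self, models: list[str]) -> "ModelPosterior":
        sub = {m: self.probabilities.get(m, 0.0) for m in models}
        tot = sum(sub.values())
        if tot <= 0:
            sub = {m: 1.0 / len(models) for m in models}
        else:
            sub = {m: v / tot for m, v in sub.items()}
        return ModelPosterior(sub, max(sub, key=sub.get), self.tolerance)


@dataclass
class ParameterPosterior:
    estimates: pd.DataFrame  # index = parameter, columns median/lo95/hi95/prior_overlap
    differentiated: dict
    tolerance: float


def _standardize(stats: np.ndarray, observed: np.ndarray):
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    scale = np.where(mad > 0, mad, stats.std(axis=0))
    keep = scale > 0
    if not np.any(keep):
        raise ValueError("all summary statistics are constant in the table")
    z = (stats[:, keep] - med[keep]) / scale[keep]
    zobs = (observed[keep] - med[keep]) / scale[keep]
    return z, zobs


def _accept(stats, observed, tolerance):
    z, zobs = _standardize(stats, observed)
    d = np.sqrt(((z - zobs) ** 2).sum(axis=1))
    n_keep = max(int(np.ceil(tolerance * len(d))), 100)
    n_keep = min(n_keep, len(d))
    if n_keep < 50:
        raise ValueError(
            f"tolerance {tolerance} retains only {n_keep} simulations (<50)"
        )
    order = np.argsort(d)[:n_keep]
    return order, d, z, zobs


def abc_model_choice(
    observed: np.ndarray,
    sims: pd.DataFrame,
    tolerance: float = 0.005,
    hierarchical: bool = False,
    seed: int = 0,
) -> ModelPosterior:
    """Posterior model probabilities by rejection plus multinomial logistic
    regression on the accepted rows.

    With hierarchical=True the base scenario family is chosen first (variant
    probabilities summed within family), then the heterogeneity variant
    within the winning family.
    """
    stats = sims[list(SUMMARY_STAT_NAMES)].to_numpy()
    labels = sims["model"].to_numpy()
    accepted, d, z, zobs = _accept(stats, observed, tolerance)
    acc_labels = labels[accepted]
    uniq = sorted(set(labels))

    probs = _classify(z[accepted], acc_labels, zobs, uniq, seed)

    if hierarchical:
        fams = sorted({m.split("_")[0] for m in uniq})
        fam_of = {m: m.split("_")[0] for m in uniq}
        fam_probs = {f: sum(v for m, v in probs.items() if fam_of[m] == f) for f in fams}
        best_fam = max(fam_probs, key=fam_probs.get)
        within = [m for m in uniq if fam_of[m] == best_fam]
        sub_mask = np.isin(acc_labels, within)
        if sub_mask.sum() >= 10:
            sub_probs = _classify(
                z[accepted][sub_mask], acc_labels[sub_mask], zobs, within, seed
            )
        else:
            tot = sum(probs[m] for m in within) or 1.0
            sub_probs = {m: probs[m] / tot for m in within}
        probs = {m: fam_probs[fam_of[m]] * sub_probs.get(m, 0.0) for m in uniq}
        # renormalise guard
        tot = sum(probs.values())
        probs = {m: v / tot for m, v in probs.items()}

    winner = max(probs, key=probs.get)
    return ModelPosterior(probs, winner, tolerance)


def _classify(z_acc, labels_acc, zobs, classes, seed):
    counts = pd.Series(labels_acc).value_counts()
    rejection = {m: counts.get(m, 0) / len(labels_acc) for m in classes}
    present = [m for m in classes if counts.get(m, 0) > 0]
    if len(present) < 2:
        return rejection
    try:
        from sklearn.linear_model import LogisticRegression

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LogisticRegression(max_iter=500, random_state=seed)
            clf.fit(z_acc, labels_acc)
            p = clf.predict_proba(zobs.reshape(1, -1))[0]
        probs = {m: 0.0 for m in classes}
        for m, v in zip(clf.classes_, p):
            probs[m] = float(v)
        return probs
    except Exception:
        return rejection


LOG_SCALE_PARAMS = {"N_anc", "N_pop1", "N_pop2", "T_split", "T_am", "T_sc"}


def abc_estimate_params(
    observed: np.ndarray,
    sims: pd.DataFrame,
    parameters: list[str],
    tolerance: float = 0.005,
) -> ParameterPosterior:
    """Rejection plus Beaumont-style local-linear regression adjustment.

    Positive-scale parameters (sizes, times) are adjusted on the log scale.
    The prior-overlap diagnostic per parameter is the fraction of posterior
    draws falling inside the central 50% of the prior (the full table's
    marginal); a posterior indistinguishable from the prior sits near 0.5.
    """
    stats = sims[list(SUMMARY_STAT_NAMES)].to_numpy()
    accepted, d, z, zobs = _accept(stats, observed, tolerance)
    d_acc = d[accepted]
    d_max = d_acc.max() if d_acc.max() > 0 else 1.0
    w = 1.0 - (d_acc / d_max) ** 2  # Epanechnikov
    w = np.where(w > 0, w, 1e-8)

    X = z[accepted]
    Xc = np.column_stack([np.ones(len(X)), X - zobs])
    rows = {}
    differentiated = {}
    for par in parameters:
        theta = sims[par].to_numpy()[accepted].astype(float)
        use_log = par in LOG_SCALE_PARAMS and np.all(theta > 0)
        y = np.log(theta) if use_log else theta
        try:
            W = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(Xc * W[:, None], y * W, rcond=None)
            adjusted = y - (Xc[:, 1:] @ beta[1:])
        except np.linalg.LinAlgError:
            warnings.warn(f"regression adjustment failed for {par}; plain rejection")
            adjusted = y
        post = np.exp(adjusted) if use_log else adjusted
        lo, med, hi = _weighted_quantiles(post, w, [0.025, 0.5, 0.975])
        prior = sims[par].to_numpy().astype(float)
        q25, q75 = np.quantile(prior, [0.25, 0.75])
        overlap = float(np.average((post >= q25) & (post <= q75), weights=w))
        rows[par] = {
            "median": med,
            "lo95": lo,
            "hi95": hi,
            "prior_overlap": overlap,
        }
        differentiated[par] = bool(overlap < 0.25 or overlap > 0.75)
    est = pd.DataFrame(rows).T
    return ParameterPosterior(est, differentiated, tolerance)


def _weighted_quantiles(x, w, qs):
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) - 0.5 * ws
    cum /= ws.sum()
    return [float(np.interp(q, cum, xs)) for q in qs]


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

def gens_to_years(t_generations: float, generation_time: float = 2.3) -> float:
    """Convert generations before present to years at the given generation
    time (default 2.3 yr/generation)."""
    if t_generations < 0:
        raise ValueError("time must be non-negative")
    return t_generations * generation_time


def migrants_per_generation(ne: float, m: float) -> float:
    """Number of migrants per generation, Ne * m."""
    if ne <= 0 or m < 0:
        raise ValueError("Ne must be positive and m non-negative")
    return ne * m


def scaled_migration(n0: float, m: float) -> float:
    """Population-scaled migration rate M = 4 * N0 * m."""
    if n0 <= 0 or m < 0:
        raise ValueError("N0 must be positive and m non-negative")
    return 4.0 * n0 * m
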