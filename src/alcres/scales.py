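"""Scale scoring and one-factor measurement models for parenting quality.

Scoring rules:

* bonding: 12 items (1-4), summed — range 12-48;
* closeness: 2 items on different response formats, each standardized
  against the analysis sample then averaged;
* communication: 3 yes/no items, coded 0/1 and summed — range 0-3;
* involvement: 6 yes/no items, coded 0/1 and summed — range 0-6;
* monitoring: 3 items (1 = always ... 4 = rarely), reverse coded
  (1<->4, 2<->3) and summed — range 3-12.

``fit_one_factor_cfa`` fits the four parenting indicators to a single
factor (variance fixed to 1) by ML/FIML, reports chi-square against the
saturated model, CFI against the independence baseline, SRMR, and
regression-method factor scores (conditional-normal on the available
indicators when some are missing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from alcres.sem import (
    SemError,
    _LOG2PI,
    fit_sem,
    saturated_mvn_fit,
)

__all__ = ["ScaleScore", "CfaFit", "score_scale", "score_subjects", "fit_one_factor_cfa"]


class ScaleError(ValueError):
    pass


@dataclass
class ScaleScore:
    subject_id: str
    scale_name: str
    value: float
    n_items_answered: int


_SCALE_RULES = {
    # name -> (n_items, min, max, reverse)
    "bonding": (12, 1, 4, False),
    "communication": (3, 0, 1, False),
    "involvement": (6, 0, 1, False),
    "monitoring": (3, 1, 4, True),
}


def score_scale(items, scale_name: str, *, subject_id: str = "", closeness_stats=None) -> ScaleScore:
    """Apply a single scale's scoring rule to one response vector.

    ``closeness_stats`` must be ``((mean1, sd1), (mean2, sd2))`` for the
    closeness scale (the analysis sample's item means/SDs used for
    standardization); other scales ignore it.  All-missing responses yield
    a missing (NaN) score; out-of-range responses raise with the item index.
    """
    arr = np.asarray(items, dtype=float)
    if scale_name == "closeness":
        if arr.shape != (2,):
            raise ScaleError("closeness expects exactly 2 items")
        if closeness_stats is None:
            raise ScaleError("closeness scoring requires the sample item means/SDs")
        formats = ((1, 4), (1, 3))
        z = []
        for k, (x, (lo, hi), (mean, sd)) in enumerate(zip(arr, formats, closeness_stats)):
            if np.isnan(x):
                continue
            if not lo <= x <= hi:
                raise ScaleError(f"closeness item {k + 1} response {x} outside [{lo}, {hi}]")
            z.append((x - mean) / sd if sd > 0 else 0.0)
        if not z:
            return ScaleScore(subject_id, scale_name, float("nan"), 0)
        return ScaleScore(subject_id, scale_name, float(np.mean(z)), len(z))

    if scale_name not in _SCALE_RULES:
        raise ScaleError(f"unknown scale {scale_name!r}")
    n_items, lo, hi, reverse = _SCALE_RULES[scale_name]
    if arr.shape != (n_items,):
        raise ScaleError(f"{scale_name} expects {n_items} items, got {arr.shape}")
    answered = ~np.isnan(arr)
    for k in np.flatnonzero(answered):
        if not lo <= arr[k] <= hi:
            raise ScaleError(
                f"{scale_name} item {k + 1} response {arr[k]} outside [{lo}, {hi}]"
            )
    if not answered.any():
        return ScaleScore(subject_id, scale_name, float("nan"), 0)
    if not answered.all():
        # scale scores are sums; any unanswered item leaves the sum undefined
        return ScaleScore(subject_id, scale_name, float("nan"), int(answered.sum()))
    vals = (lo + hi) - arr if reverse else arr
    return ScaleScore(subject_id, scale_name, float(vals.sum()), n_items)


def score_subjects(subjects_df: pd.DataFrame) -> pd.DataFrame:
    """Score every parenting/monitoring scale for all subjects.

    Returns one row per subject with columns ``{f,m}_{bonding,closeness,
    communication,involvement}`` and ``monitoring``.  Closeness item
    standardization uses the full analysis sample's means/SDs.
    """
    out = pd.DataFrame({"subject_id": subjects_df["subject_id"]})
    spec = {
        "bonding": ("bond", 12),
        "closeness": ("close", 2),
        "communication": ("comm", 3),
        "involvement": ("inv", 6),
    }
    for parent in ("f", "m"):
        close_cols = [f"{parent}_close_{j}" for j in (1, 2)]
        stats_close = tuple(
            (float(subjects_df[c].mean()), float(subjects_df[c].std(ddof=0)))
            for c in close_cols
        )
        for scale, (stub, count) in spec.items():
            cols = [f"{parent}_{stub}_{j + 1}" for j in range(count)]
            vals = subjects_df[cols].to_numpy(dtype=float)
            scores = [
                score_scale(
                    row, scale, subject_id=str(sid), closeness_stats=stats_close
                ).value
                for sid, row in zip(subjects_df["subject_id"], vals)
            ]
            out[f"{parent}_{scale}"] = scores
    mon_cols = [f"mon_{j + 1}" for j in range(3)]
    out["monitoring"] = [
        score_scale(row, "monitoring", subject_id=str(sid)).value
        for sid, row in zip(
            subjects_df["subject_id"], subjects_df[mon_cols].to_numpy(dtype=float)
        )
    ]
    return out


@dataclass
class CfaFit:
    loadings: np.ndarray
    residual_variances: np.ndarray
    chi_square: float
    df: int
    cfi: float
    srmr: float
    factor_scores: np.ndarray
    indicator_names: list[str]
    loglik: float
    n: int
    heywood: bool
    intercepts: np.ndarray


def fit_one_factor_cfa(indicator_matrix: pd.DataFrame, *, starts: int = 3, seed: int = 0) -> CfaFit:
    """One-factor ML/FIML CFA of the given indicator columns.

    Factor variance is fixed to 1 so the reported loadings are on the
    factor's standardized scale.  Negative residual variances (Heywood
    cases) are flagged, not truncated.
    """
    names = list(indicator_matrix.columns)
    if len(names) < 4:
        raise SemError("need at least 4 indicators")
    text = "f =~ " + " + ".join(names)
    fit = fit_sem(text, indicator_matrix, compute_se=False, starts=starts, seed=seed)

    lam = np.array([fit.param(f"f=~{v}") for v in names])
    psi = np.array([fit.param(f"{v}~~{v}") for v in names])
    mu = np.array([fit.param(f"{v}~1") for v in names])

    arr = indicator_matrix.to_numpy(dtype=float)
    keep = ~np.all(np.isnan(arr), axis=1)
    ll_sat, mu_sat, sigma_sat = saturated_mvn_fit(arr)
    chi_square = max(2.0 * (ll_sat - fit.loglik), 0.0)

    # independence baseline: per-variable univariate normal ML (exact under
    # ignorable missingness since variables are independent in the baseline)
    ll_base = 0.0
    p = len(names)
    for j in range(p):
        col = arr[:, j]
        col = col[~np.isnan(col)]
        v = col.var()
        ll_base += -0.5 * len(col) * (_LOG2PI + np.log(v) + 1.0)
    chi_base = max(2.0 * (ll_sat - ll_base), 0.0)
    df_base = p * (p - 1) // 2

    num = max(chi_square - fit.df, 0.0)
    den = max(chi_base - df_base, num)
    cfi = 1.0 - num / den if den > 0 else 1.0

    sigma_model = np.outer(lam, lam) + np.diag(psi)
    sd = np.sqrt(np.diag(sigma_sat))
    resid = (sigma_sat - sigma_model) / np.outer(sd, sd)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    # regression-method factor scores; conditional normal on observed subset
    scores = np.full(arr.shape[0], np.nan)
    for i in range(arr.shape[0]):
        obs = np.flatnonzero(~np.isnan(arr[i]))
        if len(obs) == 0:
            continue
        sig_o = sigma_model[np.ix_(obs, obs)]
        scores[i] = float(lam[obs] @ np.linalg.solve(sig_o, arr[i, obs] - mu[obs]))

    return CfaFit(
        loadings=lam,
        residual_variances=psi,
        chi_square=float(chi_square),
        df=int(fit.df),
        cfi=float(cfi),
        srmr=srmr,
        factor_scores=scores,
        indicator_names=names,
        loglik=fit.loglik,
        n=int(keep.sum()),
        heywood=fit.heywood,
        intercepts=mu,
    )


def relationship_quality_scores(scores_df: pd.DataFrame, *, seed: int = 0) -> tuple[pd.DataFrame, dict[str, CfaFit]]:
    """Fit the father- and mother-quality CFAs; return factor scores + fits."""
    out = scores_df[["subject_id"]].copy()
    fits: dict[str, CfaFit] = {}
    for parent, label in (("f", "father"), ("m", "mother")):
        cols = [f"{parent}_{s}" for s in ("bonding", "closeness", "communication", "involvement")]
        fit = fit_one_factor_cfa(scores_df[cols], seed=seed)
        fits[label] = fit
        out[f"{label}_quality"] = fit.factor_scores
    return out, fits
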