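"""Univariable family-clustered association models.

Deviance-residual outcomes use a random-intercept (family) linear model by
ML; the binary AUD-resistance outcome uses a family random-intercept
probit whose likelihood is integrated by Gauss-Hermite quadrature.  Each
predictor enters a separate model; continuous predictors and outcomes are
standardized so coefficients are on a per-SD scale, while binary
predictors stay on the 0/1 scale (outcome standardized), matching the
latent-probit z-scale interpretation of the published tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats

logger = logging.getLogger(__name__)

PREDICTORS = (
    "father_quality",
    "mother_quality",
    "monitoring",
    "peer_drinking",
    "partner_drinking",
    "social_competence",
)

PROBIT_COVARIATES = ("baseline_age", "sex", "has_mother_data", "has_father_data")


class AssocError(ValueError):
    pass


@dataclass
class AssocResult:
    predictor_name: str
    outcome: str
    beta_std: float
    se: float
    ci95: tuple[float, float]
    n_used: int
    model: str  # "family_lm" | "family_probit"
    family_variance: float
    note: str = ""

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return not (lo <= 0.0 <= hi)


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[~np.isnan(x)])
    return len(vals) <= 2 and set(np.round(vals, 12)).issubset({0.0, 1.0})


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise AssocError("zero variance; cannot standardize")
    return (x - x.mean()) / sd


def fit_family_lm(
    outcome: np.ndarray,
    predictor: np.ndarray,
    family_ids: np.ndarray,
    *,
    predictor_name: str = "x",
    outcome_name: str = "y",
) -> AssocResult:
    """Random-intercept linear model (ML) of a standardized outcome.

    Binary predictors stay on the 0/1 scale; continuous predictors are
    standardized.  If the between-family variance collapses to (near) zero
    the estimates coincide with OLS, which is logged.
    """
    y = np.asarray(outcome, float)
    x = np.asarray(predictor, float)
    fam = np.asarray(family_ids)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x, fam = y[ok], x[ok], fam[ok]
    if len(np.unique(fam)) < 2:
        raise AssocError("need at least 2 families")
    if y.std() == 0:
        raise AssocError("outcome has zero variance")
    y = _standardize(y)
    binary = _is_binary(x)
    if not binary:
        x = _standardize(x)
    exog = sm.add_constant(x)

    note = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=fam)
        try:
            res = model.fit(reml=False, method="lbfgs")
        except Exception:
            res = model.fit(reml=False)
    fam_var = float(np.asarray(res.cov_re)[0, 0])
    beta = float(res.params[1])
    se = float(res.bse[1])
    if fam_var < 1e-8:
        ols = sm.OLS(y, exog).fit()
        beta, se = float(ols.params[1]), float(ols.bse[1])
        note = "between-family variance ~ 0; degenerated to OLS"
        logger.info("%s -> %s: %s", predictor_name, outcome_name, note)
    z = stats.norm.ppf(0.975)
    return AssocResult(
        predictor_name=predictor_name,
        outcome=outcome_name,
        beta_std=beta,
        se=se,
        ci95=(beta - z * se, beta + z * se),
        n_used=int(len(y)),
        model="family_lm",
        family_variance=fam_var,
        note=note,
    )


# ---------------------------------------------------------------------------
# random-intercept probit with Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

class RandomInterceptProbit:
    """ML probit with a family random intercept.

    Latent model: y* = X beta + sigma * u_family + e, u ~ N(0, 1),
    e ~ N(0, 1); the family likelihood integrates the shared u by
    Gauss-Hermite quadrature (``nodes`` points).  ``fix_sigma`` pins the
    random-effect SD (0 collapses to ordinary probit ML).
    """

    def __init__(self, y, X, family_ids, *, nodes: int = 15, fix_sigma: float | None = None):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        fam = pd.Series(np.asarray(family_ids))
        self.fam_codes = fam.astype("category").cat.codes.to_numpy()
        self.n_fam = int(self.fam_codes.max()) + 1
        self.nodes = nodes
        self.fix_sigma = fix_sigma
        if set(np.unique(self.y)) - {0.0, 1.0}:
            raise AssocError("outcome must be binary 0/1")
        if len(np.unique(self.y)) < 2:
            raise AssocError("outcome must have both classes")
        z, w = hermgauss(nodes)
        self.quad_z = z * np.sqrt(2.0)  # nodes on the N(0,1) scale
        self.quad_w = w / np.sqrt(np.pi)
        self.sign = 2.0 * self.y - 1.0

    def loglik(self, beta: np.ndarray, sigma: float) -> float:
        eta = self.X @ beta
        # (n_obs, nodes): per-observation log Phi at each quadrature point
        args = self.sign[:, None] * (eta[:, None] + sigma * self.quad_z[None, :])
        logphi = stats.norm.logcdf(args)
        fam_log = np.zeros((self.n_fam, self.nodes))
        np.add.at(fam_log, self.fam_codes, logphi)
        m = fam_log.max(axis=1, keepdims=True)
        lik = np.exp(fam_log - m) @ self.quad_w
        return float(np.sum(m[:, 0] + np.log(lik)))

    def _pack(self, params):
        if self.fix_sigma is not None:
            return params, self.fix_sigma
        return params[:-1], abs(params[-1])

    def fit(self, *, maxiter: int = 500):
        k = self.X.shape[1]
        # ordinary probit start
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start_beta = sm.Probit(self.y, self.X).fit(disp=0, maxiter=200).params
        x0 = np.asarray(start_beta, float)
        if self.fix_sigma is None:
            x0 = np.append(x0, 0.5)

        def nll(p):
            beta, sigma = self._pack(p)
            ll = self.loglik(beta, sigma)
            return -ll if np.isfinite(ll) else 1e12

        res = optimize.minimize(nll, x0, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-7})
        if not np.isfinite(res.fun):
            raise AssocError(f"random-intercept probit did not converge: {res.message}")
        beta, sigma = self._pack(res.x)
        H = _numeric_hessian(nll, res.x)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se_beta = se_all[:k]
        return {
            "beta": np.asarray(beta),
            "sigma": float(sigma),
            "se": se_beta,
            "loglik": -float(res.fun),
            "converged": bool(res.success or np.max(np.abs(res.jac)) < 1e-3),
            "message": str(res.message),
        }


def _numeric_hessian(f, x, h=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        hi = h * max(1.0, abs(x[i]))
        for j in range(i, k):
            hj = h * max(1.0, abs(x[j]))
            xpp = x.copy(); xpp[i] += hi; xpp[j] += hj
            xpm = x.copy(); xpm[i] += hi; xpm[j] -= hj
            xmp = x.copy(); xmp[i] -= hi; xmp[j] += hj
            xmm = x.copy(); xmm[i] -= hi; xmm[j] -= hj
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * hi * hj)
    return H


def fit_family_probit(
    outcome: np.ndarray,
    predictor: np.ndarray,
    covariates: pd.DataFrame | None,
    family_ids: np.ndarray,
    *,
    predictor_name: str = "x",
    outcome_name: str = "aud",
    nodes: int = 15,
    fix_sigma: float | None = None,
) -> AssocResult:
    """Family random-intercept probit of a binary outcome on one predictor.

    Coefficients are on the latent-probit z scale.  Complete separation on
    the predictor is detected and reported as an error naming it.
    """
    y = np.asarray(outcome, float)
    x = np.asarray(predictor, float)
    fam = np.asarray(family_ids)
    cov = covariates.to_numpy(dtype=float) if covariates is not None else np.empty((len(y), 0))
    ok = ~(np.isnan(y) | np.isnan(x) | np.isnan(cov).any(axis=1))
    y, x, fam, cov = y[ok], x[ok], fam[ok], cov[ok]
    if len(np.unique(y)) < 2:
        raise AssocError("outcome must have both classes")
    binary = _is_binary(x)
    if not binary:
        x = _standardize(x)
    # complete separation check on the predictor
    if x[y == 1].size and x[y == 0].size:
        if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
            raise AssocError(f"complete separation on predictor {predictor_name!r}")
    cols = [np.ones(len(y)), x]
    for j in range(cov.shape[1]):
        c = cov[:, j]
        if np.ptp(c) == 0:
            continue
        cols.append(_standardize(c) if not _is_binary(c) else c)
    X = np.column_stack(cols)
    model = RandomInterceptProbit(y, X, fam, nodes=nodes, fix_sigma=fix_sigma)
    out = model.fit()
    beta, se = float(out["beta"][1]), float(out["se"][1])
    z = stats.norm.ppf(0.975)
    return AssocResult(
        predictor_name=predictor_name,
        outcome=outcome_name,
        beta_std=beta,
        se=se,
        ci95=(beta - z * se, beta + z * se),
        n_used=int(len(y)),
        model="family_probit",
        family_variance=float(out["sigma"]) ** 2,
    )


# ---------------------------------------------------------------------------
# Table-2-shaped runner
# ---------------------------------------------------------------------------

def univariable_table(
    resistance_df: pd.DataFrame,
    predictors_df: pd.DataFrame,
    subjects_df: pd.DataFrame,
    *,
    nodes: int = 15,
) -> pd.DataFrame:
    """All predictor-by-outcome univariable models, one row each.

    ``predictors_df`` carries subject_id plus the six predictor columns;
    the AUD outcome model adds the demographic covariates and ancestry
    dummies from ``subjects_df``.
    """
    base = predictors_df.merge(
        subjects_df[
            ["subject_id", "family_id", "baseline_age", "sex", "ancestry_group",
             "has_mother_data", "has_father_data"]
        ],
        on="subject_id",
    )
    base["ancestry_aa"] = (base["ancestry_group"] == "AA").astype(float)
    rows = []
    for pheno in ("initiation", "hed", "aud"):
        res = resistance_df.loc[resistance_df["phenotype"] == pheno, ["subject_id", "value"]]
        merged = base.merge(res, on="subject_id")
        for pred in PREDICTORS:
            if pred not in merged.columns:
                continue
            try:
                if pheno == "aud":
                    covs = merged[list(PROBIT_COVARIATES) + ["ancestry_aa"]]
                    r = fit_family_probit(
                        merged["value"].to_numpy(),
                        merged[pred].to_numpy(),
                        covs,
                        merged["family_id"].to_numpy(),
                        predictor_name=pred,
                        outcome_name=pheno,
                        nodes=nodes,
                    )
                else:
                    r = fit_family_lm(
                        merged["value"].to_numpy(),
                        merged[pred].to_numpy(),
                        merged["family_id"].to_numpy(),
                        predictor_name=pred,
                        outcome_name=pheno,
                    )
            except AssocError as exc:
                logger.warning("skipping %s -> %s: %s", pred, pheno, exc)
                continue
            rows.append(
                {
                    "predictor": r.predictor_name,
                    "outcome": r.outcome,
                    "beta_std": r.beta_std,
                    "se": r.se,
                    "ci_low": r.ci95[0],
                    "ci_high": r.ci95[1],
                    "significant": r.significant,
                    "n_used": r.n_used,
                    "model": r.model,
                    "note": r.note,
                }
            )
    return pd.DataFrame(rows)
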