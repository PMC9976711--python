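"""Realized-resistance phenotypes from family-clustered survival models.

The initiation and heavy-episodic-drinking phenotypes are deviance
residuals from Cox proportional-hazards models with genetic-risk
predictors and demographic covariates, clustered by family either through
a shared gamma frailty (penalized partial likelihood, frailty variance by
profile likelihood) or through a cluster-robust sandwich variance.  The
AUD phenotype is a rule-based binary code.

Sign convention for deviance residuals: positive = onset sooner than
expected = lower resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

SIGN_CONVENTION = "positive = onset sooner than expected = lower resistance"

COX_COVARIATES = (
    "fhd", "prs_z", "baseline_age", "sex", "pc1", "pc2",
    "has_mother_data", "has_father_data",
)


class CoxError(ValueError):
    pass


class CoxConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[str] | None = None):
        super().__init__(message + ("\n" + "\n".join(trace) if trace else ""))
        self.trace = trace or []


@dataclass
class SurvivalRecord:
    subject_id: str
    family_id: int
    time: float
    event: int
    covariates: dict[str, float]

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise CoxError(f"time must be positive, got {self.time} for {self.subject_id}")
        if self.event not in (0, 1):
            raise CoxError(f"event must be 0/1, got {self.event}")


@dataclass
class CoxFit:
    """Fitted family-clustered Cox model with Breslow baseline hazard."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    baseline_times: np.ndarray       # distinct event times, ascending
    baseline_jumps: np.ndarray       # Breslow hazard increments at those times
    cluster_mode: str
    frailty_variance: float
    frailty_by_family: dict
    subject_ids: list[str]
    family_ids: np.ndarray
    times: np.ndarray
    events: np.ndarray
    eta0: np.ndarray                 # linear predictor excluding frailty
    martingale: np.ndarray
    deviance: np.ndarray
    dropped: list[str] = field(default_factory=list)
    n_events: int = 0
    tie_method: str = "breslow"

    @property
    def baseline_cumhaz(self) -> np.ndarray:
        return np.cumsum(self.baseline_jumps)

    def cumhaz_at(self, times: np.ndarray) -> np.ndarray:
        """Step-function Breslow cumulative hazard evaluated at ``times``."""
        idx = np.searchsorted(self.baseline_times, times, side="right")
        ch = np.concatenate([[0.0], self.baseline_cumhaz])
        return ch[idx]

    def hr_ci(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy import stats as _stats

        z = _stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "covariate": self.names,
                "beta": self.beta,
                "se": self.se,
                "hr": np.exp(self.beta),
                "hr_low": np.exp(self.beta - z * self.se),
                "hr_high": np.exp(self.beta + z * self.se),
            }
        )


@dataclass
class ResistanceScore:
    subject_id: str
    phenotype: str  # initiation | hed | aud
    value: float
    sign_convention: str = SIGN_CONVENTION


# ---------------------------------------------------------------------------
# partial likelihood machinery
# ---------------------------------------------------------------------------

class _CoxData:
    """Sorted arrays and tie bookkeeping for partial-likelihood evaluation."""

    def __init__(self, times, events, X, offset, groups):
        order = np.lexsort((1 - events, times))  # time asc, events before censored
        self.order = order
        self.t = np.asarray(times, float)[order]
        self.d = np.asarray(events, int)[order]
        self.X = np.asarray(X, float)[order]
        self.off = np.asarray(offset, float)[order]
        self.groups = np.asarray(groups)[order]
        self.n, self.p = self.X.shape
        ev = self.d == 1
        self.event_times, self.tie_index = np.unique(self.t[ev], return_inverse=True)
        self.d_k = np.bincount(self.tie_index, minlength=len(self.event_times))

    def loglik_grad_hess(self, beta, tie_method="breslow"):
        eta = self.X @ beta + self.off
        w = np.exp(eta)
        wx = self.X * w[:, None]
        # suffix sums: risk set at time t = all subjects with time >= t
        S0_all = np.cumsum(w[::-1])[::-1]
        S1_all = np.cumsum(wx[::-1], axis=0)[::-1]
        wxx = np.einsum("ij,ik->ijk", self.X, wx)
        S2_all = np.cumsum(wxx[::-1], axis=0)[::-1]
        # index of the first subject with time >= each event time
        first = np.searchsorted(self.t, self.event_times, side="left")
        S0 = S0_all[first]
        S1 = S1_all[first]
        S2 = S2_all[first]

        ev = self.d == 1
        ll = float(eta[ev].sum())
        grad = self.X[ev].sum(axis=0)
        hess = np.zeros((self.p, self.p))

        if tie_method == "breslow":
            ll -= float(self.d_k @ np.log(S0))
            xbar = S1 / S0[:, None]
            grad -= (self.d_k[:, None] * xbar).sum(axis=0)
            for k in range(len(self.event_times)):
                v = S2[k] / S0[k] - np.outer(xbar[k], xbar[k])
                hess -= self.d_k[k] * v
        elif tie_method == "efron":
            for k in range(len(self.event_times)):
                tied = ev & (self.t == self.event_times[k])
                dk = int(self.d_k[k])
                w_d = w[tied].sum()
                s1_d = wx[tied].sum(axis=0)
                s2_d = wxx[tied].sum(axis=0)
                for l in range(dk):
                    f = l / dk
                    s0 = S0[k] - f * w_d
                    s1 = S1[k] - f * s1_d
                    s2 = S2[k] - f * s2_d
                    ll -= math.log(s0)
                    xb = s1 / s0
                    grad -= xb
                    hess -= s2 / s0 - np.outer(xb, xb)
        else:
            raise CoxError(f"unknown tie method {tie_method!r}")
        return ll, grad, hess, w, S0

    def breslow_baseline(self, beta):
        """Distinct event times and Breslow hazard increments."""
        eta = self.X @ beta + self.off
        w = np.exp(eta)
        S0_all = np.cumsum(w[::-1])[::-1]
        first = np.searchsorted(self.t, self.event_times, side="left")
        jumps = self.d_k / S0_all[first]
        return self.event_times, jumps


def _newton(data: _CoxData, tie_method: str, beta0=None, tol=1e-10, max_iter=50):
    beta = np.zeros(data.p) if beta0 is None else np.array(beta0, float)
    trace = []
    ll_prev = -np.inf
    for it in range(max_iter):
        ll, grad, hess, _, _ = data.loglik_grad_hess(beta, tie_method)
        trace.append(f"iter {it}: loglik={ll:.10g} |grad|={np.max(np.abs(grad)):.3g}")
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError("singular information matrix", trace) from exc
        # step-halving on the partial likelihood
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_new = data.loglik_grad_hess(cand, tie_method)[0]
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            alpha /= 2.0
        beta = beta + alpha * step
        if np.max(np.abs(grad)) < tol * (1 + abs(ll)) or abs(ll - ll_prev) < tol * (1 + abs(ll)):
            ll_final, grad, hess, _, _ = data.loglik_grad_hess(beta, tie_method)
            return beta, ll_final, -hess, trace
        ll_prev = ll
    raise CoxConvergenceError("Newton iteration did not converge", trace)


def _score_residuals(data: _CoxData, beta: np.ndarray):
    """Per-subject score residuals (Breslow ties) in sorted order."""
    eta = data.X @ beta + data.off
    w = np.exp(eta)
    S0_all = np.cumsum(w[::-1])[::-1]
    S1_all = np.cumsum((data.X * w[:, None])[::-1], axis=0)[::-1]
    first = np.searchsorted(data.t, data.event_times, side="left")
    S0 = S0_all[first]
    xbar = S1_all[first] / S0[:, None]
    haz = data.d_k / S0                       # Breslow jumps
    cumhaz = np.concatenate([[0.0], np.cumsum(haz)])
    cumB = np.concatenate([[np.zeros(data.p)], np.cumsum(haz[:, None] * xbar, axis=0)])
    pos = np.searchsorted(data.event_times, data.t, side="right")
    Lam = cumhaz[pos]
    B = cumB[pos]
    U = -w[:, None] * (data.X * Lam[:, None] - B)
    ev = data.d == 1
    ev_k = np.searchsorted(data.event_times, data.t[ev])
    U[ev] += data.X[ev] - xbar[ev_k]
    return U


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _records_to_arrays(records: Sequence[SurvivalRecord]):
    names = list(records[0].covariates.keys())
    for r in records:
        if list(r.covariates.keys()) != names:
            raise CoxError("all records must share the same covariate names")
    X = np.array([[r.covariates[k] for k in names] for r in records], float)
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    fams = np.array([r.family_id for r in records])
    ids = [r.subject_id for r in records]
    return names, X, times, events, fams, ids


def fit_clustered_cox(
    records: Sequence[SurvivalRecord],
    cluster_mode: str = "gamma_frailty",
    *,
    tie_method: str = "breslow",
    theta_max: float = 4.0,
) -> CoxFit:
    """Cox PH fit with family clustering by gamma frailty or robust variance.

    ``gamma_frailty`` maximizes the observable marginal likelihood over the
    frailty variance (profile over theta, EM in the inner loop);
    ``robust`` fits the ordinary partial likelihood and reports the
    family-clustered sandwich variance.  Covariates constant over the
    sample are non-identifiable and dropped (recorded in ``dropped``).
    """
    if cluster_mode not in ("gamma_frailty", "robust"):
        raise CoxError(f"unknown cluster_mode {cluster_mode!r}")
    if not records:
        raise CoxError("no records")
    names, X, times, events, fams, ids = _records_to_arrays(records)
    if not np.isfinite(X).all():
        raise CoxError("covariates contain non-finite values")
    if events.sum() == 0:
        raise CoxError("no events")

    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    names_kept = [names[j] for j in keep]
    X = X[:, keep]
    if X.shape[1] and np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise CoxError("covariate matrix is rank deficient after dropping constants")

    data = _CoxData(times, events, X, np.zeros(len(times)), fams)
    beta, ll, info, trace = _newton(data, tie_method)

    if cluster_mode == "robust":
        U = _score_residuals(data, beta)
        fam_sorted = data.groups
        df_u = pd.DataFrame(U)
        df_u["fam"] = fam_sorted
        Uc = df_u.groupby("fam").sum().to_numpy()
        inv_info = np.linalg.inv(info)
        V = inv_info @ (Uc.T @ Uc) @ inv_info
        se = np.sqrt(np.diag(V))
        frailty_var = 0.0
        frailty = {}
        eta0 = X @ beta
        bt, bj = data.breslow_baseline(beta)
        fit_beta, fit_ll = beta, ll
    else:
        fit_beta, fit_ll, info, frailty_var, frailty, bt, bj = _gamma_frailty_fit(
            data, tie_method, theta_max
        )
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        eta0 = X @ fit_beta

    fit = CoxFit(
        names=names_kept,
        beta=fit_beta,
        se=se,
        loglik=float(fit_ll),
        baseline_times=bt,
        baseline_jumps=bj,
        cluster_mode=cluster_mode,
        frailty_variance=float(frailty_var),
        frailty_by_family=frailty,
        subject_ids=ids,
        family_ids=fams,
        times=times,
        events=events,
        eta0=eta0,
        martingale=np.empty(0),
        deviance=np.empty(0),
        dropped=dropped,
        n_events=int(events.sum()),
        tie_method=tie_method,
    )
    mart, dev = residuals(fit)
    fit.martingale, fit.deviance = mart, dev
    return fit


def _gamma_frailty_fit(data: _CoxData, tie_method: str, theta_max: float):
    """Profile the gamma-frailty marginal likelihood over theta."""
    fams = data.groups
    fam_names = pd.unique(fams)
    fam_pos = pd.Series(np.arange(len(fam_names)), index=fam_names)
    fam_idx = fam_pos[fams].to_numpy()
    D_f = np.bincount(fam_idx, weights=data.d, minlength=len(fam_names))

    def inner(theta):
        """EM at fixed theta; returns marginal loglik and fitted pieces."""
        logw = np.zeros(len(fam_names))
        beta = np.zeros(data.p)
        ll_m = -np.inf
        for _ in range(200):
            offset = logw[fam_idx]
            d2 = _CoxData(data.t, data.d, data.X, offset, fams)
            # note: d2 re-sorts an already sorted copy; order is stable
            beta, _, info, _ = _newton(d2, tie_method, beta0=beta)
            bt, bj = d2.breslow_baseline(beta)
            eta0 = data.X @ beta
            idx = np.searchsorted(bt, data.t, side="right")
            ch = np.concatenate([[0.0], np.cumsum(bj)])
            lam_i = ch[idx] * np.exp(eta0)
            A_f = np.bincount(fam_idx, weights=lam_i, minlength=len(fam_names))
            if theta > 0:
                new_w = (1.0 / theta + D_f) / (1.0 / theta + A_f)
                logw_new = np.log(new_w)
            else:
                logw_new = np.zeros(len(fam_names))
            ll_new = _marginal_loglik(data, fam_idx, D_f, A_f, beta, bt, bj, theta)
            if abs(ll_new - ll_m) < 1e-8 * (1 + abs(ll_new)):
                logw = logw_new
                ll_m = ll_new
                break
            logw = logw_new
            ll_m = ll_new
        return ll_m, beta, info, logw, bt, bj

    ll0 = inner(0.0)[0]

    def neg_profile(log_theta):
        return -inner(math.exp(log_theta))[0]

    res = optimize.minimize_scalar(
        neg_profile, bounds=(math.log(1e-3), math.log(theta_max)), method="bounded",
        options={"xatol": 1e-3},
    )
    if -res.fun > ll0 + 1e-8:
        theta = math.exp(res.x)
    else:
        theta = 0.0
    ll_m, beta, info, logw, bt, bj = inner(theta)
    frailty = {fam: float(np.exp(logw[fam_pos[fam]])) for fam in fam_names}
    return beta, ll_m, info, theta, frailty, bt, bj


def _marginal_loglik(data, fam_idx, D_f, A_f, beta, bt, bj, theta):
    """Observable marginal likelihood of the shared gamma-frailty model."""
    eta0 = data.X @ beta
    ev = data.d == 1
    k_idx = np.searchsorted(bt, data.t[ev])
    ll = float(eta0[ev].sum() + np.log(bj[k_idx]).sum())
    if theta <= 0:
        return ll - float(A_f.sum())
    inv = 1.0 / theta
    ll += float(
        np.sum(
            D_f * math.log(theta)
            + special.gammaln(inv + D_f)
            - special.gammaln(inv)
            - (inv + D_f) * np.log1p(theta * A_f)
        )
    )
    return ll


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------

def residuals(fit: CoxFit, frailty: str = "conditional") -> tuple[np.ndarray, np.ndarray]:
    """Martingale and deviance residuals, in the original record order.

    M_i = delta_i - Lambda0(t_i) * exp(eta_i); with ``frailty='conditional'``
    (default) eta includes the family's estimated log-frailty.
    D_i = sign(M_i) * sqrt(-2 * [M_i + delta_i * log(delta_i - M_i)]),
    with the delta_i = 0 convention that the log term vanishes.
    """
    if frailty not in ("conditional", "marginal"):
        raise CoxError(f"unknown residual frailty mode {frailty!r}")
    eta = fit.eta0.copy()
    if fit.cluster_mode == "gamma_frailty" and frailty == "conditional":
        eta += np.log(np.array([fit.frailty_by_family[f] for f in fit.family_ids]))
    lam = fit.cumhaz_at(fit.times) * np.exp(eta)
    delta = fit.events.astype(float)
    mart = delta - lam
    if np.any(mart >= delta + 1e-12):
        raise CoxError("martingale residual >= event indicator; invalid cumulative hazard")
    inner = delta - mart  # = Lambda * exp(eta) >= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(delta > 0, np.log(np.where(inner > 0, inner, 1.0)), 0.0)
    arg = -2.0 * (mart + delta * logterm)
    dev = np.sign(mart) * np.sqrt(np.maximum(arg, 0.0))
    if not np.isfinite(dev).all():
        raise CoxError("non-finite deviance residuals")
    return mart, dev


# ---------------------------------------------------------------------------
# AUD coding and subsamples
# ---------------------------------------------------------------------------

def code_aud_resistance(subjects_df: pd.DataFrame) -> pd.Series:
    """Rule-based AUD-resistance code per subject.

    Affected (diagnosis at age >= 15) -> 0; drinkers assessed through age
    23 and never diagnosed -> 1; non-drinkers, and drinkers not assessed
    through age 23 without a diagnosis -> missing.
    """
    diagnosed = subjects_df["aud_diagnosed"].to_numpy(dtype=float) == 1
    drinker = subjects_df["drinker"].to_numpy(dtype=float) == 1
    last_age = subjects_df["last_assessment_age"].to_numpy(dtype=float)
    code = np.full(len(subjects_df), np.nan)
    code[diagnosed & (last_age >= 15.0)] = 0.0
    code[~diagnosed & drinker & (last_age >= 23.0)] = 1.0
    return pd.Series(code, index=subjects_df.index, name="aud_resistance")


def build_analysis_subsamples(
    subjects_df: pd.DataFrame, genrisk_df: pd.DataFrame
) -> dict[str, pd.Series]:
    """Boolean masks for the three analysis subsamples.

    initiation: no alcohol initiation at baseline; hed: no heavy episodic
    drinking at baseline; aud: high genetic risk with a non-missing
    AUD-resistance code.
    """
    merged = subjects_df.merge(genrisk_df, on="subject_id", how="left")
    aud_code = code_aud_resistance(subjects_df)
    masks = {
        "initiation": pd.Series(
            subjects_df["initiated_at_baseline"].to_numpy(dtype=float) != 1,
            index=subjects_df.index,
        ),
        "hed": pd.Series(
            subjects_df["hed_at_baseline"].to_numpy(dtype=float) != 1,
            index=subjects_df.index,
        ),
        "aud": pd.Series(
            (merged["high_risk"].to_numpy(dtype=bool)) & aud_code.notna().to_numpy(),
            index=subjects_df.index,
        ),
    }
    return masks


# ---------------------------------------------------------------------------
# pipeline entry: derive all three phenotypes
# ---------------------------------------------------------------------------

def _survival_records(df: pd.DataFrame, time_col: str, event_col: str) -> list[SurvivalRecord]:
    recs = []
    for row in df.itertuples():
        recs.append(
            SurvivalRecord(
                subject_id=str(row.subject_id),
                family_id=row.family_id,
                time=float(getattr(row, time_col)),
                event=int(getattr(row, event_col)),
                covariates={k: float(getattr(row, k)) for k in COX_COVARIATES},
            )
        )
    return recs


def resistance_phenotypes(
    subjects_df: pd.DataFrame,
    genrisk_df: pd.DataFrame,
    *,
    cluster_mode: str = "gamma_frailty",
    tie_method: str = "breslow",
    residual_frailty: str = "conditional",
    stratify_by_ancestry: bool = True,
) -> tuple[pd.DataFrame, dict[str, CoxFit]]:
    """Derive the three resistance phenotypes.

    Survival models are fitted separately within each ancestry group (the
    phenotype is defined within stratum) and the residuals pooled; the AUD
    code is rule-based.  Returns a long frame (subject_id, phenotype,
    value, sign_convention) and the fitted Cox models keyed by
    ``"{phenotype}:{ancestry}"``.
    """
    df = subjects_df.merge(genrisk_df, on="subject_id", how="left")
    masks = build_analysis_subsamples(subjects_df, genrisk_df)
    rows: list[dict] = []
    fits: dict[str, CoxFit] = {}

    for pheno, time_col, event_col in (
        ("initiation", "onset_age_initiation", "event_initiation"),
        ("hed", "onset_age_hed", "event_hed"),
    ):
        sub = df.loc[masks[pheno].to_numpy()]
        strata = sub["ancestry_group"].unique() if stratify_by_ancestry else ["all"]
        for anc in strata:
            block = sub if anc == "all" else sub.loc[sub["ancestry_group"] == anc]
            if block.empty:
                continue
            recs = _survival_records(block, time_col, event_col)
            fit = fit_clustered_cox(recs, cluster_mode, tie_method=tie_method)
            fits[f"{pheno}:{anc}"] = fit
            _, dev = residuals(fit, residual_frailty)
            for sid, d in zip(fit.subject_ids, dev):
                rows.append({"subject_id": sid, "phenotype": pheno, "value": float(d)})

    aud_code = code_aud_resistance(subjects_df)
    aud_mask = masks["aud"]
    for sid, ok, val in zip(subjects_df["subject_id"], aud_mask, aud_code):
        if ok and not np.isnan(val):
            rows.append({"subject_id": str(sid), "phenotype": "aud", "value": float(val)})

    out = pd.DataFrame(rows, columns=["subject_id", "phenotype", "value"])
    out["sign_convention"] = SIGN_CONVENTION
    return out, fits
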