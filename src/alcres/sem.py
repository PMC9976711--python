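"""Gaussian structural equation models with full-information ML.

A small lavaan-style engine sufficient for the path models used here:

* measurement lines ``f =~ a + b + c + d`` (latent ``f`` with indicators),
* regressions ``y ~ x1 + x2``,
* covariances/variances ``a ~~ b``.

Identification fixes every exogenous latent variance to 1 (standardized
loadings are reported directly); all observed variables carry free
intercepts.  Two estimation routes are kept deliberately distinct:

* complete data: the mean structure is saturated, so intercepts are
  profiled out exactly and the ML discrepancy is minimized on the sample
  covariance alone (with analytic gradients);
* missing data: case-wise (pattern-grouped) FIML over means and
  covariances, also with analytic gradients.

Multi-group fits support equality constraints on labelled parameters, and
``lrt`` performs the likelihood-ratio test between nested fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SemSpec",
    "SemFit",
    "SemError",
    "SemConvergenceError",
    "parse_model",
    "fiml_loglik",
    "fit_sem",
    "fit_multigroup",
    "lrt",
    "saturated_mvn_fit",
    "structural_path_labels",
]


class SemError(ValueError):
    pass


class SemConvergenceError(RuntimeError):
    """Raised when no optimizer start converges; carries the trace."""

    def __init__(self, message: str, trace: list[str] | None = None):
        super().__init__(message + ("\n" + "\n".join(trace) if trace else ""))
        self.trace = trace or []


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class SemSpec:
    """Parsed model: measurement, regressions, declared (co)variances."""

    measurement: dict[str, list[str]] = field(default_factory=dict)
    regressions: dict[str, list[str]] = field(default_factory=dict)
    covariances: list[tuple[str, str]] = field(default_factory=list)

    @property
    def latents(self) -> list[str]:
        return list(self.measurement)

    def observed_vars(self) -> list[str]:
        """All non-latent variables, in first-mention order."""
        seen: dict[str, None] = {}
        for inds in self.measurement.values():
            for v in inds:
                seen.setdefault(v)
        for lhs, rhs in self.regressions.items():
            seen.setdefault(lhs)
            for v in rhs:
                seen.setdefault(v)
        for a, b in self.covariances:
            seen.setdefault(a)
            seen.setdefault(b)
        return [v for v in seen if v not in self.measurement]


def parse_model(text: str) -> SemSpec:
    """Parse one-equation-per-line model syntax (``=~``, ``~~``, ``~``)."""
    spec = SemSpec()
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for segment in line.split(";"):
            segment = segment.strip()
            if not segment:
                continue
            if "=~" in segment:
                lhs, rhs = segment.split("=~")
                name = lhs.strip()
                inds = [v.strip() for v in rhs.split("+")]
                if not name or any(not v for v in inds):
                    raise SemError(f"malformed measurement line: {segment!r}")
                spec.measurement.setdefault(name, []).extend(inds)
            elif "~~" in segment:
                lhs, rhs = segment.split("~~")
                a, b = lhs.strip(), rhs.strip()
                if not a or not b:
                    raise SemError(f"malformed covariance line: {segment!r}")
                spec.covariances.append((a, b))
            elif "~" in segment:
                lhs, rhs = segment.split("~", 1)
                name = lhs.strip()
                preds = [v.strip() for v in rhs.split("+")]
                if not name or any(not v for v in preds):
                    raise SemError(f"malformed regression line: {segment!r}")
                spec.regressions.setdefault(name, []).extend(preds)
            else:
                raise SemError(f"unrecognized model line: {segment!r}")
    if not (spec.measurement or spec.regressions or spec.covariances):
        raise SemError("empty model")
    return spec


def structural_path_labels(spec: SemSpec) -> list[str]:
    """Labels of all structural regression coefficients (``y~x``)."""
    return [f"{lhs}~{rhs}" for lhs, preds in spec.regressions.items() for rhs in preds]


# ---------------------------------------------------------------------------
# parameter table and implied moments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Param:
    label: str
    matrix: str  # 'A' (directed paths), 'P' (variances/covariances), 'M' (means)
    i: int
    j: int


class _Model:
    """Internal: parameter bookkeeping and implied-moment computation."""

    def __init__(self, spec: SemSpec, observed: Sequence[str]):
        self.spec = spec
        self.latents = spec.latents
        self.observed = list(observed)
        missing = set(spec.observed_vars()) - set(self.observed)
        if missing:
            raise SemError(f"model variables absent from data: {sorted(missing)}")
        self.names = self.latents + self.observed
        self.index = {v: i for i, v in enumerate(self.names)}
        self.m = len(self.names)
        self.obs_idx = np.array([self.index[v] for v in self.observed])

        endogenous: set[str] = set()
        params: list[_Param] = []
        fixed_P: list[tuple[int, int, float]] = []

        for lat, inds in spec.measurement.items():
            for ind in inds:
                if ind in spec.measurement:
                    raise SemError("latent indicators of latents are not supported")
                params.append(_Param(f"{lat}=~{ind}", "A", self.index[ind], self.index[lat]))
                endogenous.add(ind)
        for lhs, preds in spec.regressions.items():
            for rhs in preds:
                params.append(_Param(f"{lhs}~{rhs}", "A", self.index[lhs], self.index[rhs]))
            endogenous.add(lhs)

        for v in self.names:
            i = self.index[v]
            if v in spec.measurement and v not in endogenous:
                fixed_P.append((i, i, 1.0))  # exogenous latent: variance fixed to 1
            else:
                params.append(_Param(f"{v}~~{v}", "P", i, i))
        for a, b in spec.covariances:
            if a == b:
                continue  # variance already free or fixed
            ia, ib = self.index[a], self.index[b]
            params.append(_Param(f"{a}~~{b}", "P", max(ia, ib), min(ia, ib)))
        for v in self.observed:
            params.append(_Param(f"{v}~1", "M", self.index[v], -1))

        self.params = params
        self.fixed_P = fixed_P
        self.labels = [p.label for p in params]
        if len(set(self.labels)) != len(self.labels):
            raise SemError("duplicate parameter labels in model specification")
        self.cov_mask = np.array([p.matrix != "M" for p in params])
        self.n_cov_params = int(self.cov_mask.sum())

    # -- assembly ---------------------------------------------------------
    def matrices(self, theta: np.ndarray):
        m = self.m
        A = np.zeros((m, m))
        P = np.zeros((m, m))
        Mu = np.zeros(m)
        for i, j, v in self.fixed_P:
            P[i, j] = P[j, i] = v
        for val, p in zip(theta, self.params):
            if p.matrix == "A":
                A[p.i, p.j] = val
            elif p.matrix == "P":
                P[p.i, p.j] = val
                P[p.j, p.i] = val
            else:
                Mu[p.i] = val
        return A, P, Mu

    def implied(self, theta: np.ndarray):
        """Return (Sigma_obs, mu_obs, B, P, Sigma_all)."""
        A, P, Mu = self.matrices(theta)
        try:
            B = np.linalg.inv(np.eye(self.m) - A)
        except np.linalg.LinAlgError as exc:  # cyclic/degenerate path matrix
            raise SemError("I - A is singular; model is non-recursive") from exc
        sigma_all = B @ P @ B.T
        mu_all = B @ Mu
        o = self.obs_idx
        return sigma_all[np.ix_(o, o)], mu_all[o], B, P, sigma_all

    def start_values(self, data_mean: np.ndarray, data_var: np.ndarray) -> np.ndarray:
        sd = np.sqrt(np.maximum(data_var, 1e-6))
        col = {v: k for k, v in enumerate(self.observed)}
        theta = np.zeros(len(self.params))
        for k, p in enumerate(self.params):
            name_i = self.names[p.i]
            if p.matrix == "A":
                src = self.names[p.j]
                if src in self.spec.measurement:  # loading
                    theta[k] = 0.7 * sd[col[name_i]] if name_i in col else 0.7
                else:
                    theta[k] = 0.0
            elif p.matrix == "P":
                if p.i == p.j:
                    theta[k] = 0.5 * data_var[col[name_i]] if name_i in col else 0.5
                else:
                    theta[k] = 0.0
            else:
                theta[k] = data_mean[col[name_i]]
        return theta


# ---------------------------------------------------------------------------
# data summaries
# ---------------------------------------------------------------------------

class _PatternData:
    """Per-missingness-pattern sufficient statistics for FIML."""

    def __init__(self, data: np.ndarray):
        if data.ndim != 2:
            raise SemError("data must be a 2-D array")
        keep = ~np.all(np.isnan(data), axis=1)
        if not keep.all():
            data = data[keep]
        if data.shape[0] == 0:
            raise SemError("no usable cases (every row fully missing)")
        self.n, self.p = data.shape
        obs = ~np.isnan(data)
        self.patterns = []
        # group rows by missingness pattern
        codes = obs @ (1 << np.arange(self.p, dtype=np.int64))
        for code in np.unique(codes):
            rows = data[codes == code]
            cols = np.flatnonzero(obs[np.argmax(codes == code)])
            sub = rows[:, cols]
            ng = sub.shape[0]
            mean = sub.mean(axis=0)
            centered = sub - mean
            scatter = centered.T @ centered / ng
            self.patterns.append((cols, ng, mean, scatter))
        self.complete = len(self.patterns) == 1 and len(self.patterns[0][0]) == self.p


_LOG2PI = math.log(2.0 * math.pi)


def _fiml_value_grad(model: _Model, pat: _PatternData, theta: np.ndarray, need_grad: bool):
    """-2 log-likelihood (FIML) and its gradient at theta."""
    try:
        sigma, mu, B, P, _ = model.implied(theta)
    except SemError:
        return np.inf, None
    m = model.m
    f = 0.0
    W = np.zeros((len(model.observed),) * 2)  # accumulated dF/dSigma (observed block)
    gmu = np.zeros(len(model.observed))
    for cols, ng, mean, scatter in pat.patterns:
        sig = sigma[np.ix_(cols, cols)]
        try:
            chol = np.linalg.cholesky(sig)
        except np.linalg.LinAlgError:
            return np.inf, None
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        inv = np.linalg.inv(sig)
        d = mean - mu[cols]
        quad = scatter + np.outer(d, d)
        f += ng * (len(cols) * _LOG2PI + logdet + float(np.sum(inv * quad)))
        if need_grad:
            w = ng * (inv - inv @ quad @ inv)
            W[np.ix_(cols, cols)] += w
            gmu[cols] += -2.0 * ng * (inv @ d)
    if not need_grad:
        return f, None
    grad = _assemble_grad(model, theta, B, P, W, gmu)
    return f, grad


def _ml_value_grad(model: _Model, S: np.ndarray, n: int, theta_cov: np.ndarray, need_grad: bool):
    """n * ML discrepancy (means profiled) and gradient, complete data."""
    theta = _expand_cov(model, theta_cov)
    try:
        sigma, _, B, P, _ = model.implied(theta)
    except SemError:
        return np.inf, None
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf, None
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    inv = np.linalg.inv(sigma)
    f = n * (logdet + float(np.sum(inv * S)))
    if not need_grad:
        return f, None
    W = n * (inv - inv @ S @ inv)
    grad_full = _assemble_grad(model, theta, B, P, W, None)
    return f, grad_full[model.cov_mask]


def _assemble_grad(model, theta, B, P, W, gmu):
    """Map dF/dSigma_obs (and dF/dmu_obs) to the free-parameter gradient."""
    m = model.m
    o = model.obs_idx
    Wt = np.zeros((m, m))
    Wt[np.ix_(o, o)] = W
    BtWB = B.T @ Wt @ B                    # dF/dP (before symmetry doubling)
    C = (B @ P @ B.T) @ Wt @ B             # dF/dA_ij = 2 * C[j, i]
    if gmu is not None:
        gmu_full = np.zeros(m)
        gmu_full[o] = gmu
        Btg = B.T @ gmu_full               # dF/dMu_j
        Bm0 = B @ model.matrices(theta)[2]
    grad = np.zeros(len(model.params))
    for k, p in enumerate(model.params):
        if p.matrix == "A":
            g = 2.0 * C[p.j, p.i]
            if gmu is not None:
                g += Btg[p.i] * Bm0[p.j]
            grad[k] = g
        elif p.matrix == "P":
            grad[k] = BtWB[p.i, p.j] if p.i == p.j else 2.0 * BtWB[p.i, p.j]
        else:
            grad[k] = Btg[p.i] if gmu is not None else 0.0
    return grad


def _expand_cov(model: _Model, theta_cov: np.ndarray) -> np.ndarray:
    theta = np.zeros(len(model.params))
    theta[model.cov_mask] = theta_cov
    return theta


def _obs_scale(model: _Model, arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column scale factors (SDs) and per-parameter back-transform factors.

    Fitting runs on ``x / s`` (scaled, not centered), which keeps the
    optimization well conditioned when indicators live on very different
    ranges.  Under pure scaling every parameter maps back linearly:
    paths/loadings by s_i/s_j, (co)variances by s_i*s_j, intercepts by s_i
    (latent scales are 1).
    """
    s_obs = np.array([np.sqrt(np.nanvar(arr[:, j])) for j in range(arr.shape[1])])
    s_obs[~np.isfinite(s_obs) | (s_obs <= 0)] = 1.0
    s_all = np.ones(model.m)
    s_all[model.obs_idx] = s_obs
    factors = np.empty(len(model.params))
    for k, p in enumerate(model.params):
        if p.matrix == "A":
            factors[k] = s_all[p.i] / s_all[p.j]
        elif p.matrix == "P":
            factors[k] = s_all[p.i] * s_all[p.j]
        else:
            factors[k] = s_all[p.i]
    return s_obs, factors


def _scale_loglik_correction(pat: _PatternData, log_s: np.ndarray) -> float:
    """loglik(raw) = loglik(scaled) - sum over cases of log s_j (observed)."""
    return float(sum(ng * log_s[cols].sum() for cols, ng, _, _ in pat.patterns))


def _solve_means(model: _Model, theta: np.ndarray, xbar: np.ndarray) -> np.ndarray:
    """Intercepts reproducing the sample means exactly (saturated mean part)."""
    A, _, _ = model.matrices(theta)
    B = np.linalg.inv(np.eye(model.m) - A)
    o = model.obs_idx
    Boo = B[np.ix_(o, o)]
    m0_obs = np.linalg.solve(Boo, xbar)
    out = theta.copy()
    for k, p in enumerate(model.params):
        if p.matrix == "M":
            out[k] = m0_obs[model.observed.index(model.names[p.i])]
    return out


# ---------------------------------------------------------------------------
# saturated model (for chi-square); EM under missing data
# ---------------------------------------------------------------------------

def saturated_mvn_fit(
    data: np.ndarray, tol: float = 1e-9, max_iter: int = 1000
) -> tuple[float, np.ndarray, np.ndarray]:
    """ML fit of an unstructured Gaussian (mu, Sigma) allowing missing values.

    Complete data is closed-form; otherwise a standard EM with conditional
    expectations per missingness pattern.  Returns (loglik, mu, Sigma).
    """
    data = np.asarray(data, dtype=float)
    keep = ~np.all(np.isnan(data), axis=1)
    data = data[keep]
    n, p = data.shape
    if n == 0:
        raise SemError("no usable cases")
    if not np.isnan(data).any():
        mu = data.mean(axis=0)
        centered = data - mu
        sigma = centered.T @ centered / n
        chol = np.linalg.cholesky(sigma)
        loglik = -0.5 * n * (p * _LOG2PI + 2 * np.log(np.diag(chol)).sum() + p)
        return loglik, mu, sigma

    pat = _PatternData(data)
    # initialize from available-case moments, regularized to PD
    mu = np.array([np.nanmean(data[:, j]) for j in range(p)])
    sigma = np.diag([max(np.nanvar(data[:, j]), 1e-3) for j in range(p)])
    last = -np.inf
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        loglik = 0.0
        for cols, ng, mean, scatter in pat.patterns:
            miss = np.setdiff1d(np.arange(p), cols)
            soo = sigma[np.ix_(cols, cols)]
            inv = np.linalg.inv(soo)
            d = mean - mu[cols]
            quad = scatter + np.outer(d, d)
            chol = np.linalg.cholesky(soo)
            loglik += -0.5 * ng * (
                len(cols) * _LOG2PI + 2 * np.log(np.diag(chol)).sum() + float(np.sum(inv * quad))
            )
            # E-step moments: reconstruct expected sums for this pattern
            reg = sigma[np.ix_(miss, cols)] @ inv if len(miss) else None
            ex = np.zeros((p, 1))
            ex[cols, 0] = mean
            exx = np.zeros((p, p))
            exx[np.ix_(cols, cols)] = scatter + np.outer(mean, mean)
            if len(miss):
                mmean = mu[miss] + reg @ d
                ex[miss, 0] = mmean
                cond_cov = sigma[np.ix_(miss, miss)] - reg @ sigma[np.ix_(cols, miss)]
                exm_o = np.outer(mmean, mean) + reg @ scatter
                exx[np.ix_(miss, cols)] = exm_o
                exx[np.ix_(cols, miss)] = exm_o.T
                exx[np.ix_(miss, miss)] = (
                    cond_cov + reg @ scatter @ reg.T + np.outer(mmean, mmean)
                )
            sum_x += ng * ex[:, 0]
            sum_xx += ng * exx
        mu = sum_x / n
        sigma = sum_xx / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2.0
        if abs(loglik - last) < tol * (1 + abs(loglik)):
            break
        last = loglik
    return loglik, mu, sigma


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class SemFit:
    """Fitted model: likelihood, estimates, SEs, standardized solution."""

    labels: list[str]
    estimates: np.ndarray
    se: np.ndarray | None
    loglik: float
    n: int
    df: int
    chi_square: float | None
    converged: bool
    n_free: int
    standardized: pd.DataFrame | None = None
    groups: dict[str, "SemFit"] | None = None
    n_per_group: dict[str, int] | None = None
    constraint_labels: list[str] = field(default_factory=list)
    heywood: bool = False
    condition_flag: bool = False
    trace: list[str] = field(default_factory=list)

    def param(self, label: str) -> float:
        return float(self.estimates[self.labels.index(label)])

    def param_se(self, label: str) -> float:
        if self.se is None:
            raise SemError("standard errors were not computed for this fit")
        return float(self.se[self.labels.index(label)])

    def ci95(self, label: str) -> tuple[float, float]:
        est, se = self.param(label), self.param_se(label)
        return est - 1.959963984540054 * se, est + 1.959963984540054 * se

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"label": self.labels, "estimate": self.estimates})
        if self.se is not None:
            out["se"] = self.se
            out["ci_low"] = out["estimate"] - 1.959963984540054 * out["se"]
            out["ci_high"] = out["estimate"] + 1.959963984540054 * out["se"]
        return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _prepare(spec_or_text, data: pd.DataFrame):
    spec = parse_model(spec_or_text) if isinstance(spec_or_text, str) else spec_or_text
    observed = [v for v in spec.observed_vars()]
    missing_cols = [v for v in observed if v not in data.columns]
    if missing_cols:
        raise SemError(f"data is missing model columns: {missing_cols}")
    arr = data[observed].to_numpy(dtype=float)
    model = _Model(spec, observed)
    return spec, model, arr


def fiml_loglik(spec_or_text, data: pd.DataFrame, params) -> float:
    """Case-wise Gaussian log-likelihood of ``data`` at the given parameters.

    ``params`` is either a full parameter vector (model ordering) or a
    mapping from parameter label to value covering every free parameter.
    """
    _, model, arr = _prepare(spec_or_text, data)
    if isinstance(params, Mapping):
        unknown = set(params) - set(model.labels)
        if unknown:
            raise SemError(f"unknown parameters: {sorted(unknown)}")
        missing = set(model.labels) - set(params)
        if missing:
            raise SemError(f"parameters not supplied: {sorted(missing)}")
        theta = np.array([params[lab] for lab in model.labels], dtype=float)
    else:
        theta = np.asarray(params, dtype=float)
        if theta.shape != (len(model.labels),):
            raise SemError(
                f"expected {len(model.labels)} parameters, got shape {theta.shape}"
            )
    pat = _PatternData(arr)
    f, _ = _fiml_value_grad(model, pat, theta, need_grad=False)
    if not np.isfinite(f):
        raise SemError("model-implied covariance is not positive definite at params")
    return -0.5 * f


def _optimize(fun, x0, trace, label, maxiter=2000):
    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 5 * maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    trace.append(f"{label}: success={res.success} f={res.fun:.8g} nit={res.nit} {res.message}")
    return res


def _multi_start(fun, x0, starts, seed, trace):
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(starts, 1)):
        x = x0 if s == 0 else x0 * (1 + 0.1 * rng.standard_normal(x0.shape)) + 0.01 * rng.standard_normal(x0.shape)
        res = _optimize(fun, x, trace, f"start {s}")
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-10):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise SemConvergenceError("no optimizer start converged", trace)
    return best


def _hessian_from_grad(grad_fun, theta, h=1e-5):
    k = len(theta)
    H = np.zeros((k, k))
    for j in range(k):
        step = h * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += step
        tm = theta.copy(); tm[j] -= step
        H[:, j] = (grad_fun(tp) - grad_fun(tm)) / (2 * step)
    return (H + H.T) / 2.0


def _standardized_table(model: _Model, theta: np.ndarray, cov_theta: np.ndarray | None):
    """Standardized loadings/paths/correlations with delta-method SEs."""

    def std_vector(t: np.ndarray) -> np.ndarray:
        _, _, B, P, sigma_all = model.implied(t)
        sd = np.sqrt(np.maximum(np.diag(sigma_all), 1e-12))
        out = []
        for p in model.params:
            v = t[model.labels.index(p.label)]
            if p.matrix == "A":
                out.append(v * sd[p.j] / sd[p.i])
            elif p.matrix == "P" and p.i != p.j:
                out.append(sigma_all[p.i, p.j] / (sd[p.i] * sd[p.j]))
            elif p.matrix == "P":
                out.append(1.0)  # placeholder for variances
            else:
                out.append(v)
        return np.asarray(out)

    std = std_vector(theta)
    se_std = np.full(len(std), np.nan)
    if cov_theta is not None:
        J = np.zeros((len(std), len(theta)))
        for j in range(len(theta)):
            h = 1e-6 * max(1.0, abs(theta[j]))
            tp = theta.copy(); tp[j] += h
            tm = theta.copy(); tm[j] -= h
            J[:, j] = (std_vector(tp) - std_vector(tm)) / (2 * h)
        var = np.einsum("ij,jk,ik->i", J, cov_theta, J)
        se_std = np.sqrt(np.maximum(var, 0.0))
    kinds = []
    for p in model.params:
        if p.matrix == "A":
            kinds.append("loading" if model.names[p.j] in model.spec.measurement else "path")
        elif p.matrix == "P":
            kinds.append("variance" if p.i == p.j else "correlation")
        else:
            kinds.append("intercept")
    tab = pd.DataFrame(
        {"label": model.labels, "kind": kinds, "std_estimate": std, "std_se": se_std}
    )
    tab["std_ci_low"] = tab["std_estimate"] - 1.959963984540054 * tab["std_se"]
    tab["std_ci_high"] = tab["std_estimate"] + 1.959963984540054 * tab["std_se"]
    return tab


def fit_sem(
    spec_or_text,
    data: pd.DataFrame,
    *,
    force_fiml: bool = False,
    compute_se: bool = True,
    compute_chi_square: bool = True,
    starts: int = 3,
    seed: int = 0,
    start_values: Mapping[str, float] | None = None,
) -> SemFit:
    """Fit the model by ML (complete data) or FIML (with missing values).

    With complete data and ``force_fiml=False`` the intercepts are profiled
    out and estimation runs on the sample covariance; both routes maximize
    the same likelihood.
    """
    spec, model, arr = _prepare(spec_or_text, data)
    arr = arr[~np.all(np.isnan(arr), axis=1)]  # fully-missing cases carry no information
    s_obs, factors = _obs_scale(model, arr)
    arr = arr / s_obs  # fit on the scaled data; back-transform at the end
    pat = _PatternData(arr)
    n = pat.n
    p = len(model.observed)
    ll_shift = _scale_loglik_correction(pat, np.log(s_obs))
    trace: list[str] = []

    col_mean = np.array([np.nanmean(arr[:, j]) for j in range(p)])
    col_var = np.array([max(np.nanvar(arr[:, j]), 1e-8) for j in range(p)])
    theta0 = model.start_values(col_mean, col_var)
    if start_values:
        for lab, v in start_values.items():
            if lab not in model.labels:
                raise SemError(f"unknown start value parameter {lab!r}")
            theta0[model.labels.index(lab)] = v / factors[model.labels.index(lab)]

    use_ml = pat.complete and not force_fiml
    if use_ml:
        xbar = arr.mean(axis=0)
        centered = arr - xbar
        S = centered.T @ centered / n
        x0 = theta0[model.cov_mask]

        def fun(tc):
            f, g = _ml_value_grad(model, S, n, tc, need_grad=True)
            if not np.isfinite(f):
                return 1e12, np.zeros_like(tc)
            return f, g

        best = _multi_start(fun, x0, starts, seed, trace)
        theta = _solve_means(model, _expand_cov(model, best.x), xbar)
        chol = np.linalg.cholesky(S)
        ll_sat = -0.5 * n * (p * _LOG2PI + 2 * np.log(np.diag(chol)).sum() + p)
        # the profiled mean part contributes exactly 0 at mu = xbar
        loglik = -0.5 * (best.fun + n * p * _LOG2PI)
        hess_grad = lambda tc: _ml_value_grad(model, S, n, tc, need_grad=True)[1]
        hess_theta = best.x
        free_mask = model.cov_mask
    else:
        def fun(t):
            f, g = _fiml_value_grad(model, pat, t, need_grad=True)
            if not np.isfinite(f):
                return 1e12, np.zeros_like(t)
            return f, g

        best = _multi_start(fun, theta0, starts, seed, trace)
        theta = best.x
        loglik = -0.5 * best.fun
        if compute_chi_square:
            ll_sat = saturated_mvn_fit(arr)[0]
        hess_grad = lambda t: _fiml_value_grad(model, pat, t, need_grad=True)[1]
        hess_theta = theta
        free_mask = np.ones(len(model.params), dtype=bool)

    df = p * (p + 3) // 2 - len(model.params)
    # chi-square compares two likelihoods on the same (scaled) data; the
    # scaling correction cancels
    chi_square = max(2.0 * (ll_sat - loglik), 0.0) if compute_chi_square else None
    loglik -= ll_shift

    se = None
    cov_theta_full = None
    condition_flag = False
    if compute_se:
        H = _hessian_from_grad(hess_grad, hess_theta) / 2.0  # hessian of -loglik
        cond = np.linalg.cond(H)
        condition_flag = not np.isfinite(cond) or cond > 1e10
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            condition_flag = True
        se_free = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se = np.full(len(model.params), np.nan)
        se[free_mask] = se_free
        cov_theta_full = np.zeros((len(model.params),) * 2)
        cov_theta_full[np.ix_(free_mask, free_mask)] = cov

    # back-transform to the raw data scale
    theta = theta * factors
    if se is not None:
        se = se * factors
        cov_theta_full = cov_theta_full * np.outer(factors, factors)

    heywood = any(
        theta[k] < 0 for k, prm in enumerate(model.params)
        if prm.matrix == "P" and prm.i == prm.j
    )
    standardized = _standardized_table(model, theta, cov_theta_full)

    return SemFit(
        labels=list(model.labels),
        estimates=theta,
        se=se,
        loglik=float(loglik),
        n=n,
        df=df,
        chi_square=chi_square,
        converged=bool(best.success or np.isfinite(best.fun)),
        n_free=len(model.params),
        standardized=standardized,
        heywood=heywood,
        condition_flag=condition_flag,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# multi-group estimation with equality constraints
# ---------------------------------------------------------------------------

def fit_multigroup(
    spec_or_text,
    data: pd.DataFrame,
    group_labels: Sequence,
    constraints: Iterable[str] = (),
    *,
    compute_se: bool = False,
    starts: int = 3,
    seed: int = 0,
) -> tuple[SemFit, SemFit]:
    """Fit the model freely per group and with tagged parameters equated.

    Returns ``(fit_free, fit_constrained)``.  The free model is the sum of
    independent per-group fits; the constrained model shares every
    parameter whose label appears in ``constraints`` across groups, leaving
    all other parameters group-specific.
    """
    spec = parse_model(spec_or_text) if isinstance(spec_or_text, str) else spec_or_text
    groups = pd.Series(list(group_labels))
    if groups.shape[0] != data.shape[0]:
        raise SemError("group_labels length must match data rows")
    names = [g for g in pd.unique(groups.dropna())]
    if len(names) < 2:
        raise SemError("multi-group fitting needs at least 2 groups")
    constraints = list(constraints)

    subframes = {g: data.loc[(groups == g).to_numpy()] for g in names}
    free_fits: dict[str, SemFit] = {}
    for g in names:
        free_fits[g] = fit_sem(
            spec, subframes[g], compute_se=compute_se, compute_chi_square=False,
            starts=starts, seed=seed,
        )
    labels0 = free_fits[names[0]].labels
    unknown = set(constraints) - set(labels0)
    if unknown:
        raise SemError(f"constraints reference unknown parameters: {sorted(unknown)}")

    fit_free = SemFit(
        labels=labels0,
        estimates=free_fits[names[0]].estimates,
        se=free_fits[names[0]].se,
        loglik=float(sum(f.loglik for f in free_fits.values())),
        n=int(sum(f.n for f in free_fits.values())),
        df=int(sum(f.df for f in free_fits.values())),
        chi_square=None,
        converged=all(f.converged for f in free_fits.values()),
        n_free=int(sum(f.n_free for f in free_fits.values())),
        groups={g: f for g, f in free_fits.items()},
        n_per_group={g: f.n for g, f in free_fits.items()},
    )

    if not constraints:
        import copy

        fit_con = copy.copy(fit_free)
        fit_con.constraint_labels = []
        return fit_free, fit_con

    fit_con = _fit_constrained(
        spec, subframes, names, constraints, free_fits, starts=starts, seed=seed,
        compute_se=compute_se,
    )
    if fit_con.loglik > fit_free.loglik:
        # a free per-group fit stalled short of its optimum: polish each group
        # from the constrained solution (always feasible for the free model)
        improved = False
        for g in names:
            warm = dict(zip(fit_con.groups[g].labels, fit_con.groups[g].estimates))
            refit = fit_sem(
                spec, subframes[g], compute_se=compute_se, compute_chi_square=False,
                starts=1, seed=seed, start_values=warm,
            )
            if refit.loglik > free_fits[g].loglik:
                free_fits[g] = refit
                improved = True
        if improved:
            fit_free.groups = dict(free_fits)
            fit_free.loglik = float(sum(f.loglik for f in free_fits.values()))
            fit_free.estimates = free_fits[names[0]].estimates
            fit_free.se = free_fits[names[0]].se
    return fit_free, fit_con


def _fit_constrained(spec, subframes, names, constraints, free_fits, *, starts, seed, compute_se):
    models = {}
    arrs = {}
    for g in names:
        _, model, arr = _prepare(spec, subframes[g])
        models[g] = model
        arrs[g] = arr[~np.all(np.isnan(arr), axis=1)]
    # pooled scale so that equality constraints mean the same thing in the
    # scaled and raw parameterizations
    pooled = np.vstack([arrs[g] for g in names])
    s_obs, factors = _obs_scale(models[names[0]], pooled)
    pats = {}
    ll_shift = 0.0
    for g in names:
        pats[g] = _PatternData(arrs[g] / s_obs)
        ll_shift += _scale_loglik_correction(pats[g], np.log(s_obs))
    labels = models[names[0]].labels
    shared_idx = {lab: k for k, lab in enumerate(constraints)}
    n_shared = len(constraints)
    # joint parameter vector: [shared | group-specific for each group]
    spec_labels = [lab for lab in labels if lab not in shared_idx]
    offsets = {}
    pos = n_shared
    for g in names:
        offsets[g] = pos
        pos += len(spec_labels)
    total = pos

    lab_pos = {lab: i for i, lab in enumerate(labels)}
    spec_pos = [lab_pos[lab] for lab in spec_labels]
    shared_pos = [lab_pos[lab] for lab in constraints]

    def group_theta(x, g):
        theta = np.empty(len(labels))
        theta[shared_pos] = x[:n_shared]
        theta[spec_pos] = x[offsets[g]: offsets[g] + len(spec_labels)]
        return theta

    def fun(x):
        f_total = 0.0
        grad = np.zeros(total)
        for g in names:
            f, gr = _fiml_value_grad(models[g], pats[g], group_theta(x, g), need_grad=True)
            if not np.isfinite(f):
                return 1e12, np.zeros(total)
            f_total += f
            grad[:n_shared] += gr[shared_pos]
            grad[offsets[g]: offsets[g] + len(spec_labels)] += gr[spec_pos]
        return f_total, grad

    # warm start from the free solutions: average for shared parameters
    x0 = np.zeros(total)
    for k, lab in enumerate(constraints):
        x0[k] = float(np.mean([free_fits[g].param(lab) for g in names])) / factors[lab_pos[lab]]
    for g in names:
        x0[offsets[g]: offsets[g] + len(spec_labels)] = (
            free_fits[g].estimates[spec_pos] / factors[spec_pos]
        )

    trace: list[str] = []
    best = _multi_start(fun, x0, starts, seed, trace)
    loglik = -0.5 * best.fun - ll_shift

    group_fits = {}
    se_by_group = {g: None for g in names}
    if compute_se:
        grad_only = lambda x: fun(x)[1]
        H = _hessian_from_grad(grad_only, best.x) / 2.0
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        se_x = np.sqrt(np.maximum(np.diag(cov), 0.0))
        for g in names:
            se_g = np.empty(len(labels))
            se_g[shared_pos] = se_x[:n_shared]
            se_g[spec_pos] = se_x[offsets[g]: offsets[g] + len(spec_labels)]
            se_by_group[g] = se_g * factors

    for g in names:
        theta_g = group_theta(best.x, g) * factors
        group_fits[g] = SemFit(
            labels=list(labels),
            estimates=theta_g,
            se=se_by_group[g],
            loglik=float("nan"),
            n=pats[g].n,
            df=0,
            chi_square=None,
            converged=True,
            n_free=len(labels),
            standardized=_standardized_table(models[g], theta_g, None),
        )

    return SemFit(
        labels=list(labels),
        estimates=group_theta(best.x, names[0]) * factors,
        se=se_by_group[names[0]],
        loglik=float(loglik),
        n=int(sum(p.n for p in pats.values())),
        df=0,
        chi_square=None,
        converged=bool(np.isfinite(best.fun)),
        n_free=total,
        groups=group_fits,
        n_per_group={g: pats[g].n for g in names},
        constraint_labels=list(constraints),
        trace=trace,
    )


@dataclass
class LrtResult:
    stat: float
    df: int
    p: float


def lrt(fit_free: SemFit, fit_constrained: SemFit, slack: float = 1e-6) -> LrtResult:
    """Likelihood-ratio test of the constrained model against its parent.

    ``df`` equals the number of independent equality constraints: for each
    constrained label, (number of groups - 1).
    """
    n_groups = len(fit_free.groups) if fit_free.groups else 1
    df = len(fit_constrained.constraint_labels) * (n_groups - 1)
    stat = 2.0 * (fit_free.loglik - fit_constrained.loglik)
    if stat < -slack * max(1.0, abs(fit_free.loglik)):
        raise SemError(
            f"constrained log-likelihood exceeds the free one (stat={stat:.3g}); "
            "a fit failed to converge"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LrtResult(stat=float(stat), df=int(df), p=p if df > 0 else 1.0)
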