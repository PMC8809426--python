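"""Poisson mixed model of daily detection counts.

The model is a Poisson GLMM with independent Gaussian random intercepts
(site / season / year) estimated by maximizing the Laplace-approximated
marginal likelihood:

    log L(beta, sigma) ~= l(beta, u_hat) - u_hat' D^-1 u_hat / 2
                          - log det(D) / 2 - log det(H) / 2

where u_hat is the conditional mode of the random effects (found by a
damped Newton iteration; the penalized Poisson log-likelihood is concave,
so the inner problem is well behaved), D = diag of per-group variances and
H = Z'WZ + D^-1 is the penalized Hessian at the mode.  The outer
optimization runs L-BFGS-B over (beta, log sigma).  With no random
intercepts the model degenerates to a plain Poisson GLM fit by Newton
scoring.

Fixed-effect covariates use z-standardization for continuous terms
(scaling stored on the ModelSpec for back-transformation) and either
treatment (0/1) or sum (+1/-1) coding for binary factors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "ModelSpec",
    "GlmmFit",
    "FitError",
    "fit_poisson_glmm",
    "backward_select",
    "compare_aic",
    "type3_anova",
    "diagnostics",
    "percent_change_per_day",
    "parse_formula_terms",
    "season_of",
]

#: term name -> data column for continuous (scaled) and factor variables
CONTINUOUS_VARS = {"deploy": "days_since_deploy", "lure": "days_since_lure"}
FACTOR_VARS = {"acd": "has_acd", "scrape": "is_scrape"}

_MAX_ETA = 30.0  # exp overflow guard


class FitError(RuntimeError):
    """Model could not be fit (rank deficiency, divergence, degenerate data)."""


def season_of(when) -> str:
    """Meteorological quarter of a date: DJF / MAM / JJA / SON."""
    month = when.month
    return {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
            6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}[month]


@dataclass
class ModelSpec:
    fixed_terms: list[str] = field(default_factory=list)
    random_intercepts: list[str] = field(default_factory=list)
    coding: str = "treatment"  # "treatment" (0/1) or "sum" (+1/-1) for binary factors
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coding not in ("treatment", "sum"):
            raise ValueError(f"unknown coding {self.coding!r}")
        for g in self.random_intercepts:
            if g not in ("site", "season", "year"):
                raise ValueError(f"unknown random-intercept grouping {g!r}")

    def drop_term(self, term: str) -> "ModelSpec":
        return replace(self, fixed_terms=[t for t in self.fixed_terms if t != term])


def parse_formula_terms(rhs: str) -> list[str]:
    """Expand a right-hand-side formula like ``deploy*acd + lure`` into terms.

    ``a*b`` produces all mains and interactions; ``a:b`` only the interaction.
    Term order: mains first, then interactions by order.
    """
    from itertools import combinations

    terms: list[str] = []
    for token in rhs.split("+"):
        token = token.strip()
        if not token:
            continue
        if "*" in token:
            parts = [p.strip() for p in token.split("*")]
            for size in range(1, len(parts) + 1):
                for combo in combinations(parts, size):
                    term = ":".join(combo)
                    if term not in terms:
                        terms.append(term)
        elif token not in terms:
            terms.append(token)
    mains = [t for t in terms if ":" not in t]
    inters = sorted((t for t in terms if ":" in t), key=lambda t: t.count(":"))
    return mains + inters


def _component_column(data: pd.DataFrame, name: str, spec: ModelSpec) -> np.ndarray:
    if name in CONTINUOUS_VARS:
        col = data[CONTINUOUS_VARS[name]].to_numpy(dtype=float)
        if name not in spec.scaling:
            sd = float(col.std(ddof=0))
            if sd == 0:
                raise FitError(f"covariate {name} is constant; cannot standardize")
            spec.scaling[name] = (float(col.mean()), sd)
        mean, sd = spec.scaling[name]
        return (col - mean) / sd
    if name in FACTOR_VARS:
        flag = data[FACTOR_VARS[name]].to_numpy(dtype=bool)
        if spec.coding == "sum":
            return np.where(flag, 1.0, -1.0)
        return flag.astype(float)
    if name in data.columns:
        return data[name].to_numpy(dtype=float)
    raise FitError(f"unknown model term component {name!r}")


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix with intercept; raises on rank deficiency."""
    columns = [np.ones(len(data))]
    names = ["(Intercept)"]
    for term in spec.fixed_terms:
        parts = term.split(":")
        col = np.ones(len(data))
        for part in parts:
            col = col * _component_column(data, part, spec)
        columns.append(col)
        names.append(term)
    x = np.column_stack(columns)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        aliased = [names[j] for j in range(x.shape[1]) if abs(r[j, j]) < 1e-8]
        raise FitError(f"design matrix rank deficient; aliased columns: {aliased}")
    return x, names


_GROUP_COLUMNS = {"site": "site_id", "season": "season", "year": "year"}


def _group_codes(data: pd.DataFrame, spec: ModelSpec) -> tuple[list[np.ndarray], list[int], list[list]]:
    codes_list, sizes, levels_list = [], [], []
    for g in spec.random_intercepts:
        codes, levels = pd.factorize(data[_GROUP_COLUMNS[g]], sort=True)
        codes_list.append(codes.astype(np.int64))
        sizes.append(len(levels))
        levels_list.append(list(levels))
    return codes_list, sizes, levels_list


@dataclass
class GlmmFit:
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    re_names: list[str]
    re_sd: np.ndarray
    re_modes: dict[str, dict]
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    fitted: np.ndarray
    converged: bool
    message: str
    spec: ModelSpec
    data_fingerprint: str

    def coef_table(self) -> pd.DataFrame:
        z = self.beta / self.se
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


def _fingerprint(data: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(str(sorted(data.columns)).encode())
    h.update(str(len(data)).encode())
    h.update(pd.util.hash_pandas_object(data.reset_index(drop=True), index=False).values.tobytes())
    return h.hexdigest()[:16]


def _poisson_ll(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.exp(np.clip(eta, -_MAX_ETA, _MAX_ETA))
    return float(np.sum(y * eta - mu - gammaln(y + 1)))


def _fit_glm(y: np.ndarray, x: np.ndarray, names: list[str]) -> tuple[np.ndarray, np.ndarray, float]:
    """Plain Poisson GLM by Newton scoring; returns (beta, cov, loglik)."""
    beta = np.zeros(x.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    ll_old = -np.inf
    for _ in range(100):
        eta = np.clip(x @ beta, -_MAX_ETA, _MAX_ETA)
        mu = np.exp(eta)
        grad = x.T @ (y - mu)
        hess = (x * mu[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix in GLM fit: {exc}") from exc
        # damped Newton
        for _ in range(30):
            cand = beta + step
            ll = _poisson_ll(y, x @ cand)
            if np.isfinite(ll) and ll >= ll_old - 1e-10:
                break
            step = step / 2.0
        beta = cand
        if abs(ll - ll_old) < 1e-10 * (abs(ll) + 1.0):
            break
        ll_old = ll
    eta = np.clip(x @ beta, -_MAX_ETA, _MAX_ETA)
    mu = np.exp(eta)
    cov = np.linalg.inv((x * mu[:, None]).T @ x)
    return beta, cov, _poisson_ll(y, eta)


class _LaplaceWork:
    """Inner-mode state shared across outer optimizer evaluations."""

    def __init__(self, y, x, codes_list, sizes):
        self.y = y
        self.x = x
        self.codes = codes_list
        self.sizes = sizes
        self.q = int(sum(sizes))
        self.offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1]
        self.u = np.zeros(self.q)

    def eta(self, beta, u):
        eta = self.x @ beta
        for j, codes in enumerate(self.codes):
            eta = eta + u[self.offsets[j] + codes]
        return eta

    def _grad_u(self, resid, u, inv_var):
        parts = []
        for j, codes in enumerate(self.codes):
            uj = u[self.offsets[j]: self.offsets[j] + self.sizes[j]]
            parts.append(np.bincount(codes, weights=resid, minlength=self.sizes[j]) - uj * inv_var[j])
        return np.concatenate(parts)

    def hessian(self, w, inv_var):
        """Penalized Hessian H = Z'WZ + D^-1 assembled from group sums."""
        h = np.zeros((self.q, self.q))
        for j, codes_j in enumerate(self.codes):
            oj, qj = self.offsets[j], self.sizes[j]
            diag = np.bincount(codes_j, weights=w, minlength=qj)
            h[oj: oj + qj, oj: oj + qj] += np.diag(diag)
            h[np.arange(oj, oj + qj), np.arange(oj, oj + qj)] += inv_var[j]
            for k in range(j + 1, len(self.codes)):
                codes_k, ok, qk = self.codes[k], self.offsets[k], self.sizes[k]
                cross = np.bincount(
                    codes_j * qk + codes_k, weights=w, minlength=qj * qk
                ).reshape(qj, qk)
                h[oj: oj + qj, ok: ok + qk] = cross
                h[ok: ok + qk, oj: oj + qj] = cross.T
        return h

    def penalized_ll(self, beta, u, inv_var):
        ll = _poisson_ll(self.y, self.eta(beta, u))
        for j in range(len(self.codes)):
            uj = u[self.offsets[j]: self.offsets[j] + self.sizes[j]]
            ll -= 0.5 * inv_var[j] * float(uj @ uj)
        return ll

    def solve_mode(self, beta, inv_var, tol=1e-10, max_iter=50):
        """Damped Newton for the conditional mode; warm-started across calls."""
        u = self.u.copy()
        pll = self.penalized_ll(beta, u, inv_var)
        for _ in range(max_iter):
            eta = np.clip(self.eta(beta, u), -_MAX_ETA, _MAX_ETA)
            mu = np.exp(eta)
            grad = self._grad_u(self.y - mu, u, inv_var)
            if np.max(np.abs(grad)) < 1e-9 * (1.0 + abs(pll)):
                break
            h = self.hessian(mu, inv_var)
            try:
                step = np.linalg.solve(h, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(h, grad, rcond=None)[0]
            improved = False
            for _ in range(30):
                cand = u + step
                pll_cand = self.penalized_ll(beta, cand, inv_var)
                if pll_cand >= pll - 1e-12:
                    improved = True
                    break
                step = step / 2.0
            u = cand
            if not improved or abs(pll_cand - pll) < tol * (abs(pll) + 1.0):
                pll = pll_cand
                break
            pll = pll_cand
        self.u = u.copy()
        return u

    def laplace_loglik(self, beta, log_sd):
        sd = np.exp(log_sd)
        inv_var = 1.0 / np.maximum(sd, 1e-8) ** 2
        u = self.solve_mode(beta, inv_var)
        eta = np.clip(self.eta(beta, u), -_MAX_ETA, _MAX_ETA)
        mu = np.exp(eta)
        ll = self.penalized_ll(beta, u, inv_var)
        for j in range(len(self.codes)):
            ll -= self.sizes[j] * float(log_sd[j])
        h = self.hessian(mu, inv_var)
        sign, logdet = np.linalg.slogdet(h)
        if sign <= 0:
            return -np.inf, u, mu, h
        return ll - 0.5 * logdet, u, mu, h


def fit_poisson_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    start_sd: float = 0.3,
    max_outer_iter: int = 200,
    fix_sd: float | None = None,
) -> GlmmFit:
    """Fit the Poisson model; random intercepts via the Laplace approximation.

    With ``spec.random_intercepts`` empty, this is an ordinary Poisson GLM.
    ``fix_sd`` pins every random-intercept SD at a constant (only beta is
    optimized) — mainly for the sigma -> 0 GLM-equivalence check.
    Non-convergence is flagged on the returned fit, never silent.
    """
    spec = replace(spec, scaling=dict(spec.scaling),
                   fixed_terms=list(spec.fixed_terms),
                   random_intercepts=list(spec.random_intercepts))
    y = data["count"].to_numpy(dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise FitError("response must be nonnegative integer counts")
    if y.sum() == 0:
        raise FitError("all-zero response; Poisson model degenerate")
    x, names = build_design(data, spec)
    fingerprint = _fingerprint(data)

    if not spec.random_intercepts:
        beta, cov, ll = _fit_glm(y, x, names)
        mu = np.exp(np.clip(x @ beta, -_MAX_ETA, _MAX_ETA))
        n_params = len(beta)
        return GlmmFit(
            terms=names, beta=beta, se=np.sqrt(np.diag(cov)), cov_beta=cov,
            re_names=[], re_sd=np.array([]), re_modes={},
            loglik=ll, aic=-2 * ll + 2 * n_params, n_params=n_params,
            n_obs=len(y), fitted=mu, converged=True, message="GLM Newton scoring",
            spec=spec, data_fingerprint=fingerprint,
        )

    codes_list, sizes, levels_list = _group_codes(data, spec)
    work = _LaplaceWork(y, x, codes_list, sizes)
    p, m = x.shape[1], len(sizes)

    beta0, _, _ = _fit_glm(y, x, names)
    if fix_sd is not None:
        log_fix = np.log(max(fix_sd, 1e-8))
        theta0 = np.concatenate([beta0, np.full(m, log_fix)])
        bounds = [(None, None)] * p + [(log_fix, log_fix)] * m
    else:
        theta0 = np.concatenate([beta0, np.full(m, np.log(start_sd))])
        bounds = [(None, None)] * p + [(np.log(1e-4), np.log(10.0))] * m

    def objective(theta):
        ll, _, _, _ = work.laplace_loglik(theta[:p], theta[p:])
        return -ll if np.isfinite(ll) else 1e12

    result = optimize.minimize(
        objective, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_outer_iter, "ftol": 1e-11, "gtol": 1e-6},
    )
    beta = result.x[:p]
    log_sd = result.x[p:]
    ll, u_hat, mu, h = work.laplace_loglik(beta, log_sd)

    # conditional covariance of beta: Schur complement of the joint Hessian
    xtwx = (x * mu[:, None]).T @ x
    xtwz = np.zeros((p, work.q))
    w = mu
    for j, codes in enumerate(codes_list):
        oj, qj = work.offsets[j], sizes[j]
        for col in range(p):
            xtwz[col, oj: oj + qj] = np.bincount(codes, weights=w * x[:, col], minlength=qj)
    try:
        h_inv_ztx = np.linalg.solve(h, xtwz.T)
        cov_beta = np.linalg.inv(xtwx - xtwz @ h_inv_ztx)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular covariance at optimum: {exc}") from exc

    re_modes = {}
    for j, g in enumerate(spec.random_intercepts):
        oj, qj = work.offsets[j], sizes[j]
        re_modes[g] = dict(zip(levels_list[j], u_hat[oj: oj + qj]))

    n_params = p + m
    return GlmmFit(
        terms=names, beta=beta, se=np.sqrt(np.diag(cov_beta)), cov_beta=cov_beta,
        re_names=list(spec.random_intercepts), re_sd=np.exp(log_sd), re_modes=re_modes,
        loglik=float(ll), aic=float(-2 * ll + 2 * n_params), n_params=n_params,
        n_obs=len(y), fitted=mu, converged=bool(result.success),
        message=str(result.message), spec=spec, data_fingerprint=fingerprint,
    )


def _eliminable(terms: Sequence[str]) -> list[str]:
    """Terms removable under marginality: not a proper subset of another term."""
    sets = {t: frozenset(t.split(":")) for t in terms}
    return [t for t in terms if not any(sets[t] < sets[o] for o in terms if o != t)]


def backward_select(
    data: pd.DataFrame,
    full_spec: ModelSpec,
    alpha: float = 0.05,
) -> tuple[ModelSpec, GlmmFit, list[dict]]:
    """Backward stepwise elimination by likelihood-ratio test.

    At each step the eliminable term (respecting marginality) whose removal
    least reduces the log-likelihood is dropped if the LRT for its removal
    is non-significant at ``alpha``; selection stops when every candidate
    removal is significant.  Returns the selected spec, its fit, and a trail
    of per-step records.
    """
    spec = full_spec
    fit = fit_poisson_glmm(data, spec)
    if not fit.converged:
        raise FitError("full model did not converge; aborting selection")
    trail: list[dict] = []
    while spec.fixed_terms:
        candidates = []
        for term in _eliminable(spec.fixed_terms):
            reduced_spec = spec.drop_term(term)
            reduced_fit = fit_poisson_glmm(data, reduced_spec)
            if not reduced_fit.converged:
                raise FitError(f"fit without term {term!r} did not converge; trail: {trail}")
            chi2 = max(0.0, 2.0 * (fit.loglik - reduced_fit.loglik))
            p = float(stats.chi2.sf(chi2, 1))
            candidates.append((chi2, term, reduced_spec, reduced_fit, p))
        chi2, term, reduced_spec, reduced_fit, p = min(candidates, key=lambda c: c[0])
        record = {
            "term": term, "ll_full": fit.loglik, "ll_reduced": reduced_fit.loglik,
            "chi2": chi2, "df": 1, "p": p,
            "action": "removed" if p > alpha else "kept (stop)",
        }
        trail.append(record)
        if p > alpha:
            spec, fit = reduced_spec, reduced_fit
        else:
            break
    return spec, fit, trail


def compare_aic(fits: Sequence[GlmmFit]) -> pd.DataFrame:
    """Rank fits by AIC with ΔAIC relative to the best; data must match."""
    if not fits:
        raise ValueError("no fits to compare")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise FitError("fits were computed on different data; AIC not comparable")
    rows = [
        {
            "model": " + ".join(f.spec.fixed_terms) or "(intercept only)",
            "n_params": f.n_params,
            "loglik": f.loglik,
            "aic": f.aic,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table


def type3_anova(data: pd.DataFrame, spec: ModelSpec, fit: GlmmFit | None = None) -> pd.DataFrame:
    """Per-term Wald chi-squared tests with sum-to-zero factor coding.

    Each term is tested adjusting for all others (including its own
    interactions).  The model is refit under sum coding if needed.
    """
    if fit is None or fit.spec.coding != "sum":
        fit = fit_poisson_glmm(data, replace(spec, coding="sum", scaling={}))
    if not fit.converged:
        raise FitError("model did not converge; type-III tests unavailable")
    rows = []
    for term in fit.spec.fixed_terms:
        idx = [i for i, name in enumerate(fit.terms) if name == term]
        b = fit.beta[idx]
        cov = fit.cov_beta[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(cov, b))
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular covariance for term {term!r}: {exc}") from exc
        df = len(idx)
        rows.append({"term": term, "chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))})
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"])


def diagnostics(fit: GlmmFit, data: pd.DataFrame) -> tuple[float, float]:
    """(dispersion_ratio, zero_inflation_ratio) for a fitted count model.

    dispersion = sum of squared Pearson residuals / residual df;
    zero inflation = observed zeros / expected zeros under the fitted means.
    """
    y = data["count"].to_numpy(dtype=float)
    mu = fit.fitted
    pearson = (y - mu) / np.sqrt(mu)
    resid_df = fit.n_obs - fit.n_params
    dispersion = float(np.sum(pearson**2) / resid_df)
    expected_zeros = float(np.sum(np.exp(-mu)))
    observed_zeros = float(np.sum(y == 0))
    zero_inflation = observed_zeros / expected_zeros if expected_zeros > 0 else np.inf
    return dispersion, zero_inflation


def percent_change_per_day(beta_scaled: float, covariate_sd_days: float) -> float:
    """Back-transform a z-scaled slope to percent change per raw day."""
    if covariate_sd_days <= 0:
        raise ValueError("covariate SD must be positive")
    return (np.exp(beta_scaled / covariate_sd_days) - 1.0) * 100.0
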