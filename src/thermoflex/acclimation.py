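"""Common-garden acclimation analysis.

Thermogenic flexibility (delta M_sum = post- minus pre-acclimation
summit metabolism) is modeled with a Bayesian Gaussian linear mixed
model whose population random effect carries an F_ST-derived covariance:

    y = X beta + Z u + e,   u ~ N(0, sigma_u^2 S),   e ~ N(0, sigma_e^2 I)

with S built from pairwise Weir's theta (similarity 1 - theta, projected
to the nearest positive semidefinite matrix).  Conjugate Gibbs updates
give posterior means, 95% credible intervals, and pMCMC (twice the
smaller tail probability of a fixed effect crossing zero).  The module
also provides the flexibility CV analysis and the control-group paired
t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .envwindows import standardize_2sd

__all__ = [
    "PosteriorSummary",
    "fst_covariance",
    "GibbsLMM",
    "gibbs_lmm",
    "fit_delta_model",
    "pre_acclimation_checks",
    "cv_percent",
    "cv_vs_trange",
    "paired_ttest",
]


def fst_covariance(
    fst: pd.DataFrame,
    mode: str = "similarity",
    kernel_scale: float = 0.05,
) -> pd.DataFrame:
    """Population correlation structure from a pairwise F_ST matrix.

    ``similarity`` (default): S_ij = 1 - theta_ij, S_ii = 1, then
    eigenvalue-clipped to positive semidefinite and renormalized to unit
    diagonal.  ``kernel``: Gaussian-type kernel exp(-d / scale) on the
    linearized distance d = theta/(1 - theta) (PSD by construction for
    reasonable scales, clipped the same way as a guard).
    """
    theta = fst.to_numpy(float).copy()
    if np.isnan(theta[~np.eye(len(theta), dtype=bool)]).any():
        raise ValueError("F_ST matrix has missing pairs")
    np.fill_diagonal(theta, 0.0)
    if mode == "similarity":
        S = 1.0 - theta
    elif mode == "kernel":
        d = theta / (1.0 - theta)
        S = np.exp(-d / kernel_scale)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2
    w, V = np.linalg.eigh(S)
    if w.min() < -1e-12:
        S = (V * np.clip(w, 0.0, None)) @ V.T
        d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
        S = S / np.outer(d, d)
        np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=fst.index, columns=fst.columns)


@dataclass
class PosteriorSummary:
    """Posterior means, 95% CIs, pMCMC and diagnostics per fixed effect."""

    fixed: pd.DataFrame           # index: term; mean, ci_low, ci_high, pmcmc, ess
    sigma2_u: float
    sigma2_e: float
    n_samples: int
    n_capped: int = 0
    samples: pd.DataFrame | None = field(default=None, repr=False)

    def __getitem__(self, term: str) -> pd.Series:
        return self.fixed.loc[term]


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial positive autocorrelation sum."""
    n = len(x)
    x = x - x.mean()
    v = x @ x / n
    if v == 0:
        return float(n)
    acf_sum = 0.0
    for lag in range(1, n // 2):
        rho = (x[:-lag] @ x[lag:]) / (n * v)
        if rho <= 0:
            break
        acf_sum += rho
    return float(n / (1 + 2 * acf_sum))


class GibbsLMM:
    """Gibbs sampler for the Gaussian mixed model with known correlation S.

    Priors (weakly informative, configurable): fixed effects
    N(0, beta_var) with beta_var = 1e8; both variances
    inverse-gamma(prior_a, prior_b) with a = b = 1e-3.  Divergent
    variance draws are capped at ``var_cap`` and counted.
    """

    def __init__(
        self,
        n_iter: int = 100_000,
        burn_in: int = 10_000,
        thin: int = 100,
        seed: int | np.random.Generator = 0,
        beta_var: float = 1e8,
        prior_a: float = 1e-3,
        prior_b: float = 1e-3,
        var_cap: float = 1e8,
    ) -> None:
        self.n_iter = int(n_iter)
        self.burn_in = int(burn_in)
        self.thin = int(thin)
        self.seed = seed
        self.beta_var = beta_var
        self.prior_a = prior_a
        self.prior_b = prior_b
        self.var_cap = var_cap

    def fit(
        self,
        y: np.ndarray,
        X: np.ndarray,
        Z: np.ndarray | None = None,
        S: np.ndarray | None = None,
        term_names: list[str] | None = None,
    ) -> PosteriorSummary:
        rng = (self.seed if isinstance(self.seed, np.random.Generator)
               else np.random.default_rng(self.seed))
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        n, p = X.shape
        names = term_names or [f"b{j}" for j in range(p)]
        has_u = Z is not None
        if has_u:
            Z = np.asarray(Z, float)
            q = Z.shape[1]
            S = np.eye(q) if S is None else np.asarray(S, float)
            w, V = np.linalg.eigh((S + S.T) / 2)
            if w.min() < -1e-8:
                raise ValueError("S is not positive semidefinite; use fst_covariance")
            # jittered inverse keeps the singular all-ones limit usable
            S_inv = (V / np.clip(w, 1e-8, None)) @ V.T
            ZtZ = Z.T @ Z
            Zty = Z.T @ y

        XtX = X.T @ X
        Xty = X.T @ y
        Ip = np.eye(p) / self.beta_var

        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        u = np.zeros(q) if has_u else None
        resid0 = y - X @ beta
        s2e = max(float(resid0 @ resid0 / max(n - p, 1)), 1e-6)
        s2u = s2e if has_u else 0.0

        keep = [t for t in range(self.burn_in, self.n_iter) if (t - self.burn_in) % self.thin == 0]
        n_keep = len(keep)
        beta_s = np.empty((n_keep, p))
        var_s = np.empty((n_keep, 2))
        n_capped = 0
        k = 0
        keep_set = np.zeros(self.n_iter, bool)
        keep_set[keep] = True

        for t in range(self.n_iter):
            resp = y - Z @ u if has_u else y
            A = XtX / s2e + Ip
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, X.T @ resp / s2e)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))

            if has_u:
                r = y - X @ beta
                Au = ZtZ / s2e + S_inv / s2u
                Lu = np.linalg.cholesky(Au)
                mu = np.linalg.solve(Au, Z.T @ r / s2e)
                u = mu + np.linalg.solve(Lu.T, rng.standard_normal(q))
                quad = float(u @ S_inv @ u)
                s2u = (self.prior_b + quad / 2) / rng.gamma(self.prior_a + q / 2)
                if s2u > self.var_cap:
                    s2u = self.var_cap
                    n_capped += 1
                resid = r - Z @ u
            else:
                resid = y - X @ beta
            s2e = (self.prior_b + float(resid @ resid) / 2) / rng.gamma(self.prior_a + n / 2)
            if s2e > self.var_cap:
                s2e = self.var_cap
                n_capped += 1

            if keep_set[t]:
                beta_s[k] = beta
                var_s[k] = (s2u, s2e)
                k += 1

        rows = []
        for j, name in enumerate(names):
            draws = beta_s[:, j]
            lo, hi = np.quantile(draws, [0.025, 0.975])
            p_pos = (draws > 0).mean()
            pmcmc = max(2 * min(p_pos, 1 - p_pos), 1.0 / n_keep)
            rows.append((name, draws.mean(), lo, hi, min(pmcmc, 1.0), _ess(draws)))
        fixed = pd.DataFrame(
            rows, columns=["term", "mean", "ci_low", "ci_high", "pmcmc", "ess"]
        ).set_index("term")
        samples = pd.DataFrame(beta_s, columns=names)
        samples["sigma2_u"] = var_s[:, 0]
        samples["sigma2_e"] = var_s[:, 1]
        return PosteriorSummary(
            fixed=fixed,
            sigma2_u=float(var_s[:, 0].mean()),
            sigma2_e=float(var_s[:, 1].mean()),
            n_samples=n_keep, n_capped=n_capped, samples=samples,
        )


def gibbs_lmm(y, X, Z=None, S=None, term_names=None, **kwargs) -> PosteriorSummary:
    """Functional wrapper over :class:`GibbsLMM`."""
    return GibbsLMM(**kwargs).fit(y, X, Z=Z, S=S, term_names=term_names)


def _design_delta(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    treat = (records["treatment"] == "cold").astype(float).to_numpy()
    mass = standardize_2sd(records["mass_pre"])
    trange = standardize_2sd(records["t_range"])
    X = np.column_stack([np.ones(len(records)), mass, treat, trange, treat * trange])
    names = ["intercept", "mass_pre", "treat_cold", "t_range", "treat_cold:t_range"]
    return X, treat, names


def _pop_design(records: pd.DataFrame, fst: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    pops = list(fst.index)
    missing = set(records["population"]) - set(pops)
    if missing:
        raise ValueError(f"populations absent from F_ST matrix: {sorted(missing)}")
    Z = np.stack([(records["population"] == p).to_numpy(float) for p in pops], axis=1)
    S = fst_covariance(fst).to_numpy()
    return Z, S


def fit_delta_model(
    records: pd.DataFrame,
    fst: pd.DataFrame,
    **sampler_kwargs,
) -> PosteriorSummary:
    """Delta M_sum ~ pre-acclimation mass + treatment * T_range, F_ST random effect.

    ``records`` needs columns: population, treatment (cold/control),
    mass_pre, msum_pre, msum_post, t_range.  Treatment is coded
    control = 0, cold = 1.
    """
    records = records.dropna(subset=["msum_pre", "msum_post", "mass_pre", "t_range"])
    y = (records["msum_post"] - records["msum_pre"]).to_numpy(float)
    X, _, names = _design_delta(records)
    Z, S = _pop_design(records, fst)
    return gibbs_lmm(y, X, Z, S, term_names=names, **sampler_kwargs)


def pre_acclimation_checks(
    records: pd.DataFrame, fst: pd.DataFrame, **sampler_kwargs
) -> dict[str, PosteriorSummary]:
    """Pre-treatment balance models (each with the F_ST random effect):
    M_sum ~ treatment; M_b ~ treatment; M_sum ~ T_range; M_b ~ T_range;
    and, when a season column is present, M_sum ~ season + M_b.
    """
    Z, S = _pop_design(records, fst)
    n = len(records)
    treat = (records["treatment"] == "cold").astype(float).to_numpy()
    trange = standardize_2sd(records["t_range"])
    out: dict[str, PosteriorSummary] = {}
    specs = {
        "msum_pre~treatment": (records["msum_pre"], treat, "treat_cold"),
        "mass_pre~treatment": (records["mass_pre"], treat, "treat_cold"),
        "msum_pre~t_range": (records["msum_pre"], trange, "t_range"),
        "mass_pre~t_range": (records["mass_pre"], trange, "t_range"),
    }
    for label, (y, x, name) in specs.items():
        X = np.column_stack([np.ones(n), x])
        out[label] = gibbs_lmm(np.asarray(y, float), X, Z, S,
                               term_names=["intercept", name], **sampler_kwargs)
    if "season" in records.columns:
        season = (records["season"] != "breeding").astype(float).to_numpy()
        mass = standardize_2sd(records["mass_pre"])
        X = np.column_stack([np.ones(n), season, mass])
        out["msum_pre~season+mass"] = gibbs_lmm(
            records["msum_pre"].to_numpy(float), X, Z, S,
            term_names=["intercept", "season_nb", "mass_pre"], **sampler_kwargs)
    return out


def cv_percent(values) -> float:
    """Coefficient of variation as a percentage: 100 * sd(n-1) / mean."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("CV needs n >= 2")
    m = x.mean()
    if abs(m) < 1e-12:
        warnings.warn("mean ~ 0: CV undefined")
        return np.nan
    return float(100.0 * x.std(ddof=1) / m)


def cv_vs_trange(cv: pd.Series, t_range: pd.Series) -> dict:
    """Simple regression of per-population flexibility CV on T_range."""
    idx = cv.index.intersection(t_range.index)
    if len(idx) < 3:
        raise ValueError("need >= 3 populations")
    fit = stats.linregress(t_range.loc[idx].astype(float), cv.loc[idx].astype(float))
    return {"r2": fit.rvalue ** 2, "beta": fit.slope, "se": fit.stderr,
            "p": fit.pvalue, "n": len(idx)}


def paired_ttest(pre, post) -> dict:
    """Paired t-test on post - pre differences (two-sided)."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need matching pre/post arrays with n >= 2")
    d = post - pre
    if np.all(d == d[0]) and d[0] == 0:
        return {"t": 0.0, "df": pre.size - 1, "p": 1.0, "n": pre.size}
    res = stats.ttest_rel(post, pre)
    return {"t": float(res.statistic), "df": pre.size - 1,
            "p": float(res.pvalue), "n": pre.size}
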