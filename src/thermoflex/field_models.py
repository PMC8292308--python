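"""Field summit-metabolism models and reaction norms.

Fits the family of linear models

    M_sum = M_b + taxon * env

for each candidate environmental variable and acclimatization window,
ranks them by AIC against a null (M_b + taxon), back-transforms the
taxon-specific standardized coefficients to raw-scale reaction-norm
slopes (ml O2 min^-1 degC^-1), and regresses those slopes on each
taxon's mean annual temperature range (the thermal-heterogeneity index).

Continuous predictors are standardized by two standard deviations on the
complete-case subset actually fitted.  AIC includes the Gaussian
constant and counts the residual variance as a parameter (the R
convention), so values are comparable with AIC() output there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .envwindows import standardize_2sd

__all__ = [
    "FieldModelResult",
    "ReactionNorms",
    "fit_field_model",
    "select_model",
    "reaction_norm_slopes",
    "flexibility_vs_heterogeneity",
    "DEFAULT_REFERENCE_TAXON",
    "CANDIDATE_VARIABLES",
]

DEFAULT_REFERENCE_TAXON = "oreganus"
#: windowed candidates; elevation enters window-free
CANDIDATE_VARIABLES = ("tmin", "tmax", "prcp", "dayl", "vp", "srad", "t_d_range")


@dataclass
class FieldModelResult:
    variable: str
    window: int | None
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    aic: float
    r2: float
    n: int
    taxa: list[str]
    reference_taxon: str
    var_raw_sd: float | None  # n-1 sd of the raw variable on the fitted subset
    has_interaction: bool = True


@dataclass
class ReactionNorms:
    """Per-taxon raw-scale slope of M_sum on the environmental variable."""

    slopes: pd.Series  # ml O2 min^-1 per degC (raw scale)
    slope_se: pd.Series
    mean_annual_range: pd.Series  # degC per taxon
    variable: str = "t_d_range"


def _aic(results, n_mean_params: int) -> float:
    # 2p - 2 llf with p = mean parameters + residual variance
    return float(2 * (n_mean_params + 1) - 2 * results.llf)


def _design(
    data: pd.DataFrame,
    variable: str | None,
    reference_taxon: str,
    interaction: bool,
    extra: list[str] | None = None,
) -> tuple[pd.DataFrame, float | None, list[str]]:
    taxa = sorted(data["taxon"].unique())
    if reference_taxon not in taxa:
        raise ValueError(f"reference taxon {reference_taxon!r} not in data ({taxa})")
    others = [t for t in taxa if t != reference_taxon]
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["mass"] = standardize_2sd(data["mass"])
    for t in others:
        X[f"taxon[{t}]"] = (data["taxon"] == t).astype(float)
    var_sd = None
    if variable is not None:
        raw = data[variable].to_numpy(float)
        var_sd = float(np.std(raw, ddof=1))
        X[variable] = standardize_2sd(raw)
        if interaction:
            for t in others:
                X[f"taxon[{t}]:{variable}"] = X[f"taxon[{t}]"] * X[variable]
    for name in extra or []:
        X[name] = data[name].to_numpy(float)
    return X, var_sd, taxa


def fit_field_model(
    data: pd.DataFrame,
    variable: str | None,
    window: int | None = None,
    reference_taxon: str = DEFAULT_REFERENCE_TAXON,
    interaction: bool = True,
    extra: list[str] | None = None,
) -> FieldModelResult:
    """OLS fit of M_sum on mass, taxon, and one (standardized) env variable.

    ``data`` must hold columns msum, mass, taxon and, unless ``variable``
    is None (the null model), the named variable.  Rows with missing
    values in used columns are dropped first.
    """
    cols = ["msum", "mass", "taxon"] + ([variable] if variable else []) + (extra or [])
    data = data.dropna(subset=cols)
    # a taxon must span the variable to identify its interaction slope
    if variable is not None and interaction:
        counts = data.groupby("taxon")[variable].nunique()
        bad = counts[counts < 2].index.tolist()
        if bad:
            raise ValueError(f"taxa with <2 distinct {variable} values: {bad}")
    X, var_sd, taxa = _design(data, variable, reference_taxon, interaction, extra)
    res = sm.OLS(data["msum"].to_numpy(float), X).fit()
    return FieldModelResult(
        variable=variable or "null",
        window=window,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        cov_params=res.cov_params(),
        aic=_aic(res, X.shape[1]),
        r2=float(res.rsquared),
        n=int(len(data)),
        taxa=taxa,
        reference_taxon=reference_taxon,
        var_raw_sd=var_sd,
        has_interaction=interaction and variable is not None,
    )


def select_model(
    pheno: pd.DataFrame,
    env_features: pd.DataFrame,
    variables: tuple = CANDIDATE_VARIABLES,
    windows: range | tuple = range(7, 15),
    include_elev: bool = True,
    reference_taxon: str = DEFAULT_REFERENCE_TAXON,
) -> tuple[pd.DataFrame, FieldModelResult, dict]:
    """Rank all variable x window candidates (plus elev and null) by AIC.

    Returns (ranked table, best FieldModelResult, diagnostics).  The
    diagnostics dict reports the best model's delta-AIC against the same
    model without the taxon interaction and, when a ``season`` column is
    present in ``pheno``, against the model with a season term added.
    """
    rows, fits = [], {}
    for v in variables:
        for k in windows:
            feat = env_features.loc[env_features["window_days"] == k, ["id", v]]
            data = pheno.merge(feat, on="id")
            fit = fit_field_model(data, v, window=k, reference_taxon=reference_taxon)
            fits[(v, k)] = fit
            rows.append((v, k, fit.aic, fit.r2, fit.n))
    if include_elev and "elev" in pheno.columns:
        fit = fit_field_model(pheno, "elev", window=None, reference_taxon=reference_taxon)
        fits[("elev", None)] = fit
        rows.append(("elev", None, fit.aic, fit.r2, fit.n))
    null = fit_field_model(pheno, None, reference_taxon=reference_taxon)
    fits[("null", None)] = null
    rows.append(("null", None, null.aic, null.r2, null.n))

    table = pd.DataFrame(rows, columns=["variable", "window", "aic", "r2", "n"])
    table = table.sort_values("aic").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    best_key = (table.loc[0, "variable"], table.loc[0, "window"])
    best = fits[best_key]

    diagnostics = {}
    if best.variable != "null":
        v, k = best_key
        feat = (
            env_features.loc[env_features["window_days"] == k, ["id", v]]
            if k is not None else pheno[["id", v]] if v in pheno.columns else None
        )
        data = pheno.merge(feat, on="id") if k is not None else pheno
        no_int = fit_field_model(data, v, window=k, interaction=False,
                                 reference_taxon=reference_taxon)
        diagnostics["delta_aic_interaction"] = no_int.aic - best.aic
        if "season" in pheno.columns:
            d2 = data.copy()
            d2["season_nb"] = (d2["season"] != "breeding").astype(float)
            with_season = fit_field_model(d2, v, window=k, extra=["season_nb"],
                                          reference_taxon=reference_taxon)
            diagnostics["delta_aic_season"] = with_season.aic - best.aic
            diagnostics["season_beta"] = float(with_season.params["season_nb"])
    return table, best, diagnostics


def reaction_norm_slopes(
    best: FieldModelResult,
    pheno_env: pd.DataFrame,
) -> ReactionNorms:
    """Raw-scale per-taxon slopes from the best (interaction) model.

    The standardized slope for the reference taxon is the variable's main
    effect; for every other taxon it is main effect + that taxon's
    interaction coefficient.  Dividing by twice the raw variable's sd
    undoes the 2-SD standardization.  ``pheno_env`` must carry taxon and
    annual_temp_range per individual for the heterogeneity index.
    """
    if not best.has_interaction:
        raise ValueError("best model has no taxon x variable interaction term")
    v = best.variable
    denom = 2.0 * best.var_raw_sd
    slopes, ses = {}, {}
    for t in best.taxa:
        if t == best.reference_taxon:
            std = best.params[v]
            var = best.cov_params.loc[v, v]
        else:
            key = f"taxon[{t}]:{v}"
            std = best.params[v] + best.params[key]
            var = (
                best.cov_params.loc[v, v]
                + best.cov_params.loc[key, key]
                + 2 * best.cov_params.loc[v, key]
            )
        slopes[t] = std / denom
        ses[t] = np.sqrt(var) / denom
    mar = pheno_env.groupby("taxon")["annual_temp_range"].mean()
    return ReactionNorms(
        slopes=pd.Series(slopes), slope_se=pd.Series(ses),
        mean_annual_range=mar, variable=v,
    )


def flexibility_vs_heterogeneity(
    norms: ReactionNorms, leave_out: str | None = None
) -> dict:
    """Simple regression of reaction-norm slope on mean annual temp range."""
    taxa = [t for t in norms.slopes.index if t != leave_out]
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa after exclusion")
    x = norms.mean_annual_range.loc[taxa].to_numpy(float)
    y = norms.slopes.loc[taxa].to_numpy(float)
    fit = stats.linregress(x, y)
    return {
        "r2": fit.rvalue ** 2,
        "beta": fit.slope,
        "se": fit.stderr,
        "p": fit.pvalue,
        "n": len(taxa),
    }
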