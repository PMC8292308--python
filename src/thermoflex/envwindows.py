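"""Acclimatization-window environmental predictors.

Per-individual window means of daily weather variables (DayMet-style
tables) over the 7-14 days strictly preceding capture, the daily
temperature range T_d_range = Tmax - Tmin, and the 2-SD standardization
used for continuous predictors throughout the analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "daily_range",
    "window_mean",
    "standardize_2sd",
    "build_env_features",
    "WEATHER_VARIABLES",
]

#: daily weather fields carried through window averaging
WEATHER_VARIABLES = ("tmin", "tmax", "prcp", "vp", "srad", "dayl", "t_d_range")


def daily_range(weather: pd.DataFrame) -> pd.Series:
    """T_d_range (degC) = tmax - tmin, elementwise."""
    if (weather["tmax"] < weather["tmin"]).any():
        raise ValueError("tmax < tmin in weather table")
    return weather["tmax"] - weather["tmin"]


def window_mean(
    weather: pd.DataFrame,
    site: str,
    capture_date,
    k_days: int,
    variable: str,
) -> float:
    """Mean of ``variable`` over the k days strictly preceding capture.

    The window is capture-1 ... capture-k (capture day excluded).  Any
    missing day raises with the gap named; there is no silent imputation.
    """
    capture_date = pd.Timestamp(capture_date)
    wanted = pd.date_range(capture_date - pd.Timedelta(days=k_days),
                           capture_date - pd.Timedelta(days=1), freq="D")
    sub = weather[weather["site"] == site].set_index(pd.DatetimeIndex(weather.loc[weather["site"] == site, "date"]))
    missing = wanted.difference(sub.index)
    if len(missing):
        raise KeyError(
            f"site {site!r}: missing weather for {[str(d.date()) for d in missing]}"
        )
    return float(sub.loc[wanted, variable].mean())


def standardize_2sd(x) -> np.ndarray:
    """Center and divide by two standard deviations (n-1 denominator).

    The resulting vector has mean 0 and sd 0.5, putting continuous
    predictors on a scale comparable to binary ones.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2 to standardize")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("constant vector cannot be 2-SD standardized")
    return (x - x.mean()) / (2.0 * s)


def build_env_features(
    pheno: pd.DataFrame,
    weather: pd.DataFrame,
    bioclim: pd.DataFrame | None = None,
    windows: range | tuple = range(7, 15),
    variables: tuple = WEATHER_VARIABLES,
) -> pd.DataFrame:
    """Tidy per-individual x per-window feature table.

    ``pheno`` needs columns id, site, capture_date; ``weather`` needs
    site, date and the daily fields.  If a ``bioclim`` table (site,
    bio1..bio19) is given, BIO7 is attached as ``annual_temp_range``.
    Elevation (``elev``), when present in pheno, is carried window-free.
    """
    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])
    if "t_d_range" in variables and "t_d_range" not in weather.columns:
        weather["t_d_range"] = daily_range(weather)
    by_site = {
        s: sub.set_index("date")[list(variables)].sort_index()
        for s, sub in weather.groupby("site")
    }
    rows = []
    for _, ind in pheno.iterrows():
        sub = by_site[ind["site"]]
        cap = pd.Timestamp(ind["capture_date"])
        for k in windows:
            wanted = pd.date_range(cap - pd.Timedelta(days=k),
                                   cap - pd.Timedelta(days=1), freq="D")
            if len(wanted.difference(sub.index)):
                missing = wanted.difference(sub.index)
                raise KeyError(
                    f"site {ind['site']!r}: missing weather for "
                    f"{[str(d.date()) for d in missing]}"
                )
            row = {"id": ind["id"], "window_days": int(k),
                   **sub.loc[wanted].mean().to_dict()}
            if "elev" in pheno.columns:
                row["elev"] = ind["elev"]
            rows.append(row)
    out = pd.DataFrame(rows)
    if bioclim is not None:
        b7 = pheno.merge(
            bioclim[["site", "bio7"]].rename(columns={"bio7": "annual_temp_range"}),
            on="site", how="left",
        )[["id", "annual_temp_range"]]
        out = out.merge(b7, on="id", how="left")
    return out
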