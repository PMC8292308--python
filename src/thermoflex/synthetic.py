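"""Synthetic data with known ground truth for every pipeline stage.

Each generator emulates the statistical structure the downstream
analyses assume: respirometry traces with a planted peak VO2 plus
baseline drift and instrument noise; daily weather with a seasonal
cycle; genotypes under a Balding-Nichols island model with an optional
planted environmental cline at a subset of loci; field summit
metabolism built on taxon-specific reaction norms to the daily
temperature range; and an acclimation experiment with a planted
treatment x T_range interaction whose cold-group residual scatter
shrinks with T_range.

All randomness flows from ``SimConfig.seed``: each generator derives its
own deterministic stream, so identical configs give identical outputs
and generators do not perturb one another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .respirometry import RespTrace

__all__ = [
    "SimConfig",
    "TraceParams",
    "WeatherParams",
    "FieldParams",
    "GenotypeParams",
    "AcclimationParams",
    "gen_resp_trace",
    "gen_weather",
    "gen_genotypes",
    "gen_field_dataset",
    "gen_acclimation_dataset",
]

# stream tags keep the per-generator RNGs independent but reproducible
_STREAMS = {"trace": 1, "weather": 2, "geno": 3, "field": 4, "acclim": 5}


@dataclass
class TraceParams:
    peak_vo2: float = 3.0            # ml O2 min^-1, the planted M_sum
    flow: float = 500.0              # ml min^-1
    fio2: float = 0.21
    drift_pct_per_hr: float = 0.05   # baseline drift, %O2 per hour
    noise_sd_pct: float = 0.001      # instrument noise, %O2
    baseline_s: float = 300.0
    animal_s: float = 1800.0
    plateau_s: float = 360.0         # >= the averaging window
    dt: float = 1.0


@dataclass
class WeatherParams:
    site_mean_c: float = 10.0
    seasonal_amplitude_c: float = 12.0
    daily_range_mean_c: float = 10.0
    daily_range_sd_c: float = 5.0    # day-to-day noise in Tmax - Tmin
    noise_sd_c: float = 2.0          # day-to-day noise in the midpoint


@dataclass
class FieldParams:
    # per-taxon M_sum intercepts (ml O2/min) and raw reaction-norm slopes
    # (ml O2/min/degC on the window-mean daily temperature range)
    intercepts: dict = field(default_factory=lambda: {
        "mearnsi": 6.5, "palliatus": 5.8, "caniceps": 7.0,
        "oreganus": 7.2, "hyemalis": 8.0,
    })
    slopes: dict = field(default_factory=lambda: {
        "mearnsi": 0.03, "palliatus": 0.10, "caniceps": 0.15,
        "oreganus": 0.20, "hyemalis": 0.30,
    })
    # per-taxon mean annual temperature range (degC, BIO7-like), roughly
    # collinear with the slopes so the heterogeneity regression has signal
    annual_range: dict = field(default_factory=lambda: {
        "mearnsi": 24.0, "palliatus": 28.0, "caniceps": 32.0,
        "oreganus": 36.0, "hyemalis": 42.0,
    })
    mass_effect: float = 0.39        # ml O2/min per g
    mass_mean: float = 19.0
    mass_sd: float = 1.5
    residual_sd: float = 0.45
    n_per_taxon: int = 100
    sites_per_taxon: int = 2
    true_window: int = 8             # days; the planted predictor


@dataclass
class GenotypeParams:
    n_pops: int = 5
    n_individuals: int = 20          # per population
    n_loci: int = 2000
    fst_target: float = 0.05
    n_adaptive_loci: int = 200
    env_effect: float = 2.0          # logit-scale slope on standardized env
    missing_rate: float = 0.02       # MCAR per-site mean
    depth_mean: float = 20.0
    # optional deep background structure: clade index per population and
    # the between-clade differentiation.  With clades set, ancestry axes
    # (PC1/PC2) capture the clade splits -- the structure the conditioned
    # ordination is meant to remove -- while the environmental cline is
    # planted within/across clades.
    clades: tuple | None = None
    clade_fst: float = 0.25


@dataclass
class AcclimationParams:
    t_range: dict = field(default_factory=lambda: {
        "aikeni": 45.0, "dorsalis": 38.0, "palliatus": 32.0,
        "shufeldti": 28.0, "thurberi": 24.0,
    })
    n_per_group: int = 10            # per population per treatment
    # fixed effects on the 2-SD standardized scale; the zero intercept keeps
    # control birds centered on no change, and the treatment effect keeps
    # every population's mean cold response bounded away from zero so the
    # CV (sd/mean) stays well defined
    intercept: float = 0.0
    mass_effect: float = 0.5
    treatment_effect: float = 0.75
    interaction_effect: float = 0.6
    pop_sd: float = 0.1
    resid_sd: float = 0.35
    resid_sd_slope: float = -0.3     # cold-group sd per unit 2-SD T_range
    mass_mean: float = 19.0
    mass_sd: float = 1.5
    msum_baseline: float = 7.0


@dataclass
class SimConfig:
    seed: int = 0
    trace: TraceParams = field(default_factory=TraceParams)
    weather: WeatherParams = field(default_factory=WeatherParams)
    fieldp: FieldParams = field(default_factory=FieldParams)
    geno: GenotypeParams = field(default_factory=GenotypeParams)
    acclim: AcclimationParams = field(default_factory=AcclimationParams)

    def __post_init__(self) -> None:
        if not 0 < self.geno.fst_target < 1:
            raise ValueError("fst_target must be in (0, 1)")
        if self.geno.n_adaptive_loci > self.geno.n_loci:
            raise ValueError("n_adaptive_loci exceeds n_loci")
        if self.trace.flow <= 0 or self.trace.peak_vo2 <= 0:
            raise ValueError("flow and peak VO2 must be positive")
        if self.trace.animal_s <= 0 or self.trace.baseline_s <= 0:
            raise ValueError("trace durations must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Respirometry traces


def gen_resp_trace(cfg: SimConfig, rng: np.random.Generator | None = None
                   ) -> tuple[RespTrace, float]:
    """A trace whose drift-free 5-min-window maximum VO2 is the planted peak.

    Layout: pre baseline | animal segment | post baseline.  The VO2
    profile ramps to a plateau (>= one averaging window long) at the
    planted value, then declines; linear baseline drift and Gaussian
    noise are added to the O2 fraction.  Returns (trace, planted_msum).
    """
    p = cfg.trace
    rng = cfg.rng("trace") if rng is None else rng
    nb = int(round(p.baseline_s / p.dt))
    na = int(round(p.animal_s / p.dt))
    n = 2 * nb + na
    t = np.arange(n) * p.dt

    # piecewise VO2 profile: ramp, plateau at peak, partial recovery
    npl = int(round(p.plateau_s / p.dt))
    nramp = max((na - npl) // 2, 1)
    ndown = na - npl - nramp
    vo2 = np.concatenate([
        np.linspace(0.5 * p.peak_vo2, p.peak_vo2, nramp, endpoint=False),
        np.full(npl, p.peak_vo2),
        np.linspace(p.peak_vo2, 0.8 * p.peak_vo2, max(ndown, 0)),
    ])[:na]

    feo2 = np.full(n, p.fio2)
    feo2[nb:nb + na] = p.fio2 - vo2 * (1.0 - p.fio2) / p.flow
    drift = (p.drift_pct_per_hr / 100.0) / 3600.0   # O2 fraction per second
    feo2 = feo2 + drift * t
    feo2 = feo2 + rng.normal(0.0, p.noise_sd_pct / 100.0, size=n)

    return RespTrace(
        time=t, feo2=feo2, flow=p.flow, fio2=p.fio2,
        baseline_segments=[(0, nb), (nb + na, n)],
        animal_segment=(nb, nb + na),
    ), p.peak_vo2


# ---------------------------------------------------------------------------
# Weather


def gen_weather(
    cfg: SimConfig,
    n_days: int,
    site: str = "site_0",
    start: str = "2017-01-01",
    daily_range_mean: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """DayMet-style daily table: seasonal sinusoid midpoint +- half the range."""
    if n_days < 14:
        raise ValueError("n_days must be >= 14")
    p = cfg.weather
    rng = cfg.rng("weather") if rng is None else rng
    dr_mean = p.daily_range_mean_c if daily_range_mean is None else daily_range_mean
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    mid = (p.site_mean_c
           + p.seasonal_amplitude_c * np.sin(2 * np.pi * (doy - 105) / 365.25)
           + rng.normal(0.0, p.noise_sd_c, n_days))
    dr = dr_mean + rng.normal(0.0, p.daily_range_sd_c, n_days)
    dr = np.maximum(dr, 0.5)
    dayl = 43200.0 + 14400.0 * np.sin(2 * np.pi * (doy - 80) / 365.25)
    return pd.DataFrame({
        "site": site,
        "date": dates,
        "tmin": mid - dr / 2,
        "tmax": mid + dr / 2,
        "prcp": rng.gamma(0.4, 5.0, n_days),
        "vp": 610.0 * np.exp(0.06 * mid) + rng.normal(0, 20, n_days),
        "srad": np.maximum(250.0 + 120.0 * np.sin(2 * np.pi * (doy - 80) / 365.25)
                           + rng.normal(0, 30, n_days), 10.0),
        "dayl": dayl,
    })


# ---------------------------------------------------------------------------
# Genotypes


def gen_genotypes(
    cfg: SimConfig,
    env: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
):
    """Island-model genotypes with an optional planted environmental cline.

    Neutral loci draw population allele frequencies from the
    Balding-Nichols beta distribution with parameter set by the F_ST
    target; at adaptive loci the population frequency is logit-linear in
    the (standardized) site environmental value.  Returns
    (GenoMatrix, truth dict with adaptive locus indices and env values).
    """
    from .popgen import GenoMatrix

    g = cfg.geno
    rng = cfg.rng("geno") if rng is None else rng
    if env is None:
        env = np.linspace(-1.0, 1.0, g.n_pops) * 10 + 30
    env = np.asarray(env, float)
    if len(env) != g.n_pops:
        raise ValueError("need one environmental value per population")
    env_z = (env - env.mean()) / env.std(ddof=1) if env.std() > 0 else np.zeros_like(env)

    F = g.fst_target
    p_anc = rng.uniform(0.1, 0.9, g.n_loci)

    def _bn(p: np.ndarray, f: float, size) -> np.ndarray:
        p = np.clip(p, 1e-3, 1 - 1e-3)
        return rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f, size=size)

    if g.clades is not None:
        clades = np.asarray(g.clades)
        if len(clades) != g.n_pops:
            raise ValueError("need one clade index per population")
        labels = np.unique(clades)
        clade_freqs = _bn(p_anc, g.clade_fst, (len(labels), g.n_loci))
        parent = clade_freqs[np.searchsorted(labels, clades)]
    else:
        parent = np.broadcast_to(p_anc, (g.n_pops, g.n_loci))
    freqs = _bn(parent, F, (g.n_pops, g.n_loci))

    adaptive = rng.choice(g.n_loci, size=g.n_adaptive_loci, replace=False)
    adaptive.sort()
    if g.n_adaptive_loci:
        base = np.clip(parent[:, adaptive], 1e-3, 1 - 1e-3)
        logit = np.log(base / (1 - base))
        la = logit + g.env_effect * env_z[:, None]
        fa = 1.0 / (1.0 + np.exp(-la))
        n_clip = int(((fa <= 0.01) | (fa >= 0.99)).sum())
        if n_clip:
            warnings.warn(f"{n_clip} adaptive frequencies clipped to (0.01, 0.99)")
        freqs[:, adaptive] = np.clip(fa, 0.01, 0.99)

    n_ind = g.n_pops * g.n_individuals
    pops = np.repeat([f"pop_{i}" for i in range(g.n_pops)], g.n_individuals)
    gt = np.empty((n_ind, g.n_loci))
    for i in range(g.n_pops):
        rows = slice(i * g.n_individuals, (i + 1) * g.n_individuals)
        gt[rows] = rng.binomial(2, freqs[i], size=(g.n_individuals, g.n_loci)).astype(float)

    miss_rate = rng.uniform(0.0, 2 * g.missing_rate, g.n_loci)
    mask = rng.random((n_ind, g.n_loci)) < miss_rate[None, :]
    gt[mask] = np.nan
    depth = rng.gamma(10.0, g.depth_mean / 10.0, g.n_loci)

    gm = GenoMatrix(
        gt, depth, [f"ind_{i}" for i in range(n_ind)], pops,
        species=np.full(n_ind, "junco"),
    )
    truth = {"adaptive_loci": adaptive, "env": env, "env_z": env_z}
    return gm, truth


# ---------------------------------------------------------------------------
# Field dataset


def gen_field_dataset(cfg: SimConfig, n_days: int = 365):
    """Field phenotypes + weather + bioclim with planted reaction norms.

    M_sum = intercept_taxon + mass_effect * (M_b - mean) + slope_taxon *
    T_d_range(8-day window mean) + noise.  Each taxon occupies its own
    sites (differing in mean daily range) so window means vary both
    within and among taxa.  Returns (pheno, weather, bioclim, truth).
    """
    f = cfg.fieldp
    rng = cfg.rng("field")
    taxa = list(f.slopes)
    if len(taxa) < 2:
        raise ValueError("need >= 2 taxa")

    weather_parts, bioclim_rows, site_names = [], [], {}
    k = 0
    for tx in taxa:
        site_names[tx] = []
        for s in range(f.sites_per_taxon):
            name = f"site_{k}"
            dr = cfg.weather.daily_range_mean_c + rng.uniform(-3.0, 3.0)
            weather_parts.append(
                gen_weather(cfg, n_days, site=name, daily_range_mean=dr, rng=rng)
            )
            bioclim_rows.append({"site": name,
                                 "bio7": f.annual_range[tx] + rng.uniform(-1, 1),
                                 "elev": rng.uniform(200, 2500)})
            site_names[tx].append(name)
            k += 1
    weather = pd.concat(weather_parts, ignore_index=True)
    bioclim = pd.DataFrame(bioclim_rows)

    w_idx = {
        s: sub.set_index("date")
        for s, sub in weather.groupby("site")
    }
    rows = []
    idn = 0
    for tx in taxa:
        for _ in range(f.n_per_taxon):
            site = site_names[tx][rng.integers(len(site_names[tx]))]
            day = int(rng.integers(20, n_days - 1))
            cap = weather["date"].min() + pd.Timedelta(days=day)
            sub = w_idx[site]
            win = sub.loc[cap - pd.Timedelta(days=f.true_window):
                          cap - pd.Timedelta(days=1)]
            tdr = float((win["tmax"] - win["tmin"]).mean())
            mass = rng.normal(f.mass_mean, f.mass_sd)
            msum = (f.intercepts[tx] + f.mass_effect * (mass - f.mass_mean)
                    + f.slopes[tx] * tdr + rng.normal(0, f.residual_sd))
            rows.append({
                "id": f"bird_{idn}", "taxon": tx, "site": site,
                "capture_date": cap, "mass": mass, "msum": msum,
                "season": "breeding" if 80 <= day % 365 <= 260 else "nonbreeding",
                "elev": bioclim.set_index("site").loc[site, "elev"],
            })
            idn += 1
    pheno = pd.DataFrame(rows)
    truth = {"slopes": dict(f.slopes), "intercepts": dict(f.intercepts),
             "mass_effect": f.mass_effect, "true_window": f.true_window,
             "annual_range": dict(f.annual_range)}
    return pheno, weather, bioclim, truth


# ---------------------------------------------------------------------------
# Acclimation dataset


def gen_acclimation_dataset(
    cfg: SimConfig,
    fst: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
):
    """Common-garden records with a planted treatment x T_range interaction.

    delta M_sum = b0 + b_mass * mass_z + b_treat * cold + b_int * cold *
    T_range_z + u_pop + e, with u drawn from the F_ST-derived covariance
    and the cold-group residual sd decreasing in T_range.  Returns
    (records, fst, truth).
    """
    from .acclimation import fst_covariance

    a = cfg.acclim
    rng = cfg.rng("acclim") if rng is None else rng
    pops = list(a.t_range)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    if fst is None:
        th = rng.uniform(0.019, 0.051, size=(len(pops), len(pops)))
        th = (th + th.T) / 2
        np.fill_diagonal(th, 0.0)
        fst = pd.DataFrame(th, index=pops, columns=pops)
    missing = set(pops) - set(fst.index)
    if missing:
        raise ValueError(f"F_ST matrix lacks populations: {sorted(missing)}")

    S = fst_covariance(fst.loc[pops, pops]).to_numpy()
    L = np.linalg.cholesky(S + 1e-10 * np.eye(len(pops)))
    u = a.pop_sd * (L @ rng.standard_normal(len(pops)))
    u_base = a.pop_sd * (L @ rng.standard_normal(len(pops)))

    # standardize T_range on the individual level (balanced design) so the
    # planted coefficients sit on exactly the scale the analysis recovers
    tr = np.array([a.t_range[p] for p in pops])
    tr_ind = np.repeat(tr, 2 * a.n_per_group)
    tr_z_pop = (tr - tr_ind.mean()) / (2 * tr_ind.std(ddof=1))

    rows = []
    idn = 0
    for i, pop in enumerate(pops):
        for treatment in ("control", "cold"):
            for _ in range(a.n_per_group):
                cold = 1.0 if treatment == "cold" else 0.0
                mass = rng.normal(a.mass_mean, a.mass_sd)
                mass_z = (mass - a.mass_mean) / (2 * a.mass_sd)
                msum_pre = (a.msum_baseline + 0.3 * mass_z + u_base[i]
                            + rng.normal(0, 0.4))
                sd = a.resid_sd + (a.resid_sd_slope * tr_z_pop[i] if cold else 0.0)
                sd = max(sd, 0.05)
                delta = (a.intercept + a.mass_effect * mass_z + a.treatment_effect * cold
                         + a.interaction_effect * cold * tr_z_pop[i]
                         + u[i] + rng.normal(0, sd))
                rows.append({
                    "id": f"acc_{idn}", "population": pop, "treatment": treatment,
                    "season": "breeding" if pop != "aikeni" else "nonbreeding",
                    "mass_pre": mass, "mass_post": mass + rng.normal(0, 0.3),
                    "msum_pre": msum_pre, "msum_post": msum_pre + delta,
                    "t_range": a.t_range[pop],
                })
                idn += 1
    records = pd.DataFrame(rows)
    truth = {"interaction": a.interaction_effect, "treatment": a.treatment_effect,
             "mass_effect": a.mass_effect, "intercept": a.intercept,
             "resid_sd_slope": a.resid_sd_slope, "t_range_z": dict(zip(pops, tr_z_pop))}
    return records, fst, truth
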