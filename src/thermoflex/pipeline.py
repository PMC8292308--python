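"""Configuration-driven orchestration of all analysis stages.

A single YAML config (or :class:`RunConfig`) drives: synthetic input
generation, M_sum extraction, field model selection, the
genotype-environment association, distance/Mantel tests, and the
acclimation mixed model.  Every stage writes CSV/JSON outputs into the
run directory and a manifest records seeds, thresholds, and output
checksums, so an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acclimation as acc
from . import distances as dist
from . import envwindows, field_models, popgen, respirometry, synthetic

logger = logging.getLogger("thermoflex")

STAGES = ("simulate", "msum", "field", "gea", "mantel", "acclim")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "thermoflex_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    n_traces: int = 20
    window_s: float = 300.0
    drift_max: float = respirometry.DEFAULT_DRIFT_MAX
    flow_cv_max: float = respirometry.DEFAULT_FLOW_CV_MAX
    windows: tuple[int, int] = (7, 14)
    min_mean_dp: float = 5.0
    max_mean_dp: float = 50.0
    mac: int = 3
    max_missing_frac: float = 0.5
    strict_missing_frac: float = 0.05
    hwe_p: float = 0.001
    r_max: float = 0.70
    vif_max: float = 5.0
    n_perm_model: int = 999
    n_perm_axes: int = 299
    mcmc_iter: int = 100_000
    mcmc_burn_in: int = 10_000
    mcmc_thin: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "windows" in raw:
            raw["windows"] = tuple(raw["windows"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the requested stages in dependency order; returns the run dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, v in asdict(cfg).items():
        logger.info("config %s = %r", k, v)
    sim = synthetic.SimConfig(seed=cfg.seed)
    manifest: dict = {"seed": cfg.seed, "config": asdict(cfg), "stages": {}}
    state: dict = {}

    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.time()
        _RUNNERS[stage](cfg, sim, out, state)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        logger.info("stage %s done in %.2fs", stage, time.time() - t0)

    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json"))
        if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def _stage_simulate(cfg, sim, out, state):
    traces = []
    rng = sim.rng("trace")
    for i in range(cfg.n_traces):
        tr, planted = synthetic.gen_resp_trace(sim, rng=rng)
        respirometry.write_trace(tr, out / f"trace_{i}.csv", out / f"trace_{i}.json")
        traces.append((tr, planted))
    state["traces"] = traces
    pheno, weather, bioclim, truth = synthetic.gen_field_dataset(sim)
    pheno.to_csv(out / "field_pheno.csv", index=False)
    weather.to_csv(out / "field_weather.csv", index=False)
    bioclim.to_csv(out / "field_bioclim.csv", index=False)
    state["field"] = (pheno, weather, bioclim, truth)
    gm, gtruth = synthetic.gen_genotypes(sim)
    popgen.write_vcf(gm, out / "genotypes.vcf")
    state["geno"] = (gm, gtruth)
    records, fst, atruth = synthetic.gen_acclimation_dataset(sim)
    records.to_csv(out / "acclim_records.csv", index=False)
    fst.to_csv(out / "acclim_fst_input.csv")
    state["acclim"] = (records, fst, atruth)


def _require(state, key, stage):
    if key not in state:
        raise RuntimeError(f"stage {stage!r} needs output of an earlier stage "
                           f"({key}); enable it or run 'simulate'")
    return state[key]


def _stage_msum(cfg, sim, out, state):
    traces = _require(state, "traces", "msum")
    rows = []
    for i, (tr, planted) in enumerate(traces):
        s = respirometry.process_trace(tr, cfg.window_s, cfg.drift_max, cfg.flow_cv_max)
        row = s.as_dict()
        row["trace"] = f"trace_{i}"
        row["planted_msum"] = planted
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "msum.csv", index=False)
    state["msum"] = rows


def _stage_field(cfg, sim, out, state):
    pheno, weather, bioclim, truth = _require(state, "field", "field")
    lo, hi = cfg.windows
    feats = envwindows.build_env_features(pheno, weather, bioclim,
                                          windows=range(lo, hi + 1))
    table, best, diag = field_models.select_model(pheno, feats,
                                                  windows=range(lo, hi + 1))
    table.to_csv(out / "field_model_ranks.csv", index=False)
    norms = field_models.reaction_norm_slopes(
        best, feats.merge(pheno[["id", "taxon"]], on="id"))
    pd.DataFrame({"slope": norms.slopes, "se": norms.slope_se,
                  "annual_range": norms.mean_annual_range}).to_csv(
        out / "reaction_norms.csv", index_label="taxon")
    het = field_models.flexibility_vs_heterogeneity(norms)
    (out / "field_summary.json").write_text(json.dumps(
        {"best_variable": best.variable, "best_window": best.window,
         "r2": best.r2, "aic": best.aic, "n": best.n,
         "heterogeneity_regression": het, **diag}, indent=1, default=float))
    state["norms"] = norms


def _stage_gea(cfg, sim, out, state):
    gm, gtruth = _require(state, "geno", "gea")
    filtered, report = popgen.filter_sites(
        gm, cfg.min_mean_dp, cfg.max_mean_dp, cfg.mac,
        cfg.max_missing_frac, strict_missing_frac=cfg.strict_missing_frac,
        hwe_p=cfg.hwe_p)
    report.as_frame().to_csv(out / "filter_report.csv", index=False)
    imputed = popgen.impute_major(filtered)
    scores, pct = popgen.pca_genotypes(imputed, n_axes=2)
    pd.DataFrame(scores, columns=["PC1", "PC2"],
                 index=imputed.individuals).to_csv(out / "pca_scores.csv")
    env = pd.DataFrame({"annual_temp_range": np.repeat(
        gtruth["env"], sim.geno.n_individuals)})
    env = env.loc[[gm.individuals.index(i) for i in imputed.individuals]].reset_index(drop=True)
    env["noise_var"] = sim.rng("geno").normal(size=len(env))
    clim = env.apply(envwindows.standardize_2sd)
    rda = popgen.partial_rda(imputed, clim, scores, check_vif=True, vif_max=cfg.vif_max)
    rda = popgen.permutation_anova(rda, cfg.n_perm_model, cfg.n_perm_axes,
                                   seed=np.random.default_rng([cfg.seed, 99]))
    vp = popgen.variance_partition(imputed, clim, scores)
    vp.to_csv(out / "variance_partition.csv", index=False)
    fst = popgen.weir_fst(imputed)
    fst.to_csv(out / "fst.csv")
    (out / "rda_summary.json").write_text(json.dumps({
        "adj_r2_constrained": rda.adj_r2_constrained,
        "adj_r2_conditional": rda.adj_r2_conditional,
        "pseudo_f": rda.pseudo_f, "p_model": rda.p_model,
        "p_axes": list(rda.p_axes) if rda.p_axes is not None else None,
        "pca_pct_var": list(pct)}, indent=1, default=float))
    state["fst"] = fst
    state["gea_env"] = gtruth["env"]


def _stage_mantel(cfg, sim, out, state):
    fst = _require(state, "fst", "mantel")
    pops = list(fst.index)
    rng = np.random.default_rng([cfg.seed, 7])
    sites = pd.DataFrame({"site": pops,
                          "lat": rng.uniform(32, 48, len(pops)),
                          "lon": rng.uniform(-124, -96, len(pops))})
    env = state["gea_env"]
    bio = pd.DataFrame({"site": pops, "bio7": np.asarray(env)[:len(pops)],
                        "bio1": rng.normal(10, 4, len(pops)),
                        "bio12": rng.normal(800, 150, len(pops))})
    gd = dist.linearize_fst(fst)
    geo = dist.geodesic_distance(sites)
    ed = dist.env_distance(bio)
    res = dist.partial_mantel(gd, ed, geo, n_perm=cfg.n_perm_model,
                              seed=np.random.default_rng([cfg.seed, 8]))
    (out / "mantel.json").write_text(json.dumps(res, indent=1))


def _stage_acclim(cfg, sim, out, state):
    records, fst, truth = _require(state, "acclim", "acclim")
    post = acc.fit_delta_model(
        records, fst, n_iter=cfg.mcmc_iter, burn_in=cfg.mcmc_burn_in,
        thin=cfg.mcmc_thin, seed=np.random.default_rng([cfg.seed, 11]))
    post.fixed.to_csv(out / "acclim_posterior.csv")
    cold = records[records["treatment"] == "cold"]
    cv = cold.groupby("population").apply(
        lambda d: acc.cv_percent(d["msum_post"] - d["msum_pre"]),
        include_groups=False)
    tr = records.groupby("population")["t_range"].first()
    reg = acc.cv_vs_trange(cv, tr)
    ctrl = records[records["treatment"] == "control"]
    tt = acc.paired_ttest(ctrl["msum_pre"], ctrl["msum_post"])
    (out / "acclim_summary.json").write_text(json.dumps(
        {"cv_regression": reg, "control_paired_t": tt,
         "cv": cv.to_dict()}, indent=1, default=float))


_RUNNERS = {
    "simulate": _stage_simulate,
    "msum": _stage_msum,
    "field": _stage_field,
    "gea": _stage_gea,
    "mantel": _stage_mantel,
    "acclim": _stage_acclim,
}
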