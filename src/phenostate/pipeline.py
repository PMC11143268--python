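"""Configuration, orchestration and serialization for full experiments.

A pipeline run is described by one YAML/JSON config (validated by
pydantic).  Every stochastic stage receives a child seed derived
deterministically from the global seed, so identical configs reproduce
identical outputs; a manifest records the package version, config hash,
per-stage seeds and output paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .clustering import (cluster_bimodality, fishing_net_clusters,
                         kmeans_env_clusters, permutation_importance)
from .demography import (VitalRateModelSet, predict_recruitment_ratio,
                         predict_survival_growth_contrast)
from .generator import GeneratorParams, generate_abundance_table, \
    generate_environment, generate_two_census_inventory
from .inventory import (DETERMINANT_NAMES, FilterCriteria, Phenology,
                        apply_inclusion_filters, compute_plot_summary,
                        write_inventory_csv)
from .nullmodel import fit_zap, null_relev_ensemble, spearman_coupling_test
from .simulate import (InitScheme, SimConfig, TrueRateAdapter,
                       hysteresis_experiment, run_simulation)

ALL_STAGES = ("generate", "filter", "null-model", "demography", "simulate",
              "hysteresis", "bimodality-map", "drivers")


class GeneratorBlock(BaseModel):
    n_plots: int = 3000
    stand_size_mean: float = 25.0
    plot_area_ha: float = 0.1
    interval_yr: float = 5.0
    target_survival_advantage_de: float = 14.0
    target_survival_advantage_ev: float = 17.0
    target_growth_advantage_ev: float = 43.0
    target_growth_advantage_de: float = 4.0
    target_recruitment_ratio: float = 5.0
    abundance_coupling: float = 0.0
    mat_effect: bool = False

    def params(self, seed: int) -> GeneratorParams:
        return GeneratorParams(seed=seed, **self.model_dump())


class FilterBlock(BaseModel):
    min_trees: int = 10
    max_unknown_ba_frac: float = Field(0.10, ge=0, le=1)
    max_mortality_frac: float = Field(0.50, ge=0, le=1)
    min_species: int = 2
    max_single_species_ba_frac: float = Field(0.90, ge=0, le=1)


class NullModelBlock(BaseModel):
    n_rep: int = 1000
    min_trees: int = 10
    spline_df: int = 5
    alpha: float = 1.0
    dip_n_null: int = 2000


class DemographyBlock(BaseModel):
    feedback: bool = True
    mat_term: bool = False
    alpha: float | str = "aic"
    relev_points_survival: tuple[float, float] = (0.0, 1.0)
    relev_points_recruitment: tuple[float, float] = (0.1, 0.9)


class SimulatorBlock(BaseModel):
    n_plots: int = 1000
    horizon_years: float = 2000.0
    step_years: float = 5.0
    p_disturb_annual: float = Field(0.0036, ge=0, le=1)
    init_scheme: str = "uniform"
    variant: str = "feedback"
    mat_sections: int = 12

    def config(self, seed: int) -> SimConfig:
        return SimConfig(
            n_plots=self.n_plots, horizon_years=self.horizon_years,
            step_years=self.step_years, p_disturb_annual=self.p_disturb_annual,
            init_scheme=InitScheme(self.init_scheme), variant=self.variant,
            mat_sections=self.mat_sections, seed=seed)


class BimodalityBlock(BaseModel):
    method: str = "fishing_net"     # or 'kmeans_env'
    cell_arcmin: float = 10.0
    k: int = 50
    min_plots: int = 10
    a: float = 6.0
    b: float = 2.0


class DriversBlock(BaseModel):
    n_boot: int = 100
    frac: float = Field(0.33, gt=0, le=1)
    response: str = "bi"            # 'bi' (per cluster) or 'relev' (per plot)


class PipelineConfig(BaseModel):
    stages: list[str] = list(ALL_STAGES)
    seed: int = 0
    output_dir: str = "phenostate_out"
    generator: GeneratorBlock = GeneratorBlock()
    filters: FilterBlock = FilterBlock()
    null_model: NullModelBlock = NullModelBlock()
    demography: DemographyBlock = DemographyBlock()
    simulator: SimulatorBlock = SimulatorBlock()
    bimodality: BimodalityBlock = BimodalityBlock()
    drivers: DriversBlock = DriversBlock()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except ValidationError as err:
            keys = ", ".join(".".join(str(p) for p in e["loc"]) for e in err.errors())
            raise ValueError(f"invalid pipeline config; offending keys: {keys}") from err


def _child_seeds(seed: int, n: int = 16) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the selected stages, writing CSV/JSON outputs plus a manifest."""
    unknown = [s for s in config.stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}; valid: {ALL_STAGES}")
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(ALL_STAGES, _child_seeds(config.seed, len(ALL_STAGES))))
    cfg_json = json.dumps(config.model_dump(), sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": {s: seeds[s] for s in config.stages},
        "skipped_stages": [s for s in ALL_STAGES if s not in config.stages],
        "outputs": {},
    }

    gen_params = config.generator.params(seeds["generate"])
    env_plots = generate_environment(gen_params)
    plots = None

    def record(stage: str, name: str, path: pathlib.Path):
        manifest["outputs"].setdefault(stage, []).append(str(path))

    if "generate" in config.stages:
        plots = generate_two_census_inventory(env_plots, gen_params)
        pp, tp = out / "plots.csv", out / "trees.csv"
        write_inventory_csv(plots, pp, tp)
        record("generate", "plots", pp)
        record("generate", "trees", tp)

    if "filter" in config.stages:
        if plots is None:
            plots = generate_two_census_inventory(env_plots, gen_params)
        fc = FilterCriteria(**config.filters.model_dump())
        plots, audit = apply_inclusion_filters(plots, fc)
        ap = out / "filter_audit.csv"
        audit.to_csv(ap, index=False)
        record("filter", "audit", ap)

    if "null-model" in config.stages:
        tab = generate_abundance_table(env_plots, gen_params)
        pcs = np.array([p.env_pcs for p in env_plots])
        nm = config.null_model
        m_ev = fit_zap(tab["ev_count"].to_numpy(), pcs, df=nm.spline_df, alpha=nm.alpha)
        m_de = fit_zap(tab["de_count"].to_numpy(), pcs, df=nm.spline_df, alpha=nm.alpha)
        rng = np.random.default_rng(seeds["null-model"])
        ens = null_relev_ensemble(m_ev, m_de, pcs, tab["ev_count"].to_numpy(),
                                  tab["de_count"].to_numpy(), n_rep=nm.n_rep,
                                  min_trees=nm.min_trees, rng=rng,
                                  dip_n_null=nm.dip_n_null)
        rho, null_rho, pval = spearman_coupling_test(
            tab["ev_count"].to_numpy(), tab["de_count"].to_numpy(),
            m_ev, m_de, pcs, n_rep=nm.n_rep, rng=rng)
        np_path = out / "null_model.json"
        with open(np_path, "w") as fh:
            json.dump({
                "bin_edges": ens.bin_edges.tolist(),
                "observed_freq": ens.observed_freq.tolist(),
                "null_q025": ens.null_q025.tolist(),
                "null_q975": ens.null_q975.tolist(),
                "outer_bin_exceeds": list(ens.outer_bin_exceeds),
                "observed_dip": ens.observed_dip,
                "observed_dip_pvalue": ens.observed_dip_pvalue,
                "spearman_obs": rho,
                "spearman_pvalue": pval,
                "n_replicates": ens.n_replicates,
                "seed": seeds["null-model"],
            }, fh, indent=2)
        pd.DataFrame({"null_rho": null_rho}).to_csv(out / "null_rho.csv", index=False)
        record("null-model", "summary", np_path)
        record("null-model", "null_rho", out / "null_rho.csv")

    model_set = None
    if "demography" in config.stages:
        if plots is None:
            plots = generate_two_census_inventory(env_plots, gen_params)
        dm = config.demography
        model_set = VitalRateModelSet.fit(plots, feedback=dm.feedback,
                                          mat_term=dm.mat_term, alpha=dm.alpha)
        rows = []
        if dm.feedback:
            rng = np.random.default_rng(seeds["demography"])
            for rate in ("survival", "growth"):
                models = getattr(model_set, rate)
                for c in predict_survival_growth_contrast(
                        models[Phenology.EV], models[Phenology.DE],
                        relev_points=dm.relev_points_survival, rng=rng):
                    rows.append(dataclasses.asdict(c))
            for c in predict_recruitment_ratio(
                    model_set.recruitment[Phenology.EV],
                    model_set.recruitment[Phenology.DE],
                    relev_points=dm.relev_points_recruitment, rng=rng):
                rows.append(dataclasses.asdict(c))
        cp = out / "contrasts.csv"
        df = pd.DataFrame(rows)
        if not df.empty:
            df["con_phenology"] = df["con_phenology"].map(lambda p: p.value)
        df.to_csv(cp, index=False)
        record("demography", "contrasts", cp)

    if "simulate" in config.stages:
        sim_cfg = config.simulator.config(seeds["simulate"])
        rates = TrueRateAdapter(gen_params, variant=sim_cfg.variant)
        res = run_simulation(sim_cfg, rates, ref_plots=env_plots)
        sp = out / "simulation_final_relev.csv"
        pd.DataFrame({"init_relev": res.init_relev,
                      "final_relev": res.final_relev}).to_csv(sp, index=False)
        record("simulate", "final_relev", sp)

    if "hysteresis" in config.stages:
        hp = dataclasses.replace(gen_params, mat_effect=True)
        sim_cfg = config.simulator.config(seeds["hysteresis"])
        rows = []
        for variant in ("feedback", "null"):
            cfg_v = dataclasses.replace(sim_cfg, variant=variant)
            hy = hysteresis_experiment(cfg_v, TrueRateAdapter(hp, variant=variant))
            for j in range(len(hy.mat_mid)):
                rows.append(dict(variant=variant, mat_mid=hy.mat_mid[j],
                                 mean_ev_init=hy.mean_ev_init[j],
                                 mean_de_init=hy.mean_de_init[j],
                                 gap=hy.gap[j], gap_ci_low=hy.gap_ci_low[j],
                                 gap_ci_high=hy.gap_ci_high[j]))
        hpth = out / "hysteresis.csv"
        pd.DataFrame(rows).to_csv(hpth, index=False)
        record("hysteresis", "gaps", hpth)

    if "bimodality-map" in config.stages or "drivers" in config.stages:
        if plots is None:
            plots = generate_two_census_inventory(env_plots, gen_params)
        bm = config.bimodality
        relev = np.array([
            np.nan if (s := compute_plot_summary(p)).relev_area is None
            else s.relev_area for p in plots])
        if bm.method == "kmeans_env":
            clusters = kmeans_env_clusters(plots, k=bm.k,
                                           seed=seeds["bimodality-map"],
                                           min_plots=bm.min_plots)
        else:
            clusters = fishing_net_clusters(plots, cell_arcmin=bm.cell_arcmin,
                                            min_plots=bm.min_plots)
        btab = cluster_bimodality(clusters, relev, a=bm.a, b=bm.b)
        if "bimodality-map" in config.stages:
            bp = out / "cluster_bimodality.csv"
            btab.to_csv(bp, index=False)
            record("bimodality-map", "clusters", bp)
        if "drivers" in config.stages:
            dr = config.drivers
            if dr.response == "bi":
                feats = []
                for cid in btab["cluster_id"]:
                    idx = clusters.assignments[cid]
                    feats.append({k: np.mean([plots[i].determinants[k] for i in idx])
                                  for k in DETERMINANT_NAMES})
                features = pd.DataFrame(feats)
                response = btab["bi"].to_numpy()
            else:
                ok = np.isfinite(relev)
                features = pd.DataFrame([plots[i].determinants
                                         for i in np.flatnonzero(ok)])
                response = relev[ok]
            imp = permutation_importance(features, response, n_boot=dr.n_boot,
                                         frac=dr.frac, seed=seeds["drivers"])
            ip = out / "determinant_importance.csv"
            imp.to_csv(ip, index=False)
            record("drivers", "importance", ip)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
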