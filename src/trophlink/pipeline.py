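"""End-to-end orchestration: synth/load -> validate -> diet -> isotopes ->
trophic position -> mixing -> habitat, with a single seeded manifest.

Each stage derives its own substream from the global seed, so stage-level
reruns reproduce in isolation and adding a stage never perturbs another.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import data_io, gut_content, isotope_prep, synthetic_data, vertical_habitat
from ._samplers import MCMCSettings
from .mixing_model import (
    MixingModelSpec,
    build_mixing_model,
    fit_mixing,
    summarize_contributions,
)
from .trophic_position import TDFSpec, TPModelSpec, fit_tp

logger = logging.getLogger("trophlink")

MIXING_PREY_DEFAULT = (
    "Euphausia gibboides",
    "Diaphus brachycephalus",
    "Diaphus fragilis",
    "Diaphus mollis",
    "Hygophum taaningi",
    "Lampanyctus nobilis",
    "Lepidophanes guentheri",
    "Symbolophorus rufinus",
    "Promethichthys prometheus",
)

_STAGE_SEEDS = {"synth": 11, "tp": 13, "mixing": 17}


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(_STAGE_SEEDS[stage],))
               .generate_state(1)[0] % (2 ** 31))


class MCMCConfig(BaseModel):
    chains: int = 4
    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 1

    def settings(self, seed: int) -> MCMCSettings:
        return MCMCSettings(chains=self.chains, iterations=self.iterations,
                            burn_in=self.burn_in, thin=self.thin, seed=seed)


class RunConfig(BaseModel):
    """Config for a full pipeline run (synthetic survey or CSV inputs)."""

    seed: int = 0
    input_paths: Optional[dict[str, str]] = None  # None -> synthetic survey
    l50_cm: float = 15.0
    n_stomachs: int = 197
    vacuity: float = synthetic_data.DEFAULT_VACUITY
    tdf_n_mean: float = 3.15
    tdf_n_sd: float = 1.28
    tdf_c_mean: float = 0.0
    tdf_c_sd: float = 1.0
    baseline_taxon: str = "Zooplankton"
    mixing_prey: tuple[str, ...] = MIXING_PREY_DEFAULT
    mcmc: MCMCConfig = Field(default_factory=MCMCConfig)
    outdir: Optional[str] = None


class ConfigError(ValueError):
    pass


@dataclass
class ResultsBundle:
    dataset: data_io.Dataset
    validation: data_io.ValidationReport
    diet_tables: dict
    diet_frame: pd.DataFrame
    source_summaries: pd.DataFrame
    biplot: pd.DataFrame
    tp_posteriors: dict
    mixing_summary: pd.DataFrame
    cpue_table: pd.DataFrame
    size_table: pd.DataFrame
    envelope: Optional[vertical_habitat.HabitatEnvelope]
    manifest: dict = field(default_factory=dict)


def _preflight(cfg: RunConfig) -> None:
    if cfg.tdf_n_mean <= 0:
        raise ConfigError("tdf_n_mean must be > 0 (nitrogen TDF drives TP)")
    if cfg.tdf_n_sd < 0 or cfg.tdf_c_sd < 0:
        raise ConfigError("TDF sds must be >= 0")
    if not (0 <= cfg.vacuity <= 1):
        raise ConfigError("vacuity must lie in [0, 1]")


def run_all(cfg: RunConfig) -> ResultsBundle:
    """Execute every stage in dependency order; stage failures halt with a
    stage-named error."""
    _preflight(cfg)
    t0 = time.perf_counter()

    def stage(name: str):
        logger.info("stage %-10s t=%.1fs", name, time.perf_counter() - t0)

    stage("data")
    if cfg.input_paths is None:
        ds = synthetic_data.make_survey(
            _stage_seed(cfg.seed, "synth"), n_stomachs=cfg.n_stomachs,
            vacuity=cfg.vacuity)
    else:
        ds = data_io.load_dataset(cfg.input_paths)

    stage("validate")
    report = data_io.validate(ds)
    if report.errors():
        first = report.errors()[0]
        raise RuntimeError(f"stage validate: {first.table}/{first.record_id}: "
                           f"{first.message}")

    stage("habitat")
    vertical_habitat.label_trawls(ds)
    cpue_table = vertical_habitat.stratify(ds)
    size_table = vertical_habitat.size_by_depth(ds)
    envelope = None
    occupied = vertical_habitat.occupied_intervals(cpue_table)
    if occupied and ds.ctd:
        envelope = vertical_habitat.habitat_envelope(occupied, ds.ctd)

    stage("diet")
    trawls = ds.trawl_by_id()
    diel_by_spec = {s.specimen_id: trawls[s.trawl_id].diel_period
                    for s in ds.specimens if s.trawl_id in trawls}
    if ds.stomachs:
        tables = gut_content.diet_table(ds.stomachs, ds.specimens,
                                        diel_by_specimen=diel_by_spec,
                                        l50_cm=cfg.l50_cm)
        diet_frame = gut_content.diet_table_frame(tables)
    else:
        tables, diet_frame = {}, pd.DataFrame()

    stage("isotopes")
    summaries = isotope_prep.summarize_sources(ds.isotopes)
    summaries_df = isotope_prep.summaries_frame(summaries)
    biplot = isotope_prep.biplot_table(ds)
    by_group: dict[str, list[float]] = {}
    for s in ds.isotopes:
        by_group.setdefault(s.group, [])
    corrected = [isotope_prep.lipid_screen_and_correct(s) for s in ds.isotopes]

    stage("tp")
    tdf_n = TDFSpec(cfg.tdf_n_mean, cfg.tdf_n_sd)
    baseline = [s.d15N for s in corrected if s.taxon == cfg.baseline_taxon]
    tp_posteriors = {}
    consumer_sets = {
        "small": [s.d15N for s in corrected if s.group == "consumer-small"],
        "large": [s.d15N for s in corrected if s.group == "consumer-large"],
    }
    consumer_sets["pooled"] = consumer_sets["small"] + consumer_sets["large"]
    if baseline:
        for name, obs in consumer_sets.items():
            if not obs:
                continue
            spec = TPModelSpec(consumer_d15N=obs, baseline_d15N=baseline, tdf=tdf_n)
            tp_posteriors[name] = fit_tp(
                spec, cfg.mcmc.settings(_stage_seed(cfg.seed, "tp")))

    stage("mixing")
    mixing_summary = pd.DataFrame()
    prey = [s for s in summaries if s.taxon in cfg.mixing_prey]
    consumer_obs = np.array([[s.d13C, s.d15N] for s in corrected
                             if s.group in ("consumer-small", "consumer-large")])
    if prey and len(consumer_obs):
        spec_m = MixingModelSpec(
            sources=prey, consumer_obs=consumer_obs,
            tdf_C=TDFSpec(cfg.tdf_c_mean, cfg.tdf_c_sd), tdf_N=tdf_n,
            sd_floor=0.1)
        post = fit_mixing(build_mixing_model(spec_m),
                          cfg.mcmc.settings(_stage_seed(cfg.seed, "mixing")))
        mixing_summary = summarize_contributions(post)

    manifest = {
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            cfg.model_dump_json().encode()).hexdigest(),
        "stage_seeds": {k: _stage_seed(cfg.seed, k) for k in _STAGE_SEEDS},
        "n_records": {
            "stations": len(ds.stations), "trawls": len(ds.trawls),
            "specimens": len(ds.specimens), "stomachs": len(ds.stomachs),
            "isotopes": len(ds.isotopes), "ctd": len(ds.ctd)},
    }
    bundle = ResultsBundle(
        dataset=ds, validation=report, diet_tables=tables,
        diet_frame=diet_frame, source_summaries=summaries_df, biplot=biplot,
        tp_posteriors=tp_posteriors, mixing_summary=mixing_summary,
        cpue_table=cpue_table, size_table=size_table, envelope=envelope,
        manifest=manifest)
    if cfg.outdir:
        write_bundle(bundle, cfg.outdir, cfg)
    return bundle


def write_bundle(bundle: ResultsBundle, outdir: str | Path,
                 cfg: Optional[RunConfig] = None) -> dict:
    tables: dict[str, pd.DataFrame] = {
        "diet_table": bundle.diet_frame,
        "source_summaries": bundle.source_summaries,
        "biplot_table": bundle.biplot,
        "cpue_table": bundle.cpue_table,
        "size_by_depth": bundle.size_table,
        "mixing_contributions": bundle.mixing_summary,
    }
    if bundle.tp_posteriors:
        tables["tp_summary"] = pd.DataFrame([
            {"group": g, "mean": p.mean, "sd": p.sd,
             "ci2.5": p.ci95[0], "ci97.5": p.ci95[1],
             "rhat": p.rhat, "ess": p.ess, "converged": p.converged}
            for g, p in bundle.tp_posteriors.items()])
    manifest = data_io.write_results(
        {k: v for k, v in tables.items() if len(v)},
        outdir, config=cfg.model_dump() if cfg else None,
        seed=bundle.manifest.get("seed"))
    if bundle.envelope is not None:
        (Path(outdir) / "envelope.json").write_text(
            json.dumps(bundle.envelope.__dict__, indent=2) + "\n")
    return manifest


def report(bundle: ResultsBundle) -> str:
    """Render the bundle as a human-readable markdown summary (pure)."""
    lines = ["# Survey analysis report", ""]

    lines.append("## Diet composition")
    if bundle.diet_frame is None or bundle.diet_frame.empty:
        lines.append("_not run (no stomach data)_")
    else:
        for group, t in bundle.diet_tables.items():
            if t.is_empty:
                continue
            vi = round(t.VI_pooled) if t.VI_pooled is not None else "-"
            bj = f"{t.Bj:.2f}" if t.Bj is not None else "-"
            lines.append(f"- **{group}**: Ne={t.summary.Ne}, NSC={t.summary.NSC}, "
                         f"VI={vi}%, Bj={bj}")
        lines.append("")
        lines.append(bundle.diet_frame.to_string(index=False))

    lines.append("")
    lines.append("## Isotope sources")
    if bundle.source_summaries.empty:
        lines.append("_not run (no isotope data)_")
    else:
        lines.append(bundle.source_summaries.round(2).to_string(index=False))

    lines.append("")
    lines.append("## Trophic position")
    if not bundle.tp_posteriors:
        lines.append("_not run_")
    for g, p in bundle.tp_posteriors.items():
        flag = "" if p.converged else "  [non-converged]"
        lines.append(f"- {g}: TP = {p.mean:.2f} +/- {p.sd:.2f} "
                     f"(95% CI {p.ci95[0]:.2f}-{p.ci95[1]:.2f}){flag}")

    lines.append("")
    lines.append("## Prey contributions (mixing model)")
    if bundle.mixing_summary.empty:
        lines.append("_not run_")
    else:
        lines.append(bundle.mixing_summary.round(1).to_string(index=False))

    lines.append("")
    lines.append("## CPUE by depth stratum")
    sampled = bundle.cpue_table[bundle.cpue_table["n_trawls"] > 0]
    lines.append(sampled.round(2).to_string(index=False)
                 if len(sampled) else "_no labeled trawls_")
    if bundle.envelope is not None:
        e = bundle.envelope
        lines.append("")
        lines.append(f"Habitat envelope over {e.depth_min:.0f}-{e.depth_max:.0f} m: "
                     f"T {e.temp_min:.1f}-{e.temp_max:.1f} degC, "
                     f"O2 {e.oxy_min:.1f}-{e.oxy_max:.1f} ml/l")
    return "\n".join(lines) + "\n"
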