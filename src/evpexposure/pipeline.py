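"""End-to-end run: generate → estimate → simulate scenarios → intake tables.

Outputs (all CSV/JSON, deterministic for a fixed seed):

* ``sessions.csv`` — the synthetic crossover dataset;
* ``table2_like.csv`` — per-product sham-corrected LS means with CIs;
* ``table3_like.csv`` — emission factors next to cigarette sidestream inputs;
* ``table4_like.csv`` — non-user intakes per constituent × scenario × source
  kind with limit-reference intakes and statuses;
* ``concentrations.csv`` — scenario average concentrations;
* ``trajectory_<scenario>.csv`` — full box-model time series (EVP source);
* ``manifest.json`` — seed, package/dependency versions, file list.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .breath_stats import STATUS_BELOW_MDL, estimate_emission_factors, fit_sham_ancova
from .exposure import (
    BreathingModel,
    ConstituentSpec,
    Scenario,
    UsageModel,
    fold_difference,
    run_scenario,
)
from .airmodel import SourceProfile, simulate_box
from .exposure import source_rate as _source_rate
from .io import (
    default_design,
    default_generation_params,
    default_registry,
    default_scenarios,
    design_from_dict,
    generation_params_from_dict,
    load_yaml,
    registry_from_dict,
    scenario_from_dict,
    write_intake_table,
    write_sessions,
)
from .synthetic_study import generate_study

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("evpexposure")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and knobs for one end-to-end run; None falls back to packaged defaults."""

    out_dir: Path
    seed: int = 0
    design_path: Path | None = None
    generation_path: Path | None = None
    registry_path: Path | None = None
    scenario_paths: tuple[Path, ...] | None = None
    reference_product: str = "tp3"
    log_level: str = "INFO"


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                log.info("stage %s", name)
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("generate")
def _generate(config: PipelineConfig) -> pd.DataFrame:
    design = (
        default_design()
        if config.design_path is None
        else design_from_dict(load_yaml(config.design_path))
    )
    params = (
        default_generation_params(seed=config.seed)
        if config.generation_path is None
        else generation_params_from_dict(load_yaml(config.generation_path), seed=config.seed)
    )
    return generate_study(design, params)


@_stage("estimate")
def _estimate(sessions: pd.DataFrame, config: PipelineConfig):
    factors = estimate_emission_factors(sessions, product=config.reference_product)
    table2_rows = []
    for analyte in sessions["analyte"].unique():
        sub = sessions.loc[sessions["analyte"] == analyte]
        if bool((sub["censored_product"] & sub["censored_sham"]).all()):
            continue  # no information beyond the MDL
        for r in fit_sham_ancova(sessions, analyte):
            table2_rows.append(dataclasses.asdict(r))
    return factors, pd.DataFrame(table2_rows)


@_stage("scenarios")
def _scenarios(
    factors: pd.DataFrame, config: PipelineConfig
) -> tuple[list[Scenario], list[ConstituentSpec]]:
    registry = (
        default_registry()
        if config.registry_path is None
        else registry_from_dict(load_yaml(config.registry_path))
    )
    if config.scenario_paths is None:
        scenarios = default_scenarios()
    else:
        scenarios = [scenario_from_dict(load_yaml(p)) for p in config.scenario_paths]
    est = factors.set_index("analyte")
    merged = []
    for spec in registry:
        if spec.name in est.index:
            row = est.loc[spec.name]
            below = row["status"] == STATUS_BELOW_MDL
            merged.append(
                dataclasses.replace(
                    spec,
                    emission_factor=0.0 if below else float(row["emission_factor_full"]),
                    below_mdl=below,
                )
            )
        else:
            merged.append(spec)
    return scenarios, merged


@_stage("intake")
def _intake(
    scenarios: list[Scenario],
    constituents: list[ConstituentSpec],
    out_dir: Path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    usage, breathing = UsageModel(), BreathingModel()
    rows = []
    for scenario in scenarios:
        per_kind = {}
        for kind in ("evp", "cigarette"):
            sc = dataclasses.replace(scenario, source_kind=kind)
            per_kind[kind] = {r.constituent: r for r in run_scenario(sc, constituents, usage, breathing)}
        for spec in constituents:
            evp, cig = per_kind["evp"][spec.name], per_kind["cigarette"][spec.name]
            fold = (
                float("nan")
                if cig.status == "NA"
                else fold_difference(cig.intake, evp.intake)
            )
            rows.append(
                {
                    "constituent": spec.name,
                    "scenario": scenario.name,
                    "duration_h": scenario.duration,
                    "intake_cigarette_ug": cig.intake,
                    "cigarette_status": cig.status,
                    "intake_evp_ug": evp.intake,
                    "evp_status": evp.status,
                    "limit_reference_intake_ug": (
                        float("nan")
                        if evp.limit_reference_intake is None
                        else evp.limit_reference_intake
                    ),
                    "fold_difference": fold,
                    "avg_conc_evp_ug_m3": evp.average_concentration,
                    "avg_conc_cigarette_ug_m3": cig.average_concentration,
                }
            )
        # full EVP trajectories for the record
        traj_rows = []
        for spec in constituents:
            if spec.below_mdl:
                continue
            sc = dataclasses.replace(scenario, source_kind="evp")
            rate = _source_rate(spec, sc, usage)
            state = simulate_box(
                sc.volume, sc.ach, SourceProfile.continuous(rate), sc.duration,
                saturation_mass_concentration=spec.saturation_mass_concentration,
            )
            traj_rows.append(
                pd.DataFrame(
                    {
                        "time_h": state.time,
                        "constituent": spec.name,
                        "total_ug_m3": state.total,
                        "vapor_ug_m3": state.vapor,
                        "particle_ug_m3": state.particle,
                    }
                )
            )
        pd.concat(traj_rows, ignore_index=True).to_csv(
            out_dir / f"trajectory_{scenario.name}.csv", index=False
        )
    table4 = pd.DataFrame(rows)
    conc = table4[
        ["constituent", "scenario", "duration_h", "avg_conc_evp_ug_m3", "avg_conc_cigarette_ug_m3"]
    ].copy()
    return table4, conc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write the report bundle to ``out_dir``.

    Returns the manifest dict.  Any stage failure raises
    :class:`PipelineError` naming the stage; outputs written by earlier
    stages are left in place.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sessions = _generate(config)
    write_sessions(sessions, out_dir / "sessions.csv")

    factors, table2 = _estimate(sessions, config)
    table2.to_csv(out_dir / "table2_like.csv", index=False)
    factors.to_csv(out_dir / "factors.csv", index=False)

    scenarios, constituents = _scenarios(factors, config)
    table3 = pd.DataFrame(
        {
            "constituent": [c.name for c in constituents],
            "sidestream_ug_per_cigarette": [
                "NA" if c.sidestream_emission is None else c.sidestream_emission
                for c in constituents
            ],
            "emission_factor_ug_per_mg": [c.emission_factor for c in constituents],
            "status": [
                STATUS_BELOW_MDL if c.below_mdl else "COMPUTED" for c in constituents
            ],
        }
    )
    table3.to_csv(out_dir / "table3_like.csv", index=False)

    table4, conc = _intake(scenarios, constituents, out_dir)
    write_intake_table(table4, out_dir / "table4_like.csv")
    conc.to_csv(out_dir / "concentrations.csv", index=False)

    manifest = {
        "seed": config.seed,
        "package": {"evpexposure": __version__},
        "dependencies": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "reference_product": config.reference_product,
        "outputs": sorted(p.name for p in out_dir.glob("*.csv")),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
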