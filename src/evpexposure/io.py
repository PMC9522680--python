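"""Configuration loading/validation and the shared CSV dialect.

One flat CSV dialect everywhere: comma-separated, UTF-8, header row, "."
decimal, units embedded in column names.  Missing/inapplicable quantities
are written as explicit string sentinels ("NA", "BELOW_MDL"), never empty
cells, so reference-table semantics survive a round trip.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .exposure import ConstituentSpec, Scenario
from .synthetic_study import (
    COLLECTION_OF,
    SESSION_COLUMNS,
    GenerationParams,
    Product,
    StudyDesign,
)

__all__ = [
    "load_yaml",
    "design_from_dict",
    "generation_params_from_dict",
    "scenario_from_dict",
    "registry_from_dict",
    "default_design",
    "default_generation_params",
    "default_registry",
    "default_scenarios",
    "write_sessions",
    "read_sessions",
    "write_intake_table",
    "read_intake_table",
]

DEFAULT_SCENARIO_NAMES = ("car_closed", "car_open", "meeting_room", "restaurant")


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return out


def _packaged(name: str) -> dict:
    with resources.files("evpexposure.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def design_from_dict(d: dict) -> StudyDesign:
    products = tuple(
        Product(p["id"], float(p["nicotine_by_weight"]), bool(p.get("mentholated", False)))
        for p in d["products"]
    )
    collections = {str(k): int(v) for k, v in d["collections"].items()}
    for analyte in collections:
        if analyte not in COLLECTION_OF:
            raise ValueError(f"unknown analyte {analyte!r} in design collections")
    return StudyDesign(
        n_subjects=int(d["n_subjects"]),
        sequences=tuple(d["sequences"]),
        subjects_per_sequence=int(d["subjects_per_sequence"]),
        products=products,
        collections=collections,
    )


def generation_params_from_dict(d: dict, seed: int | None = None) -> GenerationParams:
    true_mean = {
        (analyte, pid): float(v)
        for analyte, per_prod in d["true_mean_ug"].items()
        for pid, v in per_prod.items()
    }
    for analyte in d["true_mean_ug"]:
        if analyte not in COLLECTION_OF:
            raise ValueError(f"unknown analyte {analyte!r} in true_mean_ug")
    consumption = {}
    for pid, colls in d["consumption_mg"].items():
        for key, (mean, sd) in colls.items():
            coll = int(key.removeprefix("collection"))
            consumption[pid, coll] = (float(mean), float(sd))
    return GenerationParams(
        true_mean=true_mean,
        cv_between=float(d["cv_between"]),
        cv_within=float(d["cv_within"]),
        sham_mean={k: float(v) for k, v in d["sham_mean_ug"].items()},
        mdl={k: float(v) for k, v in d["mdl_ug"].items()},
        consumption=consumption,
        seed=int(d.get("seed", 0) if seed is None else seed),
    )


def scenario_from_dict(d: dict, source_kind: str = "evp") -> Scenario:
    return Scenario(
        name=str(d["name"]),
        volume=float(d["volume_m3"]),
        ach=float(d["ach_per_h"]),
        duration=float(d["duration_h"]),
        n_users=int(d["n_users"]),
        n_occupants=int(d["n_occupants"]),
        source_kind=source_kind,
    )


def registry_from_dict(d: dict) -> list[ConstituentSpec]:
    specs = []
    for c in d["constituents"]:
        name = str(c["name"])
        if name not in COLLECTION_OF:
            raise ValueError(f"unknown analyte {name!r} in constituent registry")
        specs.append(
            ConstituentSpec(
                name=name,
                emission_factor=float(c["emission_factor_ug_per_mg"]),
                sidestream_emission=(
                    None
                    if c.get("sidestream_ug_per_cigarette") is None
                    else float(c["sidestream_ug_per_cigarette"])
                ),
                saturation_mass_concentration=(
                    None if c.get("saturation_ug_m3") is None else float(c["saturation_ug_m3"])
                ),
                exposure_limit=(
                    None
                    if c.get("exposure_limit_ug_m3") is None
                    else float(c["exposure_limit_ug_m3"])
                ),
                below_mdl=bool(c.get("below_mdl", False)),
            )
        )
    return specs


def default_design() -> StudyDesign:
    return design_from_dict(_packaged("design.yaml"))


def default_generation_params(seed: int | None = None) -> GenerationParams:
    return generation_params_from_dict(_packaged("generation.yaml"), seed=seed)


def default_registry() -> list[ConstituentSpec]:
    return registry_from_dict(_packaged("registry.yaml"))


def default_scenarios(source_kind: str = "evp") -> list[Scenario]:
    return [
        scenario_from_dict(_packaged(f"{name}.yaml"), source_kind=source_kind)
        for name in DEFAULT_SCENARIO_NAMES
    ]


# ---------------------------------------------------------------------------
# CSV dialect


def write_sessions(sessions: pd.DataFrame, path) -> None:
    sessions.loc[:, SESSION_COLUMNS].to_csv(path, index=False)


def read_sessions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sessions file {path} lacks columns {sorted(missing)}")
    return df[SESSION_COLUMNS]


_SENTINELS = ("NA", "BELOW_MDL")


def write_intake_table(table: pd.DataFrame, path) -> None:
    """Write an intake table, encoding NaN quantities by their row status."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f" and "status" in out.columns:
            out[col] = [
                (status if pd.isna(v) and status in _SENTINELS else v)
                for v, status in zip(out[col], out["status"])
            ]
    out.to_csv(path, index=False)


def read_intake_table(path) -> pd.DataFrame:
    # keep the "NA" sentinel as a string; only truly empty cells are missing
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    for col in df.columns:
        if df[col].dtype == object and col != "status":
            cleaned = df[col].mask(df[col].isin(_SENTINELS))
            numeric = pd.to_numeric(cleaned, errors="coerce")
            if numeric.notna().sum() == cleaned.notna().sum():
                df[col] = numeric  # sentinel-only gaps become NaN
    return df
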