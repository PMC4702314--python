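"""Run configuration, validation, provenance, and record-table I/O.

The canonical record store is a tidy CSV with a JSON sidecar carrying the
configuration hash and master seed; every output can thus be traced to the
exact settings that produced it. Unknown configuration keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .program import FACTOR_LEVELS, Scenario, SimSettings

__all__ = ["RunConfig", "ConfigError", "load_config", "write_records", "read_records"]

_RECORD_KEY = ["scenario_id", "replicate"]


class ConfigError(ValueError):
    pass


class FactorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    approach: list[Literal["Landrace", "LandraceDH", "LandraceElite"]] = Field(
        default_factory=lambda: list(FACTOR_LEVELS["approach"])
    )
    Ne: list[int] = Field(default_factory=lambda: list(FACTOR_LEVELS["Ne"]))
    F: list[float] = Field(default_factory=lambda: list(FACTOR_LEVELS["F"]))
    h2: list[float] = Field(default_factory=lambda: list(FACTOR_LEVELS["h2"]))
    platform: list[Literal["GBS10x@10K", "GBS1x@100K"]] = Field(
        default_factory=lambda: list(FACTOR_LEVELS["platform"])
    )
    seeds_per_landrace: list[int] = Field(
        default_factory=lambda: list(FACTOR_LEVELS["seeds_per_landrace"])
    )
    n_selected_landraces: list[int] = Field(
        default_factory=lambda: list(FACTOR_LEVELS["n_selected_landraces"])
    )
    tested_seeds_per_landrace: list[int] = Field(
        default_factory=lambda: list(FACTOR_LEVELS["tested_seeds_per_landrace"])
    )
    n_synthetic_phenotypes: list[int] = Field(
        default_factory=lambda: list(FACTOR_LEVELS["n_synthetic_phenotypes"])
    )


class SettingsConfig(BaseModel):
    """Mirrors :class:`prebreedsim.program.SimSettings`."""

    model_config = ConfigDict(extra="forbid")

    n_accessions: int = 3000
    pool_size: int = 50
    n_founder_haplotypes: int = 4
    max_landrace_generations: int = 20
    panel_haplotypes: int = 1000
    n_qtl: int = 1000
    n_chromosomes: int = 10
    chrom_length_cm: float = 200.0
    maf_min: float = 0.05
    mutation_rate: float | None = None
    loci_per_chromosome: int | None = None
    platform_markers: dict[str, int] | None = None
    gbs_error_rate: float = 0.005
    dh_candidates: int = 10
    elite_subpop_size: int = 50
    elite_generations: int = 5
    elite_top_fraction: float = 0.1
    elite_gap_sd: float | None = 16.8
    kinship_mode: Literal["ibd", "ibs"] = "ibd"
    segment_cm: float = 1.0
    n_final_selected: int = 10
    n_cycles: int = 4
    synthetic_seeds_per_plant: int = 10


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    factors: FactorConfig = Field(default_factory=FactorConfig)
    settings: SettingsConfig = Field(default_factory=SettingsConfig)
    replicates: int = 10
    scale: float = 1.0
    master_seed: int = 1
    out: str = "records.csv"

    def sim_settings(self) -> SimSettings:
        """Scaled study conditions; explicitly configured settings win over
        the scale-derived defaults."""
        overrides = self.settings.model_dump(exclude_unset=True)
        if overrides.get("platform_markers") is not None:
            overrides["platform_markers"] = tuple(
                sorted(overrides["platform_markers"].items())
            )
        else:
            overrides.pop("platform_markers", None)
        return SimSettings.at_scale(self.scale, **overrides)

    def scenarios(self) -> list[Scenario]:
        import itertools

        keys = list(FACTOR_LEVELS)
        levels = self.factors.model_dump()
        return [
            Scenario(**dict(zip(keys, combo)))
            for combo in itertools.product(*(levels[k] for k in keys))
        ]

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    An empty file yields all defaults; unknown keys fail with the offending
    key names; non-factorial values (e.g. Ne=5) are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config does not parse as YAML/JSON: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        offenders = [
            ".".join(str(loc) for loc in err["loc"]) or "<root>"
            for err in exc.errors()
        ]
        raise ConfigError(
            f"invalid configuration keys/values: {', '.join(offenders)}"
        ) from exc


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_records(
    records: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    master_seed: int | None = None,
    append: bool = False,
) -> pd.DataFrame:
    """Write the stage-record table as CSV with a provenance sidecar.

    ``append=True`` resumes a partial grid: rows whose (scenario_id,
    replicate) already exist in the file are dropped from the new batch.
    """
    path = Path(path)
    df = records
    if append and path.exists():
        old = read_records(path)
        existing = set(map(tuple, old[_RECORD_KEY].drop_duplicates().to_numpy()))
        fresh = ~records[_RECORD_KEY].apply(tuple, axis=1).isin(existing)
        df = pd.concat([old, records[fresh]], ignore_index=True)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    meta = {
        "master_seed": master_seed,
        "config_hash": config.config_hash() if config is not None else None,
        "n_rows": len(df),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return df


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a record CSV; empty metric fields come back as NaN (missing)."""
    return pd.read_csv(path)
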