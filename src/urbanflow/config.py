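"""Simulation configuration: loading, validation, defaults, hashing.

A config is a YAML (or JSON) document with sections ``grid``,
``land_uses``, ``theta``, ``agents``, ``iac``, ``schedule`` and ``run``.
Every field has a default mirroring the model's standard setup (100x100
grid of 25 m cells, the six-land-use quota table, d = 0.95, g = 1.02,
10,000 agents, 28-day runs), so an empty document is a valid config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .engine import DEFAULT_DEPARTURE_HOURS, IacParams, Schedule
from .environment import (
    DEFAULT_QUOTAS,
    EnvironmentGrid,
    LandUse,
    LandUseQuota,
    SizeDistribution,
    generate_environment,
    quotas_from_percent,
)
from .exceptions import ConfigurationError
from .population import (
    DEFAULT_EMPLOYMENT,
    DEFAULT_MIX,
    DEFAULT_SPECIAL_WORKPLACE_PROB,
    FAVORED_COUNT,
    AgentType,
    ProbabilityTable,
    generate_agents,
)


@dataclass
class GridConfig:
    rows: int = 100
    cols: int = 100
    cell_size_m: float = 25.0


@dataclass
class ThetaConfig:
    mean: float = 1.0
    sd: float = 0.05
    floor: float = 0.05


@dataclass
class AgentsConfig:
    n: int = 10000
    mix: dict = field(default_factory=lambda: {t.name.lower(): p for t, p in DEFAULT_MIX.items()})
    employment: dict = field(
        default_factory=lambda: {t.name.lower(): p for t, p in DEFAULT_EMPLOYMENT.items()}
    )
    favored_count: int = FAVORED_COUNT
    special_workplace_prob: float = DEFAULT_SPECIAL_WORKPLACE_PROB


@dataclass
class IacConfig:
    d: float = 0.95
    g: float = 1.02
    top_k: int = 10
    mood_sd: float | None = None  # None: take the probability table's value
    mood_floor: float = 0.5
    favored_boost: float | None = None  # None: take the table's value
    distance_scale: float = 1.0


@dataclass
class ScheduleConfig:
    departure_hours: dict = field(
        default_factory=lambda: {t.name.lower(): h for t, h in DEFAULT_DEPARTURE_HOURS.items()}
    )


@dataclass
class RunConfig:
    days: int = 28
    n_runs: int = 20
    master_seed: int = 0


def _default_land_uses() -> list[dict]:
    out = []
    for q in DEFAULT_QUOTAS:
        out.append(
            {
                "name": q.land_use.name.lower(),
                "cells": q.cells,
                "max_cluster": q.max_cluster,
                "size_distribution": {"kind": q.size_distribution.kind},
            }
        )
    return out


@dataclass
class SimulationConfig:
    """All tunables of one simulation study."""

    grid: GridConfig = field(default_factory=GridConfig)
    land_uses: list = field(default_factory=_default_land_uses)
    theta: ThetaConfig = field(default_factory=ThetaConfig)
    agents: AgentsConfig = field(default_factory=AgentsConfig)
    table_path: str | None = None  # None: packaged default table
    iac: IacConfig = field(default_factory=IacConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    run: RunConfig = field(default_factory=RunConfig)

    # -- construction ------------------------------------------------

    def quotas(self) -> list[LandUseQuota]:
        n_cells = self.grid.rows * self.grid.cols
        entries = [dict(e) for e in self.land_uses]
        if any("percent" in e for e in entries):
            percents, max_clusters, dists = {}, {}, {}
            for e in entries:
                lu = LandUse.from_name(e["name"])
                percents[lu] = float(e["percent"])
                max_clusters[lu] = int(e["max_cluster"])
                dists[lu] = _size_distribution(e.get("size_distribution"))
            return quotas_from_percent(percents, n_cells, max_clusters, dists)
        out = []
        for e in entries:
            out.append(
                LandUseQuota(
                    LandUse.from_name(e["name"]),
                    int(e["cells"]),
                    int(e["max_cluster"]),
                    _size_distribution(e.get("size_distribution")),
                )
            )
        return out

    def build_environment(self, rng: np.random.Generator) -> EnvironmentGrid:
        return generate_environment(
            quotas=self.quotas(),
            dims=(self.grid.rows, self.grid.cols),
            cell_size_m=self.grid.cell_size_m,
            theta_mean=self.theta.mean,
            theta_sd=self.theta.sd,
            theta_floor=self.theta.floor,
            rng=rng,
        )

    def load_table(self) -> ProbabilityTable:
        if self.table_path is None:
            return ProbabilityTable.default()
        return ProbabilityTable.from_csv(self.table_path)

    def iac_params(self, table: ProbabilityTable | None = None) -> IacParams:
        table = table or self.load_table()
        mood_sd = self.iac.mood_sd if self.iac.mood_sd is not None else table.mood_sd
        boost = (
            self.iac.favored_boost
            if self.iac.favored_boost is not None
            else table.favored_boost
        )
        return IacParams(
            d=self.iac.d,
            g=self.iac.g,
            top_k=self.iac.top_k,
            mood_sd=mood_sd,
            mood_floor=self.iac.mood_floor,
            favored_boost=boost,
            distance_scale=self.iac.distance_scale,
        )

    def schedule_obj(self) -> Schedule:
        hours = {
            AgentType.from_name(k): float(v)
            for k, v in self.schedule.departure_hours.items()
        }
        return Schedule(departure_hours=hours)

    def build_agents(self, env: EnvironmentGrid, rng: np.random.Generator):
        mix = {AgentType.from_name(k): float(v) for k, v in self.agents.mix.items()}
        employment = {
            AgentType.from_name(k): float(v) for k, v in self.agents.employment.items()
        }
        return generate_agents(
            self.agents.n,
            env,
            rng,
            mix=mix,
            employment=employment,
            favored_count=self.agents.favored_count,
            special_workplace_prob=self.agents.special_workplace_prob,
        )

    # -- persistence -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["table_path"] = self.table_path
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _size_distribution(entry) -> SizeDistribution:
    if entry is None:
        return SizeDistribution()
    return SizeDistribution(
        kind=entry.get("kind", "exponential"),
        mean=entry.get("mean"),
        sd=entry.get("sd"),
    )


def _merge_section(cls, data, problems, path):
    kwargs = {}
    valid = {f for f in cls.__dataclass_fields__}
    for key, value in (data or {}).items():
        if key not in valid:
            problems.append(f"{path}.{key}: unknown field")
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        problems.append(f"{path}: {exc}")
        return cls()


def validate_config(cfg: SimulationConfig) -> list[str]:
    """Return a list of problems; empty means valid."""
    problems: list[str] = []
    if cfg.grid.rows < 2 or cfg.grid.cols < 2:
        problems.append("grid.rows/cols: grid must be at least 2x2")
    if cfg.grid.cell_size_m <= 0:
        problems.append("grid.cell_size_m: must be positive")
    if not 0 < cfg.iac.d < 1:
        problems.append(f"iac.d: must be in (0, 1), got {cfg.iac.d}")
    if cfg.iac.g <= 1:
        problems.append(f"iac.g: must exceed 1, got {cfg.iac.g}")
    if cfg.iac.top_k < 1:
        problems.append("iac.top_k: must be >= 1")
    if cfg.theta.mean <= 0:
        problems.append("theta.mean: must be positive")
    if cfg.theta.sd < 0:
        problems.append("theta.sd: must be non-negative")
    if cfg.agents.n < 1:
        problems.append("agents.n: must be >= 1")
    mix_sum = sum(float(v) for v in cfg.agents.mix.values())
    if not np.isclose(mix_sum, 1.0):
        problems.append(f"agents.mix: proportions sum to {mix_sum}, expected 1")
    for k, v in cfg.agents.employment.items():
        if not 0 <= float(v) <= 1:
            problems.append(f"agents.employment.{k}: must be in [0, 1]")
    if cfg.run.days < 1:
        problems.append("run.days: must be >= 1")
    if cfg.run.n_runs < 1:
        problems.append("run.n_runs: must be >= 1")
    if cfg.table_path is not None and not Path(cfg.table_path).exists():
        problems.append(f"table_path: file not found: {cfg.table_path}")
    try:
        quotas = cfg.quotas()
    except ConfigurationError as exc:
        problems.append(f"land_uses: {exc}")
    else:
        total = sum(q.cells for q in quotas)
        n_cells = cfg.grid.rows * cfg.grid.cols
        if total != n_cells:
            problems.append(
                f"land_uses: quotas cover {total} cells but the grid has {n_cells}"
            )
    return problems


def from_dict(data: dict | None) -> SimulationConfig:
    """Build and validate a config from a plain mapping (YAML-shaped)."""
    data = dict(data or {})
    problems: list[str] = []
    known = {
        "grid", "land_uses", "theta", "agents", "table", "table_path",
        "iac", "schedule", "run",
    }
    for key in data:
        if key not in known:
            problems.append(f"{key}: unknown section")
    cfg = SimulationConfig(
        grid=_merge_section(GridConfig, data.get("grid"), problems, "grid"),
        land_uses=data.get("land_uses", _default_land_uses()),
        theta=_merge_section(ThetaConfig, data.get("theta"), problems, "theta"),
        agents=_merge_section(AgentsConfig, data.get("agents"), problems, "agents"),
        table_path=data.get("table", data.get("table_path")),
        iac=_merge_section(IacConfig, data.get("iac"), problems, "iac"),
        schedule=_merge_section(ScheduleConfig, data.get("schedule"), problems, "schedule"),
        run=_merge_section(RunConfig, data.get("run"), problems, "run"),
    )
    problems.extend(validate_config(cfg))
    if problems:
        raise ConfigurationError(
            "invalid configuration:\n  " + "\n  ".join(problems), problems
        )
    return cfg


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML/JSON config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is not None and not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return from_dict(data)


def default_config() -> SimulationConfig:
    return SimulationConfig()


def packaged_default_path() -> Path:
    """Path of the shipped default config document."""
    ref = resources.files("urbanflow.data") / "default_config.yaml"
    with resources.as_file(ref) as path:
        return path
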