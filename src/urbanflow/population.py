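"""Agent population and the behavioral probability tables that drive it.

Four agent archetypes — teenagers, bachelors (students), married people
and seniors — differ in where they are anchored during working hours and
in their per-period probabilities of moving and of heading toward each
land use.  The shipped default table is an editable CSV; two of its ratios
are pinned by the model's design: a married agent is 2.5x more likely
than a teenager to head to a public building in the morning rush, and a
bachelor is 25x more likely than a married agent to head to an
entertainment/retail area at night.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .environment import EnvironmentGrid, LandUse
from .exceptions import ConfigurationError, GenerationError
from .timebase import DayPeriod


class AgentType(enum.IntEnum):
    TEENAGER = 0
    BACHELOR = 1
    MARRIED = 2
    SENIOR = 3

    @classmethod
    def from_name(cls, name: str) -> "AgentType":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ConfigurationError(f"unknown agent type: {name!r}") from None


class Context(enum.IntEnum):
    """Where an agent currently is, for move-probability lookup."""

    AT_HOME = 0
    AT_ANCHOR = 1
    ELSEWHERE = 2


_CONTEXT_NAMES = {c.name.lower(): c for c in Context}

DEFAULT_MIX = {
    AgentType.TEENAGER: 0.15,
    AgentType.BACHELOR: 0.25,
    AgentType.MARRIED: 0.45,
    AgentType.SENIOR: 0.15,
}
DEFAULT_EMPLOYMENT = {
    AgentType.BACHELOR: 0.6,
    AgentType.MARRIED: 0.85,
    AgentType.SENIOR: 0.3,
}
#: Chance that an employed agent's workplace is a public building, and
#: (independently next in line) an entertainment/retail cell.
DEFAULT_SPECIAL_WORKPLACE_PROB = 0.05
FAVORED_COUNT = 40

HOME_LAND_USES = (LandUse.RESIDENTIAL, LandUse.MIXED_R_E_RETAIL)
WORK_LAND_USES = (LandUse.EMPLOYMENT, LandUse.MIXED_R_E_RETAIL)


@dataclass
class Agent:
    """One simulated person.  Cell references are flat grid indices."""

    id: int
    type: AgentType
    home: int
    employed: bool
    anchor: int | None
    favored: np.ndarray  # sorted flat indices, len == FAVORED_COUNT
    position: int

    def context(self) -> Context:
        if self.position == self.home:
            return Context.AT_HOME
        if self.anchor is not None and self.position == self.anchor:
            return Context.AT_ANCHOR
        return Context.ELSEWHERE


@dataclass
class ProbabilityTable:
    """Per-(type, period) behavioral probabilities.

    move_prob[type, period, context]  — chance of moving this iteration.
    landuse_weight[type, period, lu]  — destination land-use weights,
                                        normalized to 1 per row.
    stay_home_prob[type, period]      — chance a non-routine move is a
                                        return home (when not at home).
    routine_move_prob                 — the "very high" probability of
                                        heading to the anchor on weekday
                                        mornings.
    favored_boost                     — IAC multiplier on an agent's 40
                                        favored cells (1 elsewhere).
    mood_sd                           — spread of the random mood factor.
    """

    move_prob: np.ndarray = field(
        default_factory=lambda: np.zeros((len(AgentType), len(DayPeriod), len(Context)))
    )
    landuse_weight: np.ndarray = field(
        default_factory=lambda: np.zeros((len(AgentType), len(DayPeriod), len(LandUse)))
    )
    stay_home_prob: np.ndarray = field(
        default_factory=lambda: np.zeros((len(AgentType), len(DayPeriod)))
    )
    routine_move_prob: float = 0.95
    favored_boost: float = 1.5
    mood_sd: float = 0.05

    @classmethod
    def from_csv(cls, path) -> "ProbabilityTable":
        """Read a long-format table: agent_type, period, kind, key, value."""
        raw = pd.read_csv(path, dtype={"key": str}, keep_default_na=False)
        table = cls()
        for rec in raw.itertuples(index=False):
            kind = rec.kind.strip()
            value = float(rec.value)
            if kind == "param":
                if rec.key == "routine_move_prob":
                    table.routine_move_prob = value
                elif rec.key == "favored_boost":
                    table.favored_boost = value
                elif rec.key == "mood_sd":
                    table.mood_sd = value
                else:
                    raise ConfigurationError(f"unknown table param {rec.key!r}")
                continue
            t = AgentType.from_name(rec.agent_type)
            p = DayPeriod[rec.period.strip().upper()]
            if kind == "move":
                table.move_prob[t, p, _CONTEXT_NAMES[rec.key.strip()]] = value
            elif kind == "landuse":
                table.landuse_weight[t, p, LandUse.from_name(rec.key)] = value
            elif kind == "stay_home":
                table.stay_home_prob[t, p] = value
            else:
                raise ConfigurationError(f"unknown table row kind {kind!r}")
        return table

    @classmethod
    def default(cls) -> "ProbabilityTable":
        ref = resources.files("urbanflow.data") / "probability_table.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def to_csv(self, path) -> None:
        rows = []
        for t in AgentType:
            for p in DayPeriod:
                for c in Context:
                    rows.append((t.name.lower(), p.name.lower(), "move",
                                 c.name.lower(), self.move_prob[t, p, c]))
                for lu in LandUse:
                    rows.append((t.name.lower(), p.name.lower(), "landuse",
                                 lu.name.lower(), self.landuse_weight[t, p, lu]))
                rows.append((t.name.lower(), p.name.lower(), "stay_home", "",
                             self.stay_home_prob[t, p]))
        rows.append(("", "", "param", "routine_move_prob", self.routine_move_prob))
        rows.append(("", "", "param", "favored_boost", self.favored_boost))
        rows.append(("", "", "param", "mood_sd", self.mood_sd))
        pd.DataFrame(rows, columns=["agent_type", "period", "kind", "key", "value"]).to_csv(
            path, index=False
        )


@dataclass
class TableReport:
    """Result of validating a ProbabilityTable."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_probability_table(
    table: ProbabilityTable, rtol: float = 1e-6
) -> TableReport:
    """Check ranges, normalization and the two pinned cross-type ratios."""
    report = TableReport()
    if not ((table.move_prob >= 0) & (table.move_prob <= 1)).all():
        report.violations.append("move_prob outside [0, 1]")
    if not ((table.stay_home_prob >= 0) & (table.stay_home_prob <= 1)).all():
        report.violations.append("stay_home_prob outside [0, 1]")
    if not (0 <= table.routine_move_prob <= 1):
        report.violations.append("routine_move_prob outside [0, 1]")
    if (table.landuse_weight < 0).any():
        report.violations.append("negative land-use weight")
    if table.favored_boost <= 1:
        report.violations.append("favored_boost must exceed 1")
    sums = table.landuse_weight.sum(axis=2)
    for t in AgentType:
        for p in DayPeriod:
            if not np.isclose(sums[t, p], 1.0, rtol=rtol, atol=1e-9):
                report.violations.append(
                    f"land-use weights for ({t.name.lower()}, {p.name.lower()}) "
                    f"sum to {sums[t, p]:.6f}, expected 1"
                )
    married_pb = table.landuse_weight[
        AgentType.MARRIED, DayPeriod.MORNING_RUSH, LandUse.PUBLIC_BUILDING
    ]
    teen_pb = table.landuse_weight[
        AgentType.TEENAGER, DayPeriod.MORNING_RUSH, LandUse.PUBLIC_BUILDING
    ]
    if not np.isclose(married_pb, 2.5 * teen_pb, rtol=rtol):
        report.violations.append(
            f"married/public_building/morning_rush = {married_pb:.4f} is not "
            f"2.5x the teenager value {teen_pb:.4f}"
        )
    bach_ent = table.landuse_weight[
        AgentType.BACHELOR, DayPeriod.NIGHT, LandUse.ENTERTAINMENT_RETAIL
    ]
    married_ent = table.landuse_weight[
        AgentType.MARRIED, DayPeriod.NIGHT, LandUse.ENTERTAINMENT_RETAIL
    ]
    if not np.isclose(bach_ent, 25.0 * married_ent, rtol=rtol):
        report.violations.append(
            f"bachelor/entertainment_retail/night = {bach_ent:.4f} is not "
            f"25x the married value {married_ent:.4f}"
        )
    return report


def _draw_anchor(
    env: EnvironmentGrid,
    rng: np.random.Generator,
    special_prob: float,
) -> int:
    """Workplace cell: mostly employment/mixed, occasionally public
    building or entertainment/retail."""
    u = rng.random()
    if u < special_prob:
        pool = env.cells_of(LandUse.PUBLIC_BUILDING)
    elif u < 2 * special_prob:
        pool = env.cells_of(LandUse.ENTERTAINMENT_RETAIL)
    else:
        pool = np.concatenate(
            [env.cells_of(LandUse.EMPLOYMENT), env.cells_of(LandUse.MIXED_R_E_RETAIL)]
        )
    if pool.size == 0:
        raise GenerationError("no cells available for a workplace anchor")
    return int(pool[rng.integers(pool.size)])


def generate_agents(
    n: int,
    env: EnvironmentGrid,
    rng: np.random.Generator,
    mix: dict[AgentType, float] | None = None,
    employment: dict[AgentType, float] | None = None,
    favored_count: int = FAVORED_COUNT,
    special_workplace_prob: float = DEFAULT_SPECIAL_WORKPLACE_PROB,
) -> list[Agent]:
    """Create ``n`` agents with homes, anchors, and favored cells.

    Homes are uniform over residential and mixed cells.  Teenagers and
    non-working bachelors (students) are anchored at a public building
    (school/university); employed agents at a workplace.  Favored cells
    are drawn uniformly without replacement from the whole grid.
    """
    mix = DEFAULT_MIX if mix is None else mix
    employment = DEFAULT_EMPLOYMENT if employment is None else employment
    probs = np.array([mix.get(t, 0.0) for t in AgentType], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ConfigurationError(f"type mix sums to {probs.sum()}, expected 1")

    home_pool = np.concatenate([env.cells_of(lu) for lu in HOME_LAND_USES])
    if home_pool.size == 0:
        raise GenerationError("grid has no residential or mixed cells for homes")
    if env.cells_of(LandUse.PUBLIC_BUILDING).size == 0:
        raise GenerationError("grid has no public buildings for schools")

    agents: list[Agent] = []
    types = rng.choice(len(AgentType), size=n, p=probs)
    for i in range(n):
        t = AgentType(int(types[i]))
        home = int(home_pool[rng.integers(home_pool.size)])
        employed = False
        anchor: int | None = None
        if t is AgentType.TEENAGER:
            pb = env.cells_of(LandUse.PUBLIC_BUILDING)
            anchor = int(pb[rng.integers(pb.size)])
        else:
            employed = bool(rng.random() < employment.get(t, 0.0))
            if employed:
                anchor = _draw_anchor(env, rng, special_workplace_prob)
            elif t is AgentType.BACHELOR:
                # non-working bachelors are students at a university
                pb = env.cells_of(LandUse.PUBLIC_BUILDING)
                anchor = int(pb[rng.integers(pb.size)])
        favored = np.sort(rng.choice(env.n_cells, size=favored_count, replace=False))
        agents.append(Agent(i, t, home, employed, anchor, favored, home))
    return agents
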