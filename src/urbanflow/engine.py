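"""The two-stage movement algorithm and the IAC destination model.

Stage 1 decides whether an agent moves this iteration: anchored agents
head to work/school with very high probability on weekday mornings;
otherwise a per-(type, period, context) probability applies.  Stage 2
sets the destination: the routine anchor when the routine rule applies,
otherwise either a return home or an irregular trip.  For irregular
trips a land use is drawn from the agent's per-period weights, and every
cell of that land use is scored with the Integrated Attraction
Coefficient

    IAC_i = d**delta_i * g**gamma_i * theta_i * m_i * f_agent

where delta_i is the Euclidean distance (in cell units) from the agent
to cell i, gamma_i the size of cell i's land-use cluster, theta_i its
attractiveness, m_i a per-cell random mood factor and f_agent the
favored-cell multiplier.  The destination is picked uniformly among the
top-10 IAC scores, so choices balance proximity (d < 1) against cluster
mass (g > 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentGrid, LandUse
from .exceptions import ConfigurationError, SelectionError, UrbanFlowError
from .population import Agent, AgentType, Context, ProbabilityTable
from .timebase import (
    ITERATIONS_PER_DAY,
    Clock,
    DayPeriod,
    is_weekday,
    period_of,
)
from .trajectory import MovementEvent, TrajectoryLog


@dataclass(frozen=True)
class IacParams:
    """Parameters of the IAC score and of the top-k pick."""

    d: float = 0.95  # distance decay, 0 < d < 1
    g: float = 1.02  # gravity (cluster-size) growth, g > 1
    top_k: int = 10
    mood_sd: float = 0.05  # spread of the mood factor m ~ N(1, sd)
    mood_floor: float = 0.5  # lower truncation of m
    favored_boost: float = 1.5  # f_agent on favored cells
    distance_scale: float = 1.0  # multiplies delta before exponentiation

    def __post_init__(self):
        problems = []
        if not 0 < self.d < 1:
            problems.append(f"d must be in (0, 1), got {self.d}")
        if not self.g > 1:
            problems.append(f"g must exceed 1, got {self.g}")
        if self.top_k < 1:
            problems.append(f"top_k must be >= 1, got {self.top_k}")
        if self.mood_sd < 0:
            problems.append(f"mood_sd must be non-negative, got {self.mood_sd}")
        if problems:
            raise ConfigurationError("invalid IAC parameters", problems)


#: Hour (local time) at which each anchored type leaves its anchor on
#: weekdays: pupils leave school early, working seniors work short days,
#: bachelors stay latest.
DEFAULT_DEPARTURE_HOURS = {
    AgentType.TEENAGER: 14.0,
    AgentType.BACHELOR: 18.0,
    AgentType.MARRIED: 17.0,
    AgentType.SENIOR: 13.0,
}

#: Periods during which the weekday routine drives agents to their anchor.
ROUTINE_PERIODS = (DayPeriod.MORNING, DayPeriod.MORNING_RUSH)


@dataclass(frozen=True)
class Schedule:
    departure_hours: dict = field(
        default_factory=lambda: dict(DEFAULT_DEPARTURE_HOURS)
    )


def compute_iac(
    delta: float,
    gamma: float,
    theta: float,
    mood: float,
    f: float,
    params: IacParams = IacParams(),
) -> float:
    """Integrated Attraction Coefficient of one candidate cell.

    With the default parameters (d = 0.95, g = 1.02) a cell at distance
    27.22 in a 29-cell cluster with theta = 0.93, mood 1.03 and no
    favored boost scores 0.42.
    """
    values = (delta, gamma, theta, mood, f)
    if not all(math.isfinite(v) for v in values):
        raise UrbanFlowError(f"non-finite IAC input: {values}")
    if delta < 0:
        raise UrbanFlowError(f"negative distance: {delta}")
    if theta <= 0 or mood <= 0 or f <= 0:
        raise UrbanFlowError("theta, mood and f must be positive")
    return params.d**delta * params.g**gamma * theta * mood * f


def _routine_to_anchor(agent: Agent, period: DayPeriod, weekday: bool) -> bool:
    """True when the weekday-morning routine should route the agent to
    its anchor."""
    return (
        weekday
        and agent.anchor is not None
        and period in ROUTINE_PERIODS
        and agent.position != agent.anchor
    )


def decide_move(
    agent: Agent,
    clock: Clock,
    table: ProbabilityTable,
    rng: np.random.Generator,
    schedule: Schedule = Schedule(),
) -> bool:
    """Stage 1: does the agent move this iteration?

    Routine cases (heading to the anchor on weekday mornings; leaving it
    after the type's departure hour) use the high routine probability;
    everything else draws against move_prob[type, period, context].
    """
    period = period_of(clock)
    weekday = is_weekday(clock)
    if _routine_to_anchor(agent, period, weekday):
        return bool(rng.random() < table.routine_move_prob)
    if (
        weekday
        and agent.anchor is not None
        and agent.position == agent.anchor
        and clock.hour >= schedule.departure_hours[agent.type]
    ):
        return bool(rng.random() < table.routine_move_prob)
    p = table.move_prob[agent.type, period, agent.context()]
    return bool(rng.random() < p)


def choose_land_use(
    agent: Agent,
    period: DayPeriod,
    table: ProbabilityTable,
    rng: np.random.Generator,
) -> LandUse:
    """Stage 2, phase 1: draw a destination land use for an irregular trip."""
    weights = table.landuse_weight[agent.type, period]
    total = weights.sum()
    if total <= 0:
        raise ConfigurationError(
            f"all-zero land-use weights for ({agent.type.name}, {period.name})"
        )
    return LandUse(int(rng.choice(len(LandUse), p=weights / total)))


def _candidates(env: EnvironmentGrid, land_use: LandUse):
    """Cached per-land-use candidate arrays: flat index, row, col, gamma,
    log(theta)."""
    key = ("cand", int(land_use))
    if key not in env._cache:
        flat = env.cells_of(land_use)
        rows, cols = np.divmod(flat, env.dims[1])
        gamma = env.cluster_sizes[env.cluster_id.ravel()[flat]].astype(float)
        log_theta = np.log(env.theta.ravel()[flat])
        env._cache[key] = (
            flat,
            rows.astype(float),
            cols.astype(float),
            gamma,
            log_theta,
        )
    return env._cache[key]


def select_destination(
    agent: Agent,
    land_use: LandUse,
    env: EnvironmentGrid,
    params: IacParams,
    rng: np.random.Generator,
) -> int:
    """Stage 2, phase 2: score all cells of ``land_use`` and pick one of
    the top-k IAC values uniformly at random.

    Scores are evaluated in the log domain (equivalent to the product
    form, and immune to overflow for very large clusters).  The agent's
    current cell is never returned.  Ties are broken by (row, col) so
    ranking is reproducible.
    """
    flat, rows, cols, gamma, log_theta = _candidates(env, land_use)
    if flat.size == 0:
        raise SelectionError(f"no cells of land use {land_use.name} in the grid")
    ar, ac = divmod(agent.position, env.dims[1])
    mood = rng.normal(1.0, params.mood_sd, size=flat.size)
    np.maximum(mood, params.mood_floor, out=mood)

    keep = flat != agent.position
    if not keep.any():
        raise SelectionError(
            f"the only {land_use.name} cell is the agent's current position"
        )
    delta = np.hypot(rows - ar, cols - ac) * params.distance_scale
    log_iac = (
        delta * math.log(params.d)
        + gamma * math.log(params.g)
        + log_theta
        + np.log(mood)
    )
    # favored multiplier via binary search into the agent's sorted favored set
    if agent.favored.size:
        pos = np.searchsorted(agent.favored, flat)
        pos[pos == agent.favored.size] = 0
        favored_mask = agent.favored[pos] == flat
        log_iac = np.where(
            favored_mask, log_iac + math.log(params.favored_boost), log_iac
        )

    flat_k = flat[keep]
    order = np.lexsort((cols[keep], rows[keep], -log_iac[keep]))
    k = min(params.top_k, flat_k.size)
    return int(flat_k[order[int(rng.integers(k))]])


class Simulation:
    """Mutable simulation state: environment, agents, clock, event log."""

    def __init__(
        self,
        env: EnvironmentGrid,
        agents: list[Agent],
        table: ProbabilityTable,
        params: IacParams,
        rng: np.random.Generator,
        schedule: Schedule | None = None,
    ):
        self.env = env
        self.agents = agents
        self.table = table
        self.params = params
        self.rng = rng
        self.schedule = schedule or Schedule()
        self.clock = Clock(0)
        self.events: list[MovementEvent] = []

    def _record(self, agent: Agent, dest: int, kind: str) -> None:
        cols = self.env.dims[1]
        o = divmod(agent.position, cols)
        d = divmod(dest, cols)
        dist = math.hypot(o[0] - d[0], o[1] - d[1]) * self.env.cell_size_m
        self.events.append(
            MovementEvent(agent.id, self.clock.iteration, o, d, dist, kind)
        )
        agent.position = dest

    def step(self) -> int:
        """Advance one 15-minute iteration; returns the number of trips."""
        period = period_of(self.clock)
        weekday = is_weekday(self.clock)
        rng = self.rng
        n_before = len(self.events)
        for idx in rng.permutation(len(self.agents)):
            agent = self.agents[int(idx)]
            if not decide_move(agent, self.clock, self.table, rng, self.schedule):
                continue
            if _routine_to_anchor(agent, period, weekday):
                self._record(agent, agent.anchor, "routine")
                continue
            if (
                agent.position != agent.home
                and rng.random() < self.table.stay_home_prob[agent.type, period]
            ):
                self._record(agent, agent.home, "return_home")
                continue
            land_use = choose_land_use(agent, period, self.table, rng)
            try:
                dest = select_destination(agent, land_use, self.env, self.params, rng)
            except SelectionError:
                continue
            if dest != agent.position:
                self._record(agent, dest, "irregular")
        self.clock = self.clock.tick()
        return len(self.events) - n_before

    def run(self, days: int) -> None:
        for _ in range(days * ITERATIONS_PER_DAY):
            self.step()

    def log(self, metadata: dict | None = None) -> TrajectoryLog:
        meta = {
            "n_agents": len(self.agents),
            "iterations": self.clock.iteration,
            "cell_size_m": self.env.cell_size_m,
            "dims": list(self.env.dims),
            "env_hash": self.env.content_hash(),
        }
        meta.update(metadata or {})
        return TrajectoryLog.from_events(self.events, self.agents, self.env.dims, meta)


def run_simulation(
    config,
    env: EnvironmentGrid | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> TrajectoryLog:
    """Generate (or reuse) the environment, generate agents, run the
    configured number of days and return the full trajectory log."""
    from .config import SimulationConfig  # local import to avoid a cycle

    if not isinstance(config, SimulationConfig):
        raise ConfigurationError("run_simulation expects a SimulationConfig")
    if seed is None:
        seed = config.run.master_seed
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    env_seq, agent_seq = seq.spawn(2)
    if env is None:
        env = config.build_environment(np.random.default_rng(env_seq))
    rng = np.random.default_rng(agent_seq)
    table = config.load_table()
    agents = config.build_agents(env, rng)
    sim = Simulation(env, agents, table, config.iac_params(table), rng,
                     config.schedule_obj())
    sim.run(config.run.days)
    return sim.log(
        {"seed": _seed_repr(seq), "config_hash": config.content_hash(),
         "days": config.run.days}
    )


def _seed_repr(seq: np.random.SeedSequence):
    entropy = seq.entropy
    return int(entropy) if isinstance(entropy, int) else list(map(int, entropy))
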