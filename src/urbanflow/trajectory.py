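"""Trajectory logs: the persisted record of one simulation run."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .exceptions import IntegrityError

EVENT_COLUMNS = (
    "agent_id", "iteration", "o_row", "o_col", "d_row", "d_col", "distance_m", "kind",
)
AGENT_COLUMNS = (
    "agent_id", "type", "home_row", "home_col", "employed", "anchor_row", "anchor_col",
)


class MovementEvent(NamedTuple):
    """One recorded trip.  Cells are (row, col); distance is in meters."""

    agent_id: int
    iteration: int
    origin: tuple[int, int]
    destination: tuple[int, int]
    distance_m: float
    kind: str  # routine | irregular | return_home


@dataclass
class TrajectoryLog:
    """Ordered movement events plus the agent roster and run metadata."""

    events: pd.DataFrame
    agents: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_events(cls, events: list[MovementEvent], agents, dims,
                    metadata: dict | None = None) -> "TrajectoryLog":
        rows = [
            (e.agent_id, e.iteration, e.origin[0], e.origin[1],
             e.destination[0], e.destination[1], e.distance_m, e.kind)
            for e in events
        ]
        edf = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
        cols = dims[1]
        arows = []
        for a in agents:
            hr, hc = divmod(a.home, cols)
            ar, ac = (divmod(a.anchor, cols)) if a.anchor is not None else (-1, -1)
            arows.append((a.id, a.type.name.lower(), hr, hc, int(a.employed), ar, ac))
        adf = pd.DataFrame(arows, columns=list(AGENT_COLUMNS))
        return cls(edf, adf, dict(metadata or {}))

    def __len__(self) -> int:
        return len(self.events)

    def check_chain(self) -> None:
        """Every agent's consecutive events must share endpoints."""
        for _, g in self.events.groupby("agent_id", sort=False):
            g = g.sort_values("iteration", kind="stable")
            o = g[["o_row", "o_col"]].to_numpy()[1:]
            d = g[["d_row", "d_col"]].to_numpy()[:-1]
            if o.size and (o != d).any():
                raise IntegrityError("trajectory chain broken")

    def save(self, prefix) -> tuple[Path, Path, Path]:
        """Write events CSV, agents CSV and a JSON metadata sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        events_path = prefix.with_suffix(".csv")
        agents_path = prefix.parent / (prefix.name + "_agents.csv")
        meta_path = prefix.with_suffix(".json")
        self.events.to_csv(events_path, index=False, float_format="%.6f")
        self.agents.to_csv(agents_path, index=False)
        meta_path.write_text(json.dumps(self.metadata, indent=2, sort_keys=True))
        return events_path, agents_path, meta_path

    @classmethod
    def load(cls, prefix) -> "TrajectoryLog":
        prefix = Path(prefix)
        events = pd.read_csv(prefix.with_suffix(".csv"))
        agents = pd.read_csv(prefix.parent / (prefix.name + "_agents.csv"))
        meta_path = prefix.with_suffix(".json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(events, agents, metadata)
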