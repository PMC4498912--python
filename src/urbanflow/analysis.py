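"""Emergent mobility statistics from a trajectory log.

Three families of results:

* trip-length distribution — the heavy tail of traveled distances
  (many short trips, few long ones);
* regularity — how often each agent returns to the same cells, and the
  cumulative visit curve over an agent's most-visited locations;
* cell popularity — the rank-size structure of visits per cell, the
  three-tier popularity partition, and the spatial signature of the top
  tier (proximity to land-use boundaries).

The power-law tail fit is a continuous maximum-likelihood estimator with
the lower cutoff chosen by Kolmogorov-Smirnov minimization, compared
against an exponential tail by normalized log-likelihood ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import EnvironmentGrid, boundary_distance_field
from .exceptions import AnalysisError
from .trajectory import TrajectoryLog

DEFAULT_BIN_WIDTH_M = 250.0
DEFAULT_POPULARITY_THRESHOLDS = (10_000, 1_000)


def movement_distances(
    log: TrajectoryLog, bin_width_m: float = DEFAULT_BIN_WIDTH_M
) -> tuple[np.ndarray, pd.DataFrame]:
    """One distance per movement event, plus a binned histogram.

    Returns ``(distances_m, histogram)`` where the histogram has columns
    ``bin_left_m``, ``bin_right_m``, ``count``.
    """
    if len(log) == 0:
        raise AnalysisError("empty trajectory log")
    distances = log.events["distance_m"].to_numpy(dtype=float)
    top = max(distances.max(), bin_width_m)
    edges = np.arange(0.0, top + bin_width_m, bin_width_m)
    counts, edges = np.histogram(distances, bins=edges)
    hist = pd.DataFrame(
        {"bin_left_m": edges[:-1], "bin_right_m": edges[1:], "count": counts}
    )
    return distances, hist


@dataclass
class VisitTable:
    """Arrival tallies per cell and per (agent, cell).

    A "visit" is an arrival event; each agent's starting position (home)
    counts as one initial visit.  ``per_cell`` maps flat cell index ->
    count; ``per_agent_cell`` is a DataFrame (agent_id, cell, visits).
    """

    per_cell: pd.Series
    per_agent_cell: pd.DataFrame
    n_cells: int

    def total_arrivals(self) -> int:
        return int(self.per_cell.sum())

    def agent_top_counts(self, agent_id: int, k: int = 25) -> np.ndarray:
        """Visit counts of one agent's k most-visited cells, descending."""
        g = self.per_agent_cell[self.per_agent_cell["agent_id"] == agent_id]
        return g["visits"].sort_values(ascending=False).to_numpy()[:k]

    def cumulative_top_curve(self, agent_id: int, k: int = 25) -> np.ndarray:
        """Cumulative visit curve over the agent's top-k locations."""
        return np.cumsum(self.agent_top_counts(agent_id, k))


def visit_frequencies(log: TrajectoryLog) -> VisitTable:
    """Tally arrivals per (agent, cell), seeding each agent at home."""
    if log.agents is None or len(log.agents) == 0:
        raise AnalysisError("trajectory log carries no agent roster")
    dims = log.metadata.get("dims")
    if dims is None:
        cols = int(max(log.events[["o_col", "d_col"]].max().max() + 1, 1)) if len(log) else 1
        rows = int(max(log.events[["o_row", "d_row"]].max().max() + 1, 1)) if len(log) else 1
        n_cells = rows * cols
    else:
        rows, cols = int(dims[0]), int(dims[1])
        n_cells = rows * cols

    homes = pd.DataFrame(
        {
            "agent_id": log.agents["agent_id"],
            "cell": log.agents["home_row"] * cols + log.agents["home_col"],
        }
    )
    arrivals = pd.DataFrame(
        {
            "agent_id": log.events["agent_id"],
            "cell": log.events["d_row"] * cols + log.events["d_col"],
        }
    )
    both = pd.concat([homes, arrivals], ignore_index=True)
    per_agent_cell = (
        both.groupby(["agent_id", "cell"]).size().rename("visits").reset_index()
    )
    per_cell = both.groupby("cell").size()
    return VisitTable(per_cell, per_agent_cell, n_cells)


def rank_size(table: VisitTable) -> pd.DataFrame:
    """Cells ranked by visit count (rank 1 = most visited; ties by cell index)."""
    if table.per_cell.empty:
        raise AnalysisError("empty visit table")
    df = table.per_cell.rename("visits").reset_index()
    df = df.sort_values(["visits", "cell"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)[["rank", "cell", "visits"]]


@dataclass
class PopularityPartition:
    """Cells split into popularity tiers A (top) / B / C by visit count."""

    group_a: np.ndarray
    group_b: np.ndarray
    group_c: np.ndarray
    thresholds: tuple[float, float]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.group_a), len(self.group_b), len(self.group_c)


def popularity_groups(
    ranked: pd.DataFrame,
    thresholds: tuple[float, float] = DEFAULT_POPULARITY_THRESHOLDS,
    n_cells: int | None = None,
) -> PopularityPartition:
    """Partition cells by visit count.

    Group A: visits > thresholds[0]; group B: (thresholds[1],
    thresholds[0]]; group C: the rest.  When ``n_cells`` is given,
    never-visited cells are included in group C so the groups partition
    the whole grid.
    """
    hi, lo = thresholds
    if not hi > lo:
        raise AnalysisError(f"thresholds must be ordered, got {thresholds}")
    visits = ranked["visits"].to_numpy()
    cells = ranked["cell"].to_numpy()
    a = cells[visits > hi]
    b = cells[(visits > lo) & (visits <= hi)]
    c = cells[visits <= lo]
    if n_cells is not None:
        unseen = np.setdiff1d(np.arange(n_cells), cells, assume_unique=False)
        c = np.concatenate([c, unseen])
    return PopularityPartition(a, b, np.sort(c), (hi, lo))


@dataclass
class BoundaryProfile:
    """Boundary-distance structure of the popularity tiers."""

    distances: dict  # group label -> array of boundary distances
    near_fraction_a: float | None  # fraction of tier A within `proximity`
    proximity: float
    land_use_composition: dict  # group label -> {land use name: count}


def boundary_profile(
    partition: PopularityPartition,
    env: EnvironmentGrid,
    proximity: float = 2.0,
) -> BoundaryProfile:
    """Boundary distances per tier and the tier-A near-boundary fraction.

    Distance 1 means the cell touches a land-use boundary.  On a uniform
    (single land use) grid boundary distances are undefined and reported
    as absent (None fraction, empty distances).
    """
    all_cells = np.concatenate([partition.group_a, partition.group_b, partition.group_c])
    if all_cells.size and all_cells.max() >= env.n_cells:
        raise AnalysisError("partition refers to cells outside the environment")
    fieldv = boundary_distance_field(env).ravel()
    lu = env.land_use.ravel()
    from .environment import LandUse

    distances, composition = {}, {}
    for label, cells in (
        ("A", partition.group_a),
        ("B", partition.group_b),
        ("C", partition.group_c),
    ):
        cells = np.asarray(cells, dtype=int)
        d = fieldv[cells] if cells.size else np.empty(0)
        d = d[np.isfinite(d)]
        distances[label] = d
        names, counts = np.unique(lu[cells], return_counts=True) if cells.size else ((), ())
        composition[label] = {
            LandUse(int(code)).name.lower(): int(cnt) for code, cnt in zip(names, counts)
        }
    if distances["A"].size == 0:
        near = None
    else:
        near = float(np.mean(distances["A"] <= proximity))
    return BoundaryProfile(distances, near, proximity, composition)


@dataclass
class TailFit:
    """Continuous power-law tail fit and its exponential comparison."""

    alpha: float
    xmin: float
    ks: float
    n_tail: int
    loglikelihood_ratio: float  # normalized; > 0 favors the power law
    preferred: str  # "power_law" | "exponential"


def _powerlaw_ks(x_tail: np.ndarray, xmin: float) -> tuple[float, float]:
    """MLE exponent and KS statistic for the tail x >= xmin."""
    n = x_tail.size
    alpha = 1.0 + n / np.sum(np.log(x_tail / xmin))
    cdf_model = 1.0 - (x_tail / xmin) ** (1.0 - alpha)
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    ks = max(np.abs(cdf_model - emp_hi).max(), np.abs(cdf_model - emp_lo).max())
    return alpha, ks


def fit_tail(
    values: np.ndarray,
    xmin: float | None = None,
    max_xmin_candidates: int = 100,
) -> TailFit:
    """Fit a continuous power law to the tail of a positive sample.

    The exponent is the continuous maximum-likelihood estimate
    alpha = 1 + n / sum(log(x / xmin)); xmin (unless given) is chosen to
    minimize the KS distance between the tail and the fitted model.  The
    fit is compared against an exponential tail (MLE rate on the same
    tail) with a normalized log-likelihood ratio; a positive ratio
    favors the power law.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 50:
        raise AnalysisError(f"need at least 50 positive values, got {x.size}")
    if np.unique(x).size < 2:
        raise AnalysisError("degenerate (constant) sample")
    x = np.sort(x)

    if xmin is None:
        uniq = np.unique(x)
        # keep at least 10 tail points and cap the number of candidates
        uniq = uniq[uniq <= x[-10]] if uniq.size > 10 else uniq[:1]
        if uniq.size > max_xmin_candidates:
            idx = np.linspace(0, uniq.size - 1, max_xmin_candidates).astype(int)
            uniq = uniq[idx]
        best = None
        for cand in uniq:
            tail = x[x >= cand]
            if np.unique(tail).size < 2:
                continue
            alpha, ks = _powerlaw_ks(tail, cand)
            if best is None or ks < best[0]:
                best = (ks, cand, alpha)
        if best is None:
            raise AnalysisError("no viable xmin candidate")
        ks, xmin, alpha = best
    else:
        tail = x[x >= xmin]
        if tail.size < 10 or np.unique(tail).size < 2:
            raise AnalysisError("tail above the given xmin is degenerate")
        alpha, ks = _powerlaw_ks(tail, xmin)

    tail = x[x >= xmin]
    n = tail.size
    # log-likelihoods of the two tail models on the same data
    ll_pl = n * np.log((alpha - 1) / xmin) - alpha * np.sum(np.log(tail / xmin))
    lam = 1.0 / max(np.mean(tail) - xmin, np.finfo(float).tiny)
    ll_exp = n * np.log(lam) - lam * np.sum(tail - xmin)
    per_point = (
        np.log((alpha - 1) / xmin)
        - alpha * np.log(tail / xmin)
        - (np.log(lam) - lam * (tail - xmin))
    )
    sd = per_point.std(ddof=1)
    ratio_raw = ll_pl - ll_exp
    ratio = ratio_raw / (sd * np.sqrt(n)) if sd > 0 else np.sign(ratio_raw) * np.inf
    return TailFit(
        alpha=float(alpha),
        xmin=float(xmin),
        ks=float(ks),
        n_tail=int(n),
        loglikelihood_ratio=float(ratio),
        preferred="power_law" if ratio > 0 else "exponential",
    )


def summarize_run(
    log: TrajectoryLog,
    env: EnvironmentGrid,
    thresholds: tuple[float, float] = DEFAULT_POPULARITY_THRESHOLDS,
    bin_width_m: float = DEFAULT_BIN_WIDTH_M,
    proximity: float = 2.0,
) -> dict:
    """One-stop pipeline: distances, visits, rank-size, tiers, boundaries."""
    distances, hist = movement_distances(log, bin_width_m)
    visits = visit_frequencies(log)
    ranked = rank_size(visits)
    partition = popularity_groups(ranked, thresholds, n_cells=env.n_cells)
    profile = boundary_profile(partition, env, proximity)
    return {
        "distances_m": distances,
        "distance_histogram": hist,
        "visits": visits,
        "rank_size": ranked,
        "partition": partition,
        "boundary_profile": profile,
    }
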