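"""Synthetic city environment: land-use clusters on a cellular grid.

The environment is a square lattice (default 100x100, each cell 25 m on a
side) in which every cell carries one of six land uses, an id of the
contiguous cluster it belongs to, and a "specific attractiveness" value
theta.  Generation is seed-and-grow: a list of cluster specifications
(land use + target size) is drawn from per-land-use quotas, then clusters
are placed at random seed cells and grown over free adjacent cells until
they reach their target size or run out of room.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ConfigurationError, GenerationError, IntegrityError

UNASSIGNED = -1

#: 4-neighborhood (von Neumann) offsets used for growth and components.
VON_NEUMANN = ((-1, 0), (1, 0), (0, -1), (0, 1))
MOORE = VON_NEUMANN + ((-1, -1), (-1, 1), (1, -1), (1, 1))


class LandUse(enum.IntEnum):
    """The six land uses a cell may carry."""

    RESIDENTIAL = 0
    EMPLOYMENT = 1
    PUBLIC_BUILDING = 2
    MIXED_R_E_RETAIL = 3
    ENTERTAINMENT_RETAIL = 4
    PUBLIC_OPEN_SPACE = 5

    @classmethod
    def from_name(cls, name: str) -> "LandUse":
        key = name.strip().lower().replace(" ", "_").replace("-", "_")
        aliases = {
            "residential": cls.RESIDENTIAL,
            "r": cls.RESIDENTIAL,
            "employment": cls.EMPLOYMENT,
            "e": cls.EMPLOYMENT,
            "public_building": cls.PUBLIC_BUILDING,
            "public_buildings": cls.PUBLIC_BUILDING,
            "mixed_r_e_retail": cls.MIXED_R_E_RETAIL,
            "r_e_retail": cls.MIXED_R_E_RETAIL,
            "mixed": cls.MIXED_R_E_RETAIL,
            "entertainment_retail": cls.ENTERTAINMENT_RETAIL,
            "entertainment_and_retail": cls.ENTERTAINMENT_RETAIL,
            "public_open_space": cls.PUBLIC_OPEN_SPACE,
            "open_space": cls.PUBLIC_OPEN_SPACE,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ConfigurationError(f"unknown land use name: {name!r}") from None


@dataclass(frozen=True)
class SizeDistribution:
    """Distribution of cluster sizes for one land use.

    kind is "exponential" (parameter: mean) or "normal" (mean, sd).  Sizes
    are drawn, rounded, and truncated to [1, max_cluster].  When mean is
    None it defaults to max_cluster / 3 at draw time.
    """

    kind: str = "exponential"
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self):
        if self.kind not in ("exponential", "normal"):
            raise ConfigurationError(
                f"size distribution kind must be 'exponential' or 'normal', got {self.kind!r}"
            )


@dataclass(frozen=True)
class LandUseQuota:
    """Per-land-use cell budget and cluster-size constraints."""

    land_use: LandUse
    cells: int
    max_cluster: int
    size_distribution: SizeDistribution = field(default_factory=SizeDistribution)

    def __post_init__(self):
        if self.cells < 0:
            raise ConfigurationError(f"{self.land_use.name}: negative cell quota")
        if self.max_cluster < 1:
            raise ConfigurationError(f"{self.land_use.name}: max_cluster must be >= 1")


@dataclass(frozen=True)
class ClusterSpec:
    """One planned cluster: a land use and a target size in cells."""

    land_use: LandUse
    target_size: int


# Default quotas for the 100x100 grid: cells, max cluster size.
DEFAULT_QUOTAS = (
    LandUseQuota(LandUse.RESIDENTIAL, 3400, 1000),
    LandUseQuota(LandUse.EMPLOYMENT, 1000, 500),
    LandUseQuota(LandUse.PUBLIC_BUILDING, 1200, 200),
    LandUseQuota(LandUse.MIXED_R_E_RETAIL, 2400, 300),
    LandUseQuota(LandUse.ENTERTAINMENT_RETAIL, 800, 40),
    LandUseQuota(LandUse.PUBLIC_OPEN_SPACE, 1200, 100),
)


@dataclass
class EnvironmentGrid:
    """A fully generated city grid.

    Attributes
    ----------
    land_use : (rows, cols) int8 array of LandUse codes.
    cluster_id : (rows, cols) int32 array; ids partition the grid and each
        id labels one connected region of a single land use.
    theta : (rows, cols) float array of per-cell attractiveness, > 0.
    cell_size_m : physical edge length of a cell in meters.
    """

    land_use: np.ndarray
    cluster_id: np.ndarray
    theta: np.ndarray
    cell_size_m: float = 25.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def dims(self) -> tuple[int, int]:
        return self.land_use.shape

    @property
    def n_cells(self) -> int:
        return self.land_use.size

    @property
    def cluster_sizes(self) -> np.ndarray:
        """Size in cells of each cluster id (index = cluster id)."""
        if "cluster_sizes" not in self._cache:
            self._cache["cluster_sizes"] = np.bincount(self.cluster_id.ravel())
        return self._cache["cluster_sizes"]

    def land_use_counts(self) -> dict[LandUse, int]:
        counts = np.bincount(self.land_use.ravel(), minlength=len(LandUse))
        return {lu: int(counts[lu]) for lu in LandUse}

    def cells_of(self, land_use: LandUse) -> np.ndarray:
        """Flat indices of all cells carrying ``land_use``, sorted."""
        key = ("cells_of", int(land_use))
        if key not in self._cache:
            self._cache[key] = np.flatnonzero(self.land_use.ravel() == int(land_use))
        return self._cache[key]

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.indices(self.dims)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "land_use": [LandUse(v).name.lower() for v in self.land_use.ravel()],
                "cluster_id": self.cluster_id.ravel(),
                "theta": self.theta.ravel(),
            }
        )

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(self.land_use.astype(np.int8).tobytes())
        h.update(self.cluster_id.astype(np.int32).tobytes())
        h.update(self.theta.astype(np.float64).tobytes())
        return h.hexdigest()

    def save(self, directory) -> None:
        """Write a raster of land-use codes and a per-cell CSV table."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "land_use.txt", self.land_use, fmt="%d")
        self.to_frame().to_csv(directory / "cells.csv", index=False, float_format="%.10g")
        (directory / "grid_meta.txt").write_text(f"cell_size_m={self.cell_size_m}\n")

    @classmethod
    def load(cls, directory) -> "EnvironmentGrid":
        from pathlib import Path

        directory = Path(directory)
        table = pd.read_csv(directory / "cells.csv")
        rows = int(table["row"].max()) + 1
        cols = int(table["col"].max()) + 1
        land_use = np.empty((rows, cols), dtype=np.int8)
        cluster_id = np.empty((rows, cols), dtype=np.int32)
        theta = np.empty((rows, cols), dtype=np.float64)
        r = table["row"].to_numpy()
        c = table["col"].to_numpy()
        land_use[r, c] = [int(LandUse.from_name(n)) for n in table["land_use"]]
        cluster_id[r, c] = table["cluster_id"].to_numpy()
        theta[r, c] = table["theta"].to_numpy()
        cell_size_m = 25.0
        meta = directory / "grid_meta.txt"
        if meta.exists():
            for line in meta.read_text().splitlines():
                if line.startswith("cell_size_m="):
                    cell_size_m = float(line.split("=", 1)[1])
        return cls(land_use, cluster_id, theta, cell_size_m)


def quotas_from_percent(
    percents: dict[LandUse, float],
    n_cells: int,
    max_clusters: dict[LandUse, int],
    size_distributions: dict[LandUse, SizeDistribution] | None = None,
) -> list[LandUseQuota]:
    """Turn percentage shares into exact cell quotas by largest remainder.

    Guarantees the quotas sum to ``n_cells`` for any grid size.
    """
    total = sum(percents.values())
    if not np.isclose(total, 100.0):
        raise ConfigurationError(f"land-use percentages sum to {total}, expected 100")
    order = sorted(percents)
    raw = {lu: percents[lu] * n_cells / 100.0 for lu in order}
    floors = {lu: int(np.floor(raw[lu])) for lu in order}
    shortfall = n_cells - sum(floors.values())
    by_remainder = sorted(order, key=lambda lu: (raw[lu] - floors[lu], -int(lu)), reverse=True)
    for lu in by_remainder[:shortfall]:
        floors[lu] += 1
    size_distributions = size_distributions or {}
    return [
        LandUseQuota(lu, floors[lu], max_clusters[lu],
                     size_distributions.get(lu, SizeDistribution()))
        for lu in order
    ]


def _draw_size(dist: SizeDistribution, max_cluster: int, rng: np.random.Generator) -> int:
    mean = dist.mean if dist.mean is not None else max_cluster / 3.0
    if dist.kind == "exponential":
        raw = rng.exponential(mean)
    else:
        sd = dist.sd if dist.sd is not None else mean / 3.0
        raw = rng.normal(mean, sd)
    return int(np.clip(round(raw), 1, max_cluster))


def build_cluster_list(
    quotas: list[LandUseQuota], rng: np.random.Generator
) -> list[ClusterSpec]:
    """Draw a list of cluster specs whose sizes exhaust each quota exactly.

    Sizes come from each land use's configured distribution, truncated to
    [1, max_cluster]; the final draw per land use is clipped to the
    remaining quota so conservation is exact.
    """
    specs: list[ClusterSpec] = []
    for quota in quotas:
        if quota.cells == 0:
            continue
        if quota.max_cluster < 1:
            raise ConfigurationError(f"{quota.land_use.name}: unreachable quota")
        remaining = quota.cells
        while remaining > 0:
            size = min(_draw_size(quota.size_distribution, quota.max_cluster, rng), remaining)
            specs.append(ClusterSpec(quota.land_use, size))
            remaining -= size
    return specs


def allocate_clusters(
    dims: tuple[int, int],
    specs: list[ClusterSpec],
    rng: np.random.Generator,
    adjacency: str = "von_neumann",
    max_cluster: dict | None = None,
    max_attempts: int = 50,
) -> EnvironmentGrid:
    """Place and grow every cluster until the grid is fully covered.

    At each step a pending spec is picked at random, seeded at a random
    free cell, and grown one cell at a time over free neighbors (uniformly
    chosen) until it reaches its target size.  If growth is blocked the
    cluster closes at its current size and the shortfall is re-queued as a
    new spec of the same land use, so per-land-use totals are conserved.

    Neighboring clusters of the same land use may coalesce into one
    connected component, but a cell is only claimed when the resulting
    component stays within the land use's maximum cluster size (from
    ``max_cluster``, a LandUse -> size mapping; inferred from the largest
    spec per land use when omitted).  A layout can occasionally paint
    itself into a corner — a free pocket reachable only by land uses whose
    surrounding components are already full; such layouts are discarded
    and re-drawn, up to ``max_attempts`` times.
    """
    rows, cols = dims
    n = rows * cols
    total = sum(s.target_size for s in specs)
    if total != n:
        raise ConfigurationError(
            f"cluster specs cover {total} cells but the grid has {n}"
        )
    offsets = VON_NEUMANN if adjacency == "von_neumann" else MOORE
    if max_cluster is None:
        max_cluster = {}
        for s in specs:
            lu = int(s.land_use)
            max_cluster[lu] = max(max_cluster.get(lu, 1), s.target_size)
    else:
        max_cluster = {int(lu): int(v) for lu, v in max_cluster.items()}
    for _ in range(max_attempts):
        grid = _try_allocate(dims, specs, rng, offsets, max_cluster)
        if grid is not None:
            return grid
    raise GenerationError(
        f"could not allocate clusters in {max_attempts} attempts; the quota "
        "table may be unsatisfiable under the component-size bound"
    )


def _try_allocate(dims, specs, rng, offsets, max_cluster):
    """One seed-and-grow pass; returns None on a deadlocked layout."""
    rows, cols = dims
    n = rows * cols
    land_use = np.full(dims, UNASSIGNED, dtype=np.int8)
    cluster_id = np.full(dims, UNASSIGNED, dtype=np.int32)
    lu_flat = land_use.ravel()
    cid_flat = cluster_id.ravel()
    free = set(range(n))
    sample_pool = list(range(n))  # lazy-deleted pool for uniform seed picks
    pending: list[ClusterSpec] = list(specs)
    next_id = 0
    # union-find over cluster ids tracking merged same-use component sizes
    parent: list[int] = []
    comp_size: list[int] = []

    def find(c: int) -> int:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    def neighbors(flat: int):
        r, c = divmod(flat, cols)
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                yield rr * cols + cc

    def merged_size_if_claimed(flat: int, code: int, cid: int) -> int:
        """Component size that would result from claiming ``flat``."""
        roots = {find(cid)}
        for nb in neighbors(flat):
            if lu_flat[nb] == code:
                roots.add(find(cid_flat[nb]))
        return 1 + sum(comp_size[r] for r in roots)

    def claimable(flat: int, code: int, cid: int) -> bool:
        return merged_size_if_claimed(flat, code, cid) <= max_cluster.get(code, n)

    def claim(flat: int, code: int, cid: int) -> None:
        for nb in neighbors(flat):
            if lu_flat[nb] == code:
                r1, r2 = find(cid), find(cid_flat[nb])
                if r1 != r2:
                    parent[r2] = r1
                    comp_size[r1] += comp_size[r2]
        free.discard(flat)
        lu_flat[flat] = code
        cid_flat[flat] = cid
        comp_size[find(cid)] += 1

    def seedable(flat: int, code: int) -> bool:
        roots = set()
        for nb in neighbors(flat):
            if lu_flat[nb] == code:
                roots.add(find(cid_flat[nb]))
        return 1 + sum(comp_size[r] for r in roots) <= max_cluster.get(code, n)

    def find_seed(code: int) -> int | None:
        # a handful of uniform samples first, then an exhaustive sweep
        for _ in range(8):
            while True:
                j = int(rng.integers(len(sample_pool)))
                seed = sample_pool[j]
                if seed in free:
                    break
                sample_pool[j] = sample_pool[-1]
                sample_pool.pop()
            if seedable(seed, code):
                return seed
        candidates = sorted(c for c in free if seedable(c, code))
        if not candidates:
            return None
        return candidates[int(rng.integers(len(candidates)))]

    blocked: set[int] = set()  # land uses with no eligible seed right now
    while pending:
        open_idx = [i for i, s in enumerate(pending) if int(s.land_use) not in blocked]
        if not open_idx:
            return None  # deadlock: no pending land use can seed anywhere
        k = open_idx[int(rng.integers(len(open_idx)))]
        spec = pending[k]
        code = int(spec.land_use)
        seed = find_seed(code)
        if seed is None:
            blocked.add(code)
            continue
        pending.pop(k)
        blocked.clear()  # the board changed; re-test blocked uses later
        cid = next_id
        next_id += 1
        parent.append(cid)
        comp_size.append(0)
        placed = 1
        claim(seed, code, cid)
        frontier = {nb for nb in neighbors(seed) if nb in free}
        while placed < spec.target_size and frontier:
            ordered = sorted(frontier)
            nxt = ordered[int(rng.integers(len(ordered)))]
            frontier.discard(nxt)
            if not claimable(nxt, code, cid):
                continue  # merged component would exceed the bound
            claim(nxt, code, cid)
            placed += 1
            for nb in neighbors(nxt):
                if nb in free:
                    frontier.add(nb)
        shortfall = spec.target_size - placed
        if shortfall > 0:
            pending.append(ClusterSpec(spec.land_use, shortfall))

    # relabel ids so every merged component carries one consecutive id
    if next_id:
        roots = np.array([find(c) for c in range(next_id)])
        uniq, new_ids = np.unique(roots, return_inverse=True)
        cid_flat[:] = new_ids[cid_flat]
    theta = np.ones(dims, dtype=np.float64)
    return EnvironmentGrid(land_use, cluster_id, theta)


def assign_attractiveness(
    grid: EnvironmentGrid,
    mean: float = 1.0,
    sd: float = 0.05,
    rng: np.random.Generator | None = None,
    floor: float = 0.05,
) -> EnvironmentGrid:
    """Draw per-cell theta from Normal(mean, sd), truncated below at ``floor``."""
    if mean <= 0:
        raise ConfigurationError(f"theta mean must be positive, got {mean}")
    if sd < 0:
        raise ConfigurationError(f"theta sd must be non-negative, got {sd}")
    rng = np.random.default_rng() if rng is None else rng
    theta = rng.normal(mean, sd, size=grid.dims)
    np.maximum(theta, floor, out=theta)
    grid.theta = theta
    grid._cache.clear()
    return grid


def generate_environment(
    quotas: list[LandUseQuota] = DEFAULT_QUOTAS,
    dims: tuple[int, int] = (100, 100),
    cell_size_m: float = 25.0,
    theta_mean: float = 1.0,
    theta_sd: float = 0.05,
    theta_floor: float = 0.05,
    rng: np.random.Generator | int | None = None,
    adjacency: str = "von_neumann",
) -> EnvironmentGrid:
    """Convenience pipeline: cluster list -> allocation -> attractiveness."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    specs = build_cluster_list(list(quotas), rng)
    bounds = {q.land_use: q.max_cluster for q in quotas}
    grid = allocate_clusters(dims, specs, rng, adjacency=adjacency, max_cluster=bounds)
    grid.cell_size_m = cell_size_m
    assign_attractiveness(grid, theta_mean, theta_sd, rng, floor=theta_floor)
    return grid


def connected_components(
    grid: EnvironmentGrid, adjacency: str = "von_neumann"
) -> list[tuple[LandUse, int]]:
    """Sizes of all same-land-use connected components.

    Flood fill per land use under the same adjacency used for growth;
    component sizes sum to the total cell count.
    """
    if (grid.land_use == UNASSIGNED).any():
        raise IntegrityError("grid has unassigned cells")
    if adjacency == "von_neumann":
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    else:
        structure = np.ones((3, 3), dtype=int)
    out: list[tuple[LandUse, int]] = []
    for lu in LandUse:
        mask = grid.land_use == int(lu)
        if not mask.any():
            continue
        labels, n_labels = ndimage.label(mask, structure=structure)
        sizes = np.bincount(labels.ravel())[1:]
        out.extend((lu, int(s)) for s in sizes)
    return out


def boundary_distance(
    grid: EnvironmentGrid, cell: tuple[int, int], adjacency: str = "von_neumann"
) -> float:
    """Minimum lattice distance from ``cell`` to any cell of a different land use.

    Breadth-first search over the lattice; a cell adjacent to a different
    use is at distance 1.  Returns ``inf`` when the grid is uniform.
    """
    if (grid.land_use == UNASSIGNED).any():
        raise IntegrityError("grid has unassigned cells")
    rows, cols = grid.dims
    r0, c0 = cell
    own = grid.land_use[r0, c0]
    offsets = VON_NEUMANN if adjacency == "von_neumann" else MOORE
    seen = {(r0, c0)}
    queue = deque([(r0, c0, 0)])
    while queue:
        r, c, dist = queue.popleft()
        if grid.land_use[r, c] != own:
            return float(dist)
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and (rr, cc) not in seen:
                seen.add((rr, cc))
                queue.append((rr, cc, dist + 1))
    return float("inf")


def boundary_distance_field(grid: EnvironmentGrid) -> np.ndarray:
    """Distance of every cell to the nearest differently used cell (taxicab).

    Vectorized counterpart of :func:`boundary_distance` under the default
    4-neighborhood; cells of a uniform grid get ``inf``.
    """
    if (grid.land_use == UNASSIGNED).any():
        raise IntegrityError("grid has unassigned cells")
    out = np.full(grid.dims, np.inf)
    for lu in LandUse:
        mask = grid.land_use == int(lu)
        if not mask.any():
            continue
        if mask.all():
            continue  # uniform grid: no boundary exists
        dist = ndimage.distance_transform_cdt(mask, metric="taxicab")
        out[mask] = dist[mask]
    return out
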