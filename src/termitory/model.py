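"""Seasonal lattice model of subterranean termite foraging territories.

The model simulates competing foraging territories of *Coptotermes
formosanus* (Formosan subterranean termite) colonies on an L x L lattice.
Each cell is EMPTY, ACTIVE (a live tunneling tip able to extend the
territory) or INACTIVE (occupied but no longer growing).  A static random
landscape assigns every cell a tunneling-ease probability ``P_trans`` in
[0, 1].  Seasons alternate as a step function:

* **summer** (``T_summer`` synchronous steps): every active cell attempts to
  colonize one empty Moore neighbor, chosen with probability proportional
  to the neighbors' ``P_trans`` and succeeding with probability
  ``P_trans`` of the chosen target; territories may never overlap, and
  contested cells are awarded uniformly among the competing territories.
  An active cell whose attempt fails, or that is walled in by >= 7 inactive
  neighbors, turns inactive.
* **winter** (one step): each territory is pruned back to ``sigma`` percent
  of its cells, removing the cells farthest from the founding seed first;
  survivors all turn inactive, then a few distal cells are stochastically
  reactivated to restart growth at the next summer.

Climate forcing is encoded by the summer duration ``T_summer`` and the
winter retention fraction ``sigma``.  The analysis chain measures, per
(T, sigma, N) parameter combination, the replicate-averaged rank-size
distribution of territory sizes and its two-segment semi-log slope ``m``
(front-segment steepness = inequality among the large territories), and
clusters the (T, sigma, m) parameter surface with a Kohonen self-organizing
map followed by Ward linkage.

The module is laid out in the order the method runs: configuration ->
landscape & seeding -> summer growth -> winter shrinkage/reactivation ->
multi-season simulation -> territory/rank-size/slope analysis -> SOM +
Ward clustering -> parameter sweep -> file I/O and CLI.
"""

from __future__ import annotations

import argparse
import dataclasses
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster import hierarchy
from shapely.geometry import LineString, MultiPoint, Point, Polygon

__all__ = [
    "EMPTY", "ACTIVE", "INACTIVE", "CellState",
    "SimConfig", "Landscape", "CellGrid", "GrowthProposal", "SimulationResult",
    "generate_landscape", "place_seeds", "empty_grid",
    "propose_growth", "resolve_conflicts", "apply_state_changes",
    "summer_step", "run_summer", "winter_shrink", "reactivate",
    "run_simulation",
    "RankSizeDistribution", "SlopeFit",
    "territory_sizes", "rank_size_distribution", "fit_two_segment_slope",
    "convex_hull",
    "SOMConfig", "SOMGrid", "ClusterMap",
    "normalize_inputs", "unscale_inputs", "som_distance", "train_som",
    "initial_som_weights", "quantization_error",
    "ward_cluster", "project_clusters", "cluster_table",
    "SweepSpec", "run_sweep",
    "export_snapshot", "load_snapshot", "load_config",
    "cli_main", "main",
]

logger = logging.getLogger("termitory")

# --------------------------------------------------------------------------
# Cell states and configuration
# --------------------------------------------------------------------------


class CellState(IntEnum):
    """Lattice cell states."""

    EMPTY = 0
    ACTIVE = 1
    INACTIVE = 2


EMPTY = CellState.EMPTY
ACTIVE = CellState.ACTIVE
INACTIVE = CellState.INACTIVE

# Moore neighborhood: the 8 surrounding sites (row, col offsets).
_MOORE = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one seasonal simulation run.

    Parameters
    ----------
    L : int
        Lattice side length in cells (the field-calibrated runs use 200).
    N : int
        Number of founding pairs, i.e. territory seeds.
    T_summer : int
        Summer duration in synchronous iteration steps; 36 steps
        correspond to the summer season of New Orleans, Louisiana.
    sigma : float
        Percentage (0, 100] of each territory's cells retained after the
        winter shrinkage.
    n_react : int
        Number of cells reactivated per territory after shrinkage.
    n_cycles : int
        Maximum number of summer-winter cycles.
    steady_tol : float
        Relative change in total termite-cell count between consecutive
        post-summer censuses below which the run is declared steady.
    rng_seed : int
        Master random seed; the run is fully reproducible from it.
    """

    L: int = 200
    N: int = 30
    T_summer: int = 36
    sigma: float = 20.0
    n_react: int = 5
    n_cycles: int = 50
    steady_tol: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if not (1 <= self.N <= self.L * self.L):
            raise ValueError(f"N must be in [1, L^2]={self.L**2}, got {self.N}")
        if self.T_summer < 0:
            raise ValueError(f"T_summer must be >= 0, got {self.T_summer}")
        if not (0 < self.sigma <= 100):
            raise ValueError(f"sigma must be in (0, 100], got {self.sigma}")
        if self.n_react < 1:
            raise ValueError(f"n_react must be >= 1, got {self.n_react}")
        if self.n_cycles < 0:
            raise ValueError(f"n_cycles must be >= 0, got {self.n_cycles}")
        if self.steady_tol < 0:
            raise ValueError(f"steady_tol must be >= 0, got {self.steady_tol}")


@dataclass(frozen=True)
class Landscape:
    """Immutable L x L grid of tunneling-ease probabilities ``P_trans``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"landscape must be square 2-D, got shape {v.shape}")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("landscape values must lie in [0, 1]")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def L(self) -> int:
        return self.values.shape[0]


@dataclass
class CellGrid:
    """Mutable lattice state: cell states, territory labels and seeds.

    Invariants: ``label == 0`` exactly where ``state == EMPTY``; each
    occupied cell carries exactly one label (territories never overlap);
    seed positions are distinct.
    """

    state: np.ndarray
    label: np.ndarray
    seed_pos: np.ndarray  # (N, 2) int array of (row, col) founding cells

    @property
    def L(self) -> int:
        return self.state.shape[0]

    @property
    def N(self) -> int:
        return len(self.seed_pos)

    def copy(self) -> "CellGrid":
        return CellGrid(self.state.copy(), self.label.copy(), self.seed_pos.copy())

    def total_termite_cells(self) -> int:
        """Count of occupied (active + inactive) cells."""
        return int(np.count_nonzero(self.state != EMPTY))

    def validate(self) -> None:
        """Assert the label/state exclusivity invariants; raise on breach."""
        if not np.array_equal(self.label == 0, self.state == EMPTY):
            raise AssertionError("label==0 iff state==EMPTY violated")
        if len(np.unique(self.seed_pos, axis=0)) != len(self.seed_pos):
            raise AssertionError("seed positions are not distinct")


def empty_grid(L: int, N: int = 0) -> CellGrid:
    """All-empty L x L grid with room for ``N`` seeds (not yet placed)."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    return CellGrid(
        state=np.zeros((L, L), dtype=np.int8),
        label=np.zeros((L, L), dtype=np.int32),
        seed_pos=np.empty((0, 2), dtype=np.int64),
    )


@dataclass
class GrowthProposal:
    """Transient record of one active cell's growth attempt this step."""

    source: tuple[int, int]
    target: tuple[int, int] | None
    outcome: str  # "SUCCESS_PENDING" or "STOPPED"


@dataclass
class SimulationResult:
    """Output of :func:`run_simulation`.

    ``size_history`` holds one row per completed cycle (post-summer
    census) with one column per territory label 1..N.  ``final_grid`` is
    the post-summer grid of the last cycle run.
    """

    final_grid: CellGrid
    size_history: np.ndarray  # (cycles_run, N) int
    cycles_run: int
    steady: bool
    landscape: Landscape
    config: SimConfig


# --------------------------------------------------------------------------
# Landscape generation and seeding
# --------------------------------------------------------------------------


def generate_landscape(L: int, rng: np.random.Generator) -> Landscape:
    """Random landscape: i.i.d. uniform ``P_trans`` in [0, 1] per cell."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    return Landscape(rng.random((L, L)))


def place_seeds(grid: CellGrid, N: int, rng: np.random.Generator) -> CellGrid:
    """Introduce N founding pairs at distinct uniform positions.

    Each seed becomes an ACTIVE cell carrying its own territory label
    (1..N).  Returns a new grid; the input must be entirely empty.
    """
    L = grid.L
    if not (1 <= N <= L * L):
        raise ValueError(f"N must be in [1, L^2]={L*L}, got {N}")
    if np.any(grid.state != EMPTY):
        raise ValueError("place_seeds requires an all-empty grid")
    flat = rng.choice(L * L, size=N, replace=False)
    rows, cols = np.divmod(flat, L)
    out = grid.copy()
    out.state[rows, cols] = ACTIVE
    out.label[rows, cols] = np.arange(1, N + 1, dtype=np.int32)
    out.seed_pos = np.column_stack([rows, cols]).astype(np.int64)
    return out


# --------------------------------------------------------------------------
# Summer growth: proposals, conflicts, state changes
# --------------------------------------------------------------------------


def _neighbor_info(grid: CellGrid, land: Landscape, sources: np.ndarray):
    """Per-source Moore-neighbor coordinates, emptiness mask and weights.

    Off-lattice neighbors are treated as permanently non-empty (they never
    receive growth) and as non-inactive for the enclosure rule.
    """
    L = grid.L
    nbr = sources[:, None, :] + _MOORE[None, :, :]  # (A, 8, 2)
    in_bounds = (
        (nbr[..., 0] >= 0) & (nbr[..., 0] < L)
        & (nbr[..., 1] >= 0) & (nbr[..., 1] < L)
    )
    nr = np.clip(nbr[..., 0], 0, L - 1)
    nc = np.clip(nbr[..., 1], 0, L - 1)
    is_empty = in_bounds & (grid.state[nr, nc] == EMPTY)
    weights = np.where(is_empty, land.values[nr, nc], 0.0)
    return nbr, is_empty, weights


def propose_growth(
    source: tuple[int, int],
    grid: CellGrid,
    land: Landscape,
    rng: np.random.Generator,
) -> GrowthProposal:
    """One active cell's growth attempt.

    If the source has empty Moore neighbors, one target is sampled with
    probability proportional to its ``P_trans`` and the attempt succeeds
    with probability ``P_trans(target)`` (easy soils are both preferred
    and easier to tunnel into).  With no empty neighbor, or when every
    empty neighbor has ``P_trans`` exactly 0, the cell is STOPPED.
    """
    r, c = source
    if grid.state[r, c] != ACTIVE:
        raise ValueError(f"propose_growth source {source} is not ACTIVE")
    src = np.array([[r, c]], dtype=np.int64)
    nbr, is_empty, weights = _neighbor_info(grid, land, src)
    w = weights[0]
    total = w.sum()
    if total <= 0.0:
        return GrowthProposal(source=(r, c), target=None, outcome="STOPPED")
    # Sample target index proportional to P_trans, then Bernoulli success.
    u = rng.random() * total
    k = int(np.searchsorted(np.cumsum(w), u, side="right"))
    k = min(k, 7)
    tr, tc = int(nbr[0, k, 0]), int(nbr[0, k, 1])
    p = land.values[tr, tc]
    if rng.random() < p:
        return GrowthProposal(source=(r, c), target=(tr, tc), outcome="SUCCESS_PENDING")
    return GrowthProposal(source=(r, c), target=(tr, tc), outcome="STOPPED")


def _resolve_conflicts_idx(
    targets_flat: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices of winning proposals, one uniform winner per unique target.

    Uniformity follows from random permutation + first-occurrence choice.
    """
    n = len(targets_flat)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    perm = rng.permutation(n)
    _, first = np.unique(targets_flat[perm], return_index=True)
    return perm[first]


def resolve_conflicts(
    proposals: Sequence[GrowthProposal], rng: np.random.Generator
) -> dict[tuple[int, int], tuple[int, int]]:
    """Award each contested target to exactly one proposer, uniformly.

    Takes SUCCESS_PENDING proposals; losers are marked STOPPED in place.
    Territories can never share a site, so a single winner per target
    enforces exclusivity.  Returns target -> winning source.
    """
    props = list(proposals)
    for p in props:
        if p.outcome != "SUCCESS_PENDING":
            raise ValueError("resolve_conflicts expects SUCCESS_PENDING proposals")
    if not props:
        return {}
    targets = np.array([p.target for p in props], dtype=np.int64)
    flat = targets[:, 0] * (targets.max() + 1) + targets[:, 1]
    winners = set(_resolve_conflicts_idx(flat, rng).tolist())
    assignment: dict[tuple[int, int], tuple[int, int]] = {}
    for i, p in enumerate(props):
        if i in winners:
            assignment[p.target] = p.source
        else:
            p.outcome = "STOPPED"
    return assignment


def apply_state_changes(
    grid: CellGrid, stopped: Iterable[tuple[int, int]]
) -> CellGrid:
    """Active-to-inactive transitions after a growth round.

    Every cell whose attempt stopped this step turns INACTIVE, and every
    remaining active cell enclosed by >= 7 inactive Moore neighbors turns
    INACTIVE (a tunnel tip walled in by dead tunnel).  Labels never
    change.  Returns a new grid.
    """
    out = grid.copy()
    stopped = list(stopped)
    if stopped:
        arr = np.asarray(stopped, dtype=np.int64).reshape(-1, 2)
        if np.any(grid.state[arr[:, 0], arr[:, 1]] != ACTIVE):
            raise ValueError("stopped set contains non-ACTIVE cells")
        out.state[arr[:, 0], arr[:, 1]] = INACTIVE
    # Synchronous enclosure rule on the post-stop grid; off-lattice sites
    # do not count as inactive.
    kernel = np.ones((3, 3), dtype=np.int8)
    kernel[1, 1] = 0
    n_inactive = ndimage.convolve(
        (out.state == INACTIVE).astype(np.int8), kernel, mode="constant", cval=0
    )
    enclosed = (out.state == ACTIVE) & (n_inactive >= 7)
    out.state[enclosed] = INACTIVE
    return out


def summer_step(
    grid: CellGrid, land: Landscape, rng: np.random.Generator
) -> CellGrid:
    """One synchronous summer round over all active cells.

    All active cells propose simultaneously; conflicts are resolved;
    each winning target becomes ACTIVE with its source's label (the
    source stays active — a multiplication, not a move); then failed
    proposers and enclosed cells turn INACTIVE.  The total termite-cell
    count never decreases.
    """
    sources = np.argwhere(grid.state == ACTIVE)
    if len(sources) == 0:
        return grid.copy()
    nbr, is_empty, weights = _neighbor_info(grid, land, sources)
    wsum = weights.sum(axis=1)
    has_target = wsum > 0.0

    # Vectorized categorical sampling of one target per source.
    cum = np.cumsum(weights, axis=1)
    u = rng.random(len(sources)) * wsum
    choice = np.minimum((cum > u[:, None]).argmax(axis=1), 7)
    t_r = nbr[np.arange(len(sources)), choice, 0]
    t_c = nbr[np.arange(len(sources)), choice, 1]
    p_target = np.where(has_target, land.values[np.clip(t_r, 0, grid.L - 1),
                                                np.clip(t_c, 0, grid.L - 1)], 0.0)
    success = has_target & (rng.random(len(sources)) < p_target)

    out = grid.copy()
    stopped_mask = ~success
    succ_idx = np.flatnonzero(success)
    if len(succ_idx):
        flat_targets = t_r[succ_idx] * grid.L + t_c[succ_idx]
        win_local = _resolve_conflicts_idx(flat_targets, rng)
        winners = succ_idx[win_local]
        losers = np.setdiff1d(succ_idx, winners, assume_unique=False)
        stopped_mask[losers] = True
        wr, wc = t_r[winners], t_c[winners]
        out.state[wr, wc] = ACTIVE
        out.label[wr, wc] = grid.label[sources[winners, 0], sources[winners, 1]]
    stopped_cells = sources[stopped_mask]
    return apply_state_changes(out, [tuple(x) for x in stopped_cells])


def run_summer(
    grid: CellGrid, land: Landscape, T_summer: int, rng: np.random.Generator
) -> CellGrid:
    """Apply ``T_summer`` sequential synchronous growth rounds."""
    if T_summer < 0:
        raise ValueError(f"T_summer must be >= 0, got {T_summer}")
    for _ in range(T_summer):
        grid = summer_step(grid, land, rng)
    return grid


# --------------------------------------------------------------------------
# Winter: shrinkage and reactivation
# --------------------------------------------------------------------------


def _territory_coords(grid: CellGrid, t: int) -> np.ndarray:
    return np.argwhere(grid.label == t)


def winter_shrink(
    grid: CellGrid, sigma: float, rng: np.random.Generator | None = None
) -> CellGrid:
    """Winter contraction: prune each territory back to ``sigma`` percent.

    Independently per territory, cells are removed in order of decreasing
    Euclidean distance from the founding seed until exactly
    ``max(1, round(sigma/100 * size))`` cells remain (half-up rounding;
    distance ties broken uniformly at random).  The seed always survives.
    All survivors become INACTIVE — only subsequently reactivated cells
    restart growth.  Completes in a single winter step.
    """
    if not (0 < sigma <= 100):
        raise ValueError(f"sigma must be in (0, 100], got {sigma}")
    if rng is None:
        rng = np.random.default_rng()
    out = grid.copy()
    for t in range(1, grid.N + 1):
        coords = _territory_coords(grid, t)
        size = len(coords)
        if size == 0:
            continue
        keep = max(1, int(np.floor(sigma / 100.0 * size + 0.5)))
        seed = grid.seed_pos[t - 1]
        d = np.hypot(coords[:, 0] - seed[0], coords[:, 1] - seed[1])
        # Ascending distance, random tie-break; the first `keep` survive.
        order = np.lexsort((rng.random(size), d))
        removed = coords[order[keep:]]
        out.state[removed[:, 0], removed[:, 1]] = EMPTY
        out.label[removed[:, 0], removed[:, 1]] = 0
        survivors = coords[order[:keep]]
        out.state[survivors[:, 0], survivors[:, 1]] = INACTIVE
    return out


def reactivate(
    grid: CellGrid, n_react: int, rng: np.random.Generator
) -> CellGrid:
    """Reactivate distal cells to restart growth after the winter.

    Per territory, ``min(n_react, size)`` cells are sampled without
    replacement with probability proportional to Euclidean distance from
    the seed (new tunnels most likely start at the colony periphery).
    The seed itself has weight 0 unless it is the only cell; when all
    remaining weights are zero the draw falls back to uniform.
    """
    if np.any(grid.state == ACTIVE):
        raise ValueError("reactivate expects a grid with no ACTIVE cells")
    out = grid.copy()
    for t in range(1, grid.N + 1):
        coords = _territory_coords(grid, t)
        size = len(coords)
        if size == 0:
            continue
        k = min(n_react, size)
        seed = grid.seed_pos[t - 1]
        w = np.hypot(coords[:, 0] - seed[0], coords[:, 1] - seed[1])
        chosen = _weighted_sample_without_replacement(w, k, rng)
        sel = coords[chosen]
        out.state[sel[:, 0], sel[:, 1]] = ACTIVE
    return out


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Sequential weighted draws; uniform fallback once weights exhaust."""
    n = len(weights)
    avail = np.ones(n, dtype=bool)
    w = weights.astype(np.float64).copy()
    picks = np.empty(k, dtype=np.int64)
    for i in range(k):
        wa = np.where(avail, w, 0.0)
        total = wa.sum()
        if total > 0:
            u = rng.random() * total
            pick = int(np.searchsorted(np.cumsum(wa), u, side="right"))
            pick = min(pick, n - 1)
            # Guard against landing on an unavailable cell via fp round-off.
            if not avail[pick]:
                pick = int(np.flatnonzero(avail & (w > 0))[0])
        else:
            pick = int(rng.choice(np.flatnonzero(avail)))
        picks[i] = pick
        avail[pick] = False
    return picks


# --------------------------------------------------------------------------
# Multi-season simulation
# --------------------------------------------------------------------------


def run_simulation(config: SimConfig) -> SimulationResult:
    """Run seasonal cycles until steady state or the cycle cap.

    One cycle is summer (``T_summer`` synchronous steps) -> winter
    shrinkage (one step) -> reactivation.  The census is taken at the end
    of each summer; the run is steady when the relative change in total
    termite-cell count between consecutive post-summer censuses falls
    below ``steady_tol``.  The returned grid is the post-summer grid of
    the last cycle, fully reproducible from ``rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    land = generate_landscape(config.L, rng)
    grid = place_seeds(empty_grid(config.L), config.N, rng)

    history: list[np.ndarray] = []
    steady = False
    prev_total: int | None = None
    cycles_run = 0
    for cycle in range(config.n_cycles):
        grid = run_summer(grid, land, config.T_summer, rng)
        sizes = _census(grid)
        history.append(sizes)
        cycles_run += 1
        total = int(sizes.sum())
        logger.info("cycle %d: total termite cells = %d", cycle + 1, total)
        for t, s in enumerate(sizes, start=1):
            logger.debug("cycle %d territory %d size %d", cycle + 1, t, s)
        if prev_total is not None:
            rel = abs(total - prev_total) / max(prev_total, 1)
            if rel < config.steady_tol:
                steady = True
                break
        prev_total = total
        if cycle == config.n_cycles - 1:
            break
        grid = winter_shrink(grid, config.sigma, rng)
        grid = reactivate(grid, config.n_react, rng)

    size_history = (
        np.array(history, dtype=np.int64)
        if history
        else np.empty((0, config.N), dtype=np.int64)
    )
    return SimulationResult(
        final_grid=grid,
        size_history=size_history,
        cycles_run=cycles_run,
        steady=steady,
        landscape=land,
        config=config,
    )


def _census(grid: CellGrid) -> np.ndarray:
    """Occupied-cell counts per territory label 1..N."""
    occ = grid.state != EMPTY
    return np.bincount(grid.label[occ], minlength=grid.N + 1)[1:].astype(np.int64)


# --------------------------------------------------------------------------
# Territory analysis: sizes, rank-size distribution, two-segment slope
# --------------------------------------------------------------------------


@dataclass
class RankSizeDistribution:
    """Replicate-averaged territory sizes <A> in descending rank order."""

    ranks: np.ndarray  # 1..N
    mean_size: np.ndarray  # non-increasing
    n_replicates: int


@dataclass
class SlopeFit:
    """Two-regime semi-log fit of a rank-size distribution.

    ``breakpoint`` is the last rank of the front (large-size) segment;
    ``m_front``/``m_rear`` are the absolute slopes of ln(mean size) vs
    rank for each segment; ``sse`` is the summed residual of both fits.
    """

    breakpoint: int
    m_front: float
    m_rear: float
    sse: float


def territory_sizes(grid: CellGrid) -> dict[int, int]:
    """Occupied (active + inactive) cell count per territory label.

    Labels with no surviving cells are reported as 0.
    """
    counts = _census(grid)
    return {t: int(counts[t - 1]) for t in range(1, grid.N + 1)}


def rank_size_distribution(
    size_maps: Sequence[Mapping[int, int] | Sequence[int] | np.ndarray],
) -> RankSizeDistribution:
    """Rank-wise mean of descending-sorted sizes across replicates.

    Within each replicate the territory sizes are sorted in descending
    order; the mean <A> is then taken rank by rank.  All replicates must
    contain the same number of territories.
    """
    if not size_maps:
        raise ValueError("need at least one replicate")
    arrays = []
    for m in size_maps:
        vals = np.asarray(
            list(m.values()) if isinstance(m, Mapping) else m, dtype=np.float64
        )
        arrays.append(np.sort(vals)[::-1])
    n = {len(a) for a in arrays}
    if len(n) != 1:
        raise ValueError(f"replicates disagree on territory count: {sorted(n)}")
    stacked = np.vstack(arrays)
    mean = stacked.mean(axis=0)
    return RankSizeDistribution(
        ranks=np.arange(1, stacked.shape[1] + 1),
        mean_size=mean,
        n_replicates=len(arrays),
    )


def fit_two_segment_slope(
    dist: RankSizeDistribution | np.ndarray | Sequence[float],
) -> SlopeFit:
    """Two-segment least-squares fit of ln <A> against rank.

    Candidate breakpoints b = 2..N-2 split the ranks into a front segment
    (1..b, the large territories) and a rear segment (b+1..N); each gets
    an ordinary least-squares line on the semi-log scale and the
    breakpoint minimizing the total SSE wins (smallest breakpoint on
    ties).  ``m_front`` is the absolute front-segment slope — the measure
    of size inequality among the large territories.
    """
    sizes = (
        dist.mean_size if isinstance(dist, RankSizeDistribution) else np.asarray(dist, dtype=np.float64)
    )
    sizes = np.asarray(sizes, dtype=np.float64)
    if np.any(sizes == 0):
        warnings.warn(
            "dropping zero-size territories before log transform", stacklevel=2
        )
        sizes = sizes[sizes > 0]
    if np.any(sizes < 0):
        raise ValueError("territory sizes must be non-negative")
    N = len(sizes)
    if N < 4:
        raise ValueError(f"need at least 4 positive sizes, got {N}")
    x = np.arange(1, N + 1, dtype=np.float64)
    y = np.log(sizes)

    best: SlopeFit | None = None
    for b in range(2, N - 1):  # front = ranks 1..b, rear = b+1..N
        sf, if_, sse_f = _ols_line(x[:b], y[:b])
        sr, ir, sse_r = _ols_line(x[b:], y[b:])
        sse = sse_f + sse_r
        if best is None or sse < best.sse - 1e-15:
            best = SlopeFit(
                breakpoint=b, m_front=abs(sf), m_rear=abs(sr), sse=float(sse)
            )
    assert best is not None
    return best


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line; returns (slope, intercept, SSE)."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(resid @ resid)


def convex_hull(cells: Sequence[tuple[int, int]] | np.ndarray) -> np.ndarray:
    """Convex hull of territory member cell centers (visualization only).

    Returns the hull vertices as an (k, 2) array; degenerate inputs give
    a single vertex (one cell) or the two segment endpoints (collinear
    cells).  Every member lies inside or on the hull.
    """
    pts = np.asarray(cells, dtype=np.float64).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("convex_hull requires at least one cell")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if isinstance(hull, Point):
        return np.array([[hull.x, hull.y]])
    if isinstance(hull, LineString):
        return np.asarray(hull.coords, dtype=np.float64)
    assert isinstance(hull, Polygon)
    return np.asarray(hull.exterior.coords, dtype=np.float64)[:-1]


# --------------------------------------------------------------------------
# SOM + Ward clustering of the (T, sigma, m) parameter surface
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SOMConfig:
    """Kohonen map hyperparameters.

    The map is a rows x cols lattice of prototype vectors.  The learning
    rate decays linearly from ``alpha0`` to ``alpha_end`` and the
    Gaussian neighborhood radius linearly from ``radius0`` (default
    max(rows, cols)/2) to ``radius_end`` over ``n_iter`` presentations.
    """

    rows: int = 6
    cols: int = 7
    n_iter: int = 10_000
    alpha0: float = 0.5
    alpha_end: float = 0.01
    radius0: float | None = None
    radius_end: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 2:
            raise ValueError("SOM needs at least 2 nodes")
        if not (0 <= self.alpha_end <= self.alpha0):
            raise ValueError("need 0 <= alpha_end <= alpha0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    def alpha(self, t: int) -> float:
        """Learning rate at presentation t (strictly decreasing)."""
        frac = t / max(self.n_iter - 1, 1)
        return self.alpha0 + (self.alpha_end - self.alpha0) * frac

    def radius(self, t: int) -> float:
        r0 = self.radius0 if self.radius0 is not None else max(self.rows, self.cols) / 2
        frac = t / max(self.n_iter - 1, 1)
        return max(r0 + (self.radius_end - r0) * frac, 1e-9)


@dataclass
class SOMGrid:
    """Trained map: per-node weight vectors plus the input scaling."""

    weights: np.ndarray  # (rows*cols, P), row-major node order
    rows: int
    cols: int
    input_names: tuple[str, ...]
    scale_min: np.ndarray
    scale_max: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_coords(self) -> np.ndarray:
        r, c = np.divmod(np.arange(self.n_nodes), self.cols)
        return np.column_stack([r, c])

    def bmu(self, x: np.ndarray) -> int:
        """Best-matching unit: minimal Euclidean distance, ties to the
        lowest node index."""
        d = np.linalg.norm(self.weights - np.asarray(x, dtype=np.float64), axis=1)
        return int(np.argmin(d))


@dataclass
class ClusterMap:
    """Ward partition of the SOM nodes into k clusters (ids 1..k)."""

    assignments: np.ndarray  # (n_nodes,) ints in 1..k
    k: int
    merge_heights: np.ndarray  # Ward merge cost sequence (non-decreasing)


def normalize_inputs(
    records: Sequence[Sequence[float]] | np.ndarray,
    names: tuple[str, ...] = ("T", "sigma", "m"),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Min-max scale each input parameter to [0, 1].

    Scaling is essential here: raw T and sigma (tens) would otherwise
    swamp m (order 0.1) in the Euclidean distance.  A constant column
    maps to all zeros.  Returns (scaled, mins, maxs).
    """
    X = np.asarray(records, dtype=np.float64)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need at least 2 records of equal length")
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    span = maxs - mins
    scaled = np.where(span > 0, (X - mins) / np.where(span > 0, span, 1.0), 0.0)
    return scaled, mins, maxs


def unscale_inputs(
    scaled: np.ndarray, mins: np.ndarray, maxs: np.ndarray
) -> np.ndarray:
    """Inverse of :func:`normalize_inputs` (constant columns return min)."""
    return mins + np.asarray(scaled, dtype=np.float64) * (maxs - mins)


def som_distance(weight: np.ndarray, x: np.ndarray) -> float:
    """Euclidean distance between a node weight vector and an input."""
    w = np.asarray(weight, dtype=np.float64)
    v = np.asarray(x, dtype=np.float64)
    if w.shape != v.shape:
        raise ValueError(f"length mismatch: {w.shape} vs {v.shape}")
    return float(np.linalg.norm(v - w))


def initial_som_weights(config: SOMConfig, P: int) -> np.ndarray:
    """Small random initial weight vectors, reproducible from the seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    return rng.random((config.rows * config.cols, P)) * 0.1


def _som_step(
    weights: np.ndarray,
    node_rc: np.ndarray,
    x: np.ndarray,
    alpha: float,
    radius: float,
) -> int:
    """One Kohonen update in place; returns the best-matching unit.

    w(t+1) = w(t) + alpha * h * (x - w(t)) with Gaussian neighborhood h
    on the map-grid distance from the winner.  BMU ties resolve to the
    lowest node index.
    """
    d = np.linalg.norm(weights - x, axis=1)
    bmu = int(np.argmin(d))
    grid_d2 = ((node_rc - node_rc[bmu]) ** 2).sum(axis=1)
    h = np.exp(-grid_d2 / (2.0 * radius * radius))
    weights += alpha * h[:, None] * (x - weights)
    return bmu


def train_som(
    vectors: np.ndarray,
    config: SOMConfig,
    input_names: tuple[str, ...] = ("T", "sigma", "m"),
    scale_min: np.ndarray | None = None,
    scale_max: np.ndarray | None = None,
) -> SOMGrid:
    """Online Kohonen training on unit-scaled input vectors.

    Per presentation a random input is drawn, its best-matching unit
    (minimum Euclidean distance, ties to the lowest node index) found,
    and the winner plus its Gaussian map-grid neighborhood pulled toward
    the input: w(t+1) = w(t) + alpha(t) * h(t) * (x - w(t)), with
    alpha(t) strictly decreasing.  Deterministic given ``rng_seed``.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("training vectors must be a non-empty 2-D array")
    P = X.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    n_nodes = config.rows * config.cols
    weights = rng.random((n_nodes, P)) * 0.1  # small random initial weights
    node_rc = np.column_stack(np.divmod(np.arange(n_nodes), config.cols)).astype(float)

    for t in range(config.n_iter):
        x = X[rng.integers(len(X))]
        _som_step(weights, node_rc, x, config.alpha(t), config.radius(t))

    if scale_min is None:
        scale_min = np.zeros(P)
    if scale_max is None:
        scale_max = np.ones(P)
    return SOMGrid(
        weights=weights,
        rows=config.rows,
        cols=config.cols,
        input_names=tuple(input_names),
        scale_min=np.asarray(scale_min, dtype=np.float64),
        scale_max=np.asarray(scale_max, dtype=np.float64),
    )


def quantization_error(weights: np.ndarray, X: np.ndarray) -> float:
    """Mean distance from each input to its best-matching node."""
    d = np.linalg.norm(X[:, None, :] - weights[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def ward_cluster(som: SOMGrid, k: int) -> ClusterMap:
    """Ward minimum-variance clustering of the trained prototypes.

    Agglomerative Ward linkage on the node weight vectors, cut at k
    clusters; every cluster is non-empty.
    """
    n = som.n_nodes
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    Z = hierarchy.linkage(som.weights, method="ward")
    assignments = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(assignments)) != k:
        raise RuntimeError("Ward cut produced an empty cluster")
    return ClusterMap(
        assignments=assignments.astype(np.int64),
        k=k,
        merge_heights=Z[:, 2].copy(),
    )


def project_clusters(
    records: np.ndarray, som: SOMGrid, clusters: ClusterMap
) -> pd.DataFrame:
    """Map each (T, sigma, m) record to its best-matching node's cluster.

    ``records`` are raw (unscaled) values; they are scaled with the
    constants stored in the trained map.  Returns a tidy frame with
    columns T, sigma, m, node, cluster.
    """
    X = np.asarray(records, dtype=np.float64)
    span = som.scale_max - som.scale_min
    scaled = np.where(span > 0, (X - som.scale_min) / np.where(span > 0, span, 1.0), 0.0)
    nodes = np.array([som.bmu(x) for x in scaled])
    return pd.DataFrame(
        {
            "T": X[:, 0],
            "sigma": X[:, 1],
            "m": X[:, 2],
            "node": nodes,
            "cluster": clusters.assignments[nodes],
        }
    )


def cluster_table(projection: pd.DataFrame) -> pd.DataFrame:
    """Pivot a projection into the (T rows) x (sigma columns) cluster map."""
    return projection.pivot_table(
        index="T", columns="sigma", values="cluster", aggfunc="first"
    ).astype("Int64")


# --------------------------------------------------------------------------
# Parameter sweep
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepSpec:
    """Factorial (T, sigma, N) sweep with replicate runs.

    Defaults follow the study grid: T and sigma from 10 to 50 in steps of
    5, N in {30, 50, 70, 90}, 50 replicate runs per combination.
    """

    T_values: tuple[int, ...] = tuple(range(10, 55, 5))
    sigma_values: tuple[int, ...] = tuple(range(10, 55, 5))
    N_values: tuple[int, ...] = (30, 50, 70, 90)
    n_replicates: int = 50
    base: SimConfig = field(default_factory=SimConfig)
    master_seed: int = 0
    slope_mode: str = "averaged"  # or "per_replicate"

    def __post_init__(self) -> None:
        if not (self.T_values and self.sigma_values and self.N_values):
            raise ValueError("all sweep value lists must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.slope_mode not in ("averaged", "per_replicate"):
            raise ValueError(f"unknown slope_mode {self.slope_mode!r}")


def _replicate_seed(master: int, N: int, T: int, sigma: int, rep: int) -> int:
    """Order-independent substream seed for one replicate."""
    ss = np.random.SeedSequence([int(master), int(N), int(T), int(sigma), int(rep)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the full factorial sweep and fit the slope per combination.

    For each (N, T, sigma) combination, ``n_replicates`` independent
    simulations are run on substream seeds derived from the master seed
    (order-independent), the replicate size maps aggregated into a
    rank-size distribution, and the two-segment semi-log slope fitted.
    In ``per_replicate`` mode the slope is instead fitted to each
    replicate's own distribution and averaged.  Rows come out in
    deterministic (N, T, sigma) order.
    """
    rows = []
    for N in spec.N_values:
        for T in spec.T_values:
            for sigma in spec.sigma_values:
                size_maps = []
                totals = []
                for rep in range(spec.n_replicates):
                    cfg = dataclasses.replace(
                        spec.base,
                        N=N,
                        T_summer=T,
                        sigma=float(sigma),
                        rng_seed=_replicate_seed(spec.master_seed, N, T, sigma, rep),
                    )
                    res = run_simulation(cfg)
                    sizes = territory_sizes(res.final_grid)
                    size_maps.append(sizes)
                    totals.append(sum(sizes.values()))
                if spec.slope_mode == "averaged":
                    dist = rank_size_distribution(size_maps)
                    fit = fit_two_segment_slope(dist)
                    m_front, m_rear, bp = fit.m_front, fit.m_rear, fit.breakpoint
                else:
                    fits = [
                        fit_two_segment_slope(np.sort(np.array(list(sm.values())))[::-1])
                        for sm in size_maps
                    ]
                    m_front = float(np.mean([f.m_front for f in fits]))
                    m_rear = float(np.mean([f.m_rear for f in fits]))
                    bp = int(np.median([f.breakpoint for f in fits]))
                rows.append(
                    {
                        "N": N,
                        "T": T,
                        "sigma": sigma,
                        "n_replicates": spec.n_replicates,
                        "m_front": m_front,
                        "m_rear": m_rear,
                        "breakpoint": bp,
                        "mean_total_size": float(np.mean(totals)),
                    }
                )
                logger.info(
                    "sweep N=%d T=%d sigma=%d: m_front=%.4f", N, T, sigma, m_front
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# File I/O: config loading, snapshots
# --------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Read a JSON or YAML run-configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def export_snapshot(
    result: SimulationResult, out_dir: str | Path, png: bool = False
) -> list[Path]:
    """Write a simulation snapshot as plain-text matrices (+ optional PNG).

    Produces ``state.txt`` and ``label.txt`` (integer matrices),
    ``landscape.txt`` (float matrix), ``sizes.csv`` (cycle, territory,
    size) and ``meta.json``; with ``png=True`` also a territory render
    with one color per territory and enclosed empty cells marked.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = result.final_grid
    written = []
    for name, arr, fmt in [
        ("state.txt", grid.state, "%d"),
        ("label.txt", grid.label, "%d"),
        ("landscape.txt", result.landscape.values, "%.8f"),
    ]:
        p = out / name
        np.savetxt(p, arr, fmt=fmt)
        written.append(p)

    hist = result.size_history
    records = [
        {"cycle": c + 1, "territory": t + 1, "size": int(hist[c, t])}
        for c in range(hist.shape[0])
        for t in range(hist.shape[1])
    ]
    sizes_path = out / "sizes.csv"
    pd.DataFrame(records, columns=["cycle", "territory", "size"]).to_csv(
        sizes_path, index=False
    )
    written.append(sizes_path)

    meta_path = out / "meta.json"
    meta = dataclasses.asdict(result.config)
    meta.update(
        {
            "cycles_run": result.cycles_run,
            "steady": bool(result.steady),
            "seed_pos": grid.seed_pos.tolist(),
        }
    )
    meta_path.write_text(json.dumps(meta, indent=2))
    written.append(meta_path)

    if png:
        written.append(_render_png(result, out / "territories.png"))
    return written


def _render_png(result: SimulationResult, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    grid = result.final_grid
    N = grid.N
    cmap = colormaps["tab20"].resampled(max(N, 1))
    img = np.ones((grid.L, grid.L, 3))
    occ = grid.state != EMPTY
    colors = cmap(np.linspace(0, 1, max(N, 1)))[:, :3]
    img[occ] = colors[(grid.label[occ] - 1) % max(N, 1)]
    # Enclosed empty cells (inside a territory hull) rendered black.
    enclosed = _enclosed_empty_mask(grid)
    img[enclosed] = 0.0
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def _enclosed_empty_mask(grid: CellGrid) -> np.ndarray:
    """Empty cells fully surrounded by territory (no path to the border)."""
    empty = grid.state == EMPTY
    reach = np.zeros_like(empty)
    # Flood-fill emptiness from the border; the unreachable remainder is
    # enclosed inside territories.
    lbl, n = ndimage.label(empty)
    border_labels = np.unique(
        np.concatenate([lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]])
    )
    border_labels = border_labels[border_labels > 0]
    reach = np.isin(lbl, border_labels)
    return empty & ~reach


def load_snapshot(out_dir: str | Path) -> CellGrid:
    """Re-read the plain-text state/label matrices into a CellGrid."""
    out = Path(out_dir)
    state = np.loadtxt(out / "state.txt", dtype=np.int8, ndmin=2)
    label = np.loadtxt(out / "label.txt", dtype=np.int32, ndmin=2)
    meta = json.loads((out / "meta.json").read_text())
    seed_pos = np.asarray(meta["seed_pos"], dtype=np.int64).reshape(-1, 2)
    return CellGrid(state=state, label=label, seed_pos=seed_pos)


# --------------------------------------------------------------------------
# Command-line interface
# --------------------------------------------------------------------------

_DESK_PRESET = {
    "L": 100,
    "n_replicates": 20,
    "sigma_values": tuple(range(10, 60, 10)),
}


def _build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="termitory",
        description="Seasonal termite-territory lattice simulator and analysis",
    )
    p.add_argument("--verbose", action="store_true", help="debug logging")
    p.add_argument("--quiet", action="store_true", help="warnings only")
    sub = p.add_subparsers(dest="command", required=True)

    sim = sub.add_parser("simulate", help="run one simulation, write a snapshot")
    sim.add_argument("--config", type=Path, help="JSON/YAML SimConfig mapping")
    sim.add_argument("--out", type=Path, default=Path("out"), help="output dir")
    sim.add_argument("--seed", type=int, default=None, help="override rng_seed")
    sim.add_argument("--png", action="store_true", help="also render a PNG")

    sw = sub.add_parser("sweep", help="factorial (T, sigma, N) sweep")
    sw.add_argument("--config", type=Path, help="JSON/YAML SweepSpec mapping")
    sw.add_argument("--out", type=Path, default=Path("out"))
    sw.add_argument("--seed", type=int, default=None, help="override master seed")
    sw.add_argument("--replicates", type=int, default=None)
    sw.add_argument(
        "--preset",
        choices=["desk"],
        default=None,
        help="desk: L=100, 20 replicates, sigma in {10,20,30,40,50}",
    )

    an = sub.add_parser("analyze", help="rank-size distribution + slope fit")
    an.add_argument(
        "--sizes",
        type=Path,
        required=True,
        help="CSV with columns replicate, territory, size",
    )
    an.add_argument("--out", type=Path, default=Path("out"))

    so = sub.add_parser("som", help="SOM + Ward clustering of a sweep table")
    so.add_argument("--sweep", type=Path, required=True, help="run_sweep CSV")
    so.add_argument("--out", type=Path, default=Path("out"))
    so.add_argument("--k", type=int, default=8)
    so.add_argument("--seed", type=int, default=0)
    so.add_argument("--iters", type=int, default=10_000)
    return p


def _sim_config_from_file(path: Path | None, seed: int | None) -> SimConfig:
    data = load_config(path) if path else {}
    if seed is not None:
        data["rng_seed"] = seed
    allowed = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(**data)


def _sweep_spec_from_args(args) -> SweepSpec:
    data = load_config(args.config) if args.config else {}
    base = SimConfig(**data.pop("base", {}))
    if args.preset == "desk":
        base = dataclasses.replace(base, L=_DESK_PRESET["L"])
        data.setdefault("n_replicates", _DESK_PRESET["n_replicates"])
        data.setdefault("sigma_values", _DESK_PRESET["sigma_values"])
    if args.replicates is not None:
        data["n_replicates"] = args.replicates
    if args.seed is not None:
        data["master_seed"] = args.seed
    for key in ("T_values", "sigma_values", "N_values"):
        if key in data:
            data[key] = tuple(data[key])
    return SweepSpec(base=base, **data)


def cli_main(argv: Sequence[str] | None = None) -> int:
    """Entry point for the ``termitory`` command; returns an exit status."""
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as e:
        return int(e.code or 0)
    level = (
        logging.DEBUG if args.verbose else logging.WARNING if args.quiet else logging.INFO
    )
    logging.basicConfig(level=level, stream=sys.stderr, format="%(message)s")
    try:
        return _dispatch(args)
    except (ValueError, OSError, KeyError) as e:
        logger.error("error: %s", e)
        return 1


def _dispatch(args) -> int:
    if args.command == "simulate":
        cfg = _sim_config_from_file(args.config, args.seed)
        result = run_simulation(cfg)
        files = export_snapshot(result, args.out, png=args.png)
        logger.info("wrote %s", ", ".join(str(f) for f in files))
        return 0

    if args.command == "sweep":
        spec = _sweep_spec_from_args(args)
        table = run_sweep(spec)
        args.out.mkdir(parents=True, exist_ok=True)
        path = args.out / "sweep.csv"
        table.to_csv(path, index=False)
        logger.info("wrote %s (%d rows)", path, len(table))
        return 0

    if args.command == "analyze":
        df = pd.read_csv(args.sizes)
        maps = [g["size"].to_numpy() for _, g in df.groupby("replicate")]
        dist = rank_size_distribution(maps)
        fit = fit_two_segment_slope(dist)
        args.out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"rank": dist.ranks, "mean_size": dist.mean_size}).to_csv(
            args.out / "ranksize.csv", index=False
        )
        pd.DataFrame(
            [
                {
                    "breakpoint": fit.breakpoint,
                    "m_front": fit.m_front,
                    "m_rear": fit.m_rear,
                    "sse": fit.sse,
                }
            ]
        ).to_csv(args.out / "slopefit.csv", index=False)
        logger.info("m_front=%.4f at breakpoint %d", fit.m_front, fit.breakpoint)
        return 0

    if args.command == "som":
        table = pd.read_csv(args.sweep)
        args.out.mkdir(parents=True, exist_ok=True)
        for N, g in table.groupby("N"):
            records = g[["T", "sigma", "m_front"]].to_numpy(dtype=np.float64)
            scaled, mins, maxs = normalize_inputs(records)
            som = train_som(
                scaled,
                SOMConfig(n_iter=args.iters, rng_seed=args.seed),
                scale_min=mins,
                scale_max=maxs,
            )
            clusters = ward_cluster(som, args.k)
            proj = project_clusters(records, som, clusters)
            rc = som.node_coords()
            pd.DataFrame(
                {
                    "node_row": rc[:, 0],
                    "node_col": rc[:, 1],
                    "w_T": som.weights[:, 0],
                    "w_sigma": som.weights[:, 1],
                    "w_m": som.weights[:, 2],
                    "cluster": clusters.assignments,
                }
            ).to_csv(args.out / f"som_nodes_N{N}.csv", index=False)
            cluster_table(proj).to_csv(args.out / f"cluster_map_N{N}.csv")
            logger.info("N=%d: %d clusters over %d nodes", N, clusters.k, som.n_nodes)
        return 0

    raise ValueError(f"unknown command {args.command!r}")


def main() -> None:
    sys.exit(cli_main())


if __name__ == "__main__":
    main()
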