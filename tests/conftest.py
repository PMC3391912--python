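import numpy as np
import pytest

from termitory import CellGrid, Landscape, empty_grid
from termitory.model import ACTIVE, INACTIVE


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def uniform_landscape():
    """Factory for a constant-P_trans landscape (deterministic toy soil)."""

    def make(L: int, value: float = 1.0) -> Landscape:
        return Landscape(np.full((L, L), value))

    return make


def build_grid(L: int, territories: dict[int, list[tuple[int, int]]],
               seeds: dict[int, tuple[int, int]],
               active: set[tuple[int, int]] = frozenset()) -> CellGrid:
    """Hand-built grid: territory label -> member cells, label -> seed cell.

    Members are INACTIVE unless listed in ``active``.  Seeds must be
    members of their territory.
    """
    grid = empty_grid(L)
    n = max(territories) if territories else 0
    seed_pos = np.zeros((n, 2), dtype=np.int64)
    for t, cells in territories.items():
        assert seeds[t] in cells
        for rc in cells:
            grid.state[rc] = ACTIVE if rc in active else INACTIVE
            grid.label[rc] = t
        seed_pos[t - 1] = seeds[t]
    grid.seed_pos = seed_pos
    return grid


@pytest.fixture
def two_territory_grid():
    """3- and 7-cell territories on a 10x10 lattice."""
    return build_grid(
        10,
        territories={
            1: [(1, 1), (1, 2), (2, 1)],
            2: [(6, 6), (6, 7), (6, 8), (7, 6), (7, 7), (7, 8), (8, 6)],
        },
        seeds={1: (1, 1), 2: (7, 7)},
    )
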