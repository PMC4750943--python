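import numpy as np
import pytest

from spherosim.cells import Cell, CellState, Population
from spherosim.lattice import Lattice, build_lattice


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def regular9():
    """9^3 zero-jitter lattice (regular 6-neighbor grid)."""
    return build_lattice(9, spacing=16.8, jitter=0.0, seed=0)


@pytest.fixture
def jittered10():
    return build_lattice(10, spacing=16.8, jitter=0.2, seed=1)


def occupy_ball(lattice: Lattice, radius_sites: float,
                state: CellState = CellState.CYCLING) -> Population:
    """Populate all sites within radius_sites * spacing of the lattice
    center with single-site cells; returns the population and attaches
    the id registry the engine uses."""
    pop = Population()
    registry = {}
    lattice._registry = registry
    interior = np.flatnonzero(~lattice.is_boundary)
    center = lattice.positions[interior].mean(axis=0)
    d = np.linalg.norm(lattice.positions - center, axis=1)
    chosen = [s for s in interior
              if d[s] <= radius_sites * lattice.spacing + 1e-9]
    for s in chosen:
        c = pop.new_cell(int(s), state=state)
        lattice.occupant[s] = c.id
        registry[c.id] = c
    return pop


def path_lattice():
    """Tiny hand-built 3-site path graph 0-1-2 (for exact CTMC checks)."""
    positions = np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
    indptr = np.array([0, 1, 3, 4])
    indices = np.array([1, 0, 2, 1])
    return Lattice(positions=positions, indptr=indptr, indices=indices,
                   spacing=10.0, n_per_dim=3, jitter=0.0, seed=0)
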