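"""Cell agents and their exact stochastic dynamics.

Every process — cell-cycle stage advance, death, lysis, migration — is a
Poisson process; the population evolves by the Gillespie stochastic
simulation algorithm (exponential waiting time at the total rate, event
chosen with probability proportional to its rate).

The cell cycle is an Erlang clock: ``m_d`` sequential stage transitions,
each at rate ``m_d * k_div``, so the total cycle time has mean 1/k_div and
coefficient of variation 1/sqrt(m_d).  At stage ``m_g`` the cell doubles
its volume by occupying a second lattice site, pushing a chain of cells
toward the nearest free site if necessary; completing the last transition
splits the cell into two single-site daughters, each of which re-enters
the cycle with probability p_div (evaluated at its own site) or becomes
quiescent.  Dying cells remain on the lattice (TUNEL-positive) until they
lyse, which frees their sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .lattice import (Lattice, EMPTY, path_to_nearest_free,
                      distance_to_nearest_free)


class CapacityError(RuntimeError):
    """The spheroid reached the simulation box boundary."""


class CellState(IntEnum):
    CYCLING = 0
    QUIESCENT = 1
    DYING = 2
    LYSED = 3


# event channels
STAGE, DEATH, LYSIS, MIGRATE, REENTER = range(5)
N_CHANNELS = 5


@dataclass
class CellCycleParams:
    """Cycle topology and state-independent rates.

    ``m_d`` stages with growth at stage ``m_g``; ``tau`` is the expected
    cycle time in hours (k_div_max = 1/tau).  Re-entry from quiescence is
    off by default (p_re * k_re = 0), apoptosis is negligible, and lysis
    takes ~100 h (k_lys = 0.01/h).
    """

    m_d: int = 10
    m_g: int = 5
    tau: float = 18.0
    k_re: float = 0.0
    p_re: float = 0.0
    k_apt: float = 0.0
    k_lys: float = 0.01
    migration_D: float = 0.0       # um^2/h; 0 disables active migration
    migration_mode: str = "unbiased"   # or "biased"
    adhesion_J: float = 0.0        # contact energy in units of F_T
    push_range: int = 30           # BFS cap for pushing / free-site search

    def __post_init__(self) -> None:
        if not (1 <= self.m_g <= self.m_d):
            raise ValueError("require 1 <= m_g <= m_d")
        for name in ("tau", "k_re", "p_re", "k_apt", "k_lys", "migration_D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def k_div_max(self) -> float:
        return 1.0 / self.tau


class Cell:
    """One agent.  Occupies 1 or 2 lattice sites (2 after growth)."""

    __slots__ = ("id", "state", "M", "sites", "n_exp", "t_birth",
                 "needs_growth", "index")

    def __init__(self, cid: int, site: int, state: CellState = CellState.CYCLING,
                 M: int = 0, t_birth: float = 0.0, n_exp: float = 0.0):
        self.id = cid
        self.state = state
        self.M = M
        self.sites = [site]
        self.n_exp = n_exp
        self.t_birth = t_birth
        self.needs_growth = False
        self.index = -1  # slot in the population arrays

    @property
    def is_viable(self) -> bool:
        return self.state in (CellState.CYCLING, CellState.QUIESCENT)

    @property
    def is_dying(self) -> bool:
        return self.state == CellState.DYING


class Population:
    """Cell container with per-cell, per-channel event rates.

    The rate table doubles as the event queue of the stochastic algorithm:
    the total rate is maintained incrementally and audited against a full
    recomputation at every field update.
    """

    def __init__(self) -> None:
        self.cells: list[Cell | None] = []
        self.rates = np.zeros((0, N_CHANNELS))
        self._free_slots: list[int] = []
        self._total = 0.0
        self.next_id = 0
        self.n_births = 0
        self.n_lysed = 0

    # -- bookkeeping -------------------------------------------------------

    def _grow_arrays(self) -> int:
        self.cells.append(None)
        self.rates = np.vstack([self.rates, np.zeros((1, N_CHANNELS))])
        return len(self.cells) - 1

    def add(self, cell: Cell) -> Cell:
        idx = self._free_slots.pop() if self._free_slots else self._grow_arrays()
        cell.index = idx
        self.cells[idx] = cell
        self.rates[idx] = 0.0
        return cell

    def new_cell(self, site: int, **kw) -> Cell:
        cell = Cell(self.next_id, site, **kw)
        self.next_id += 1
        return self.add(cell)

    def remove(self, cell: Cell) -> None:
        self._total -= self.rates[cell.index].sum()
        self.rates[cell.index] = 0.0
        self.cells[cell.index] = None
        self._free_slots.append(cell.index)
        cell.index = -1

    def set_rates(self, cell: Cell, channel_rates: np.ndarray) -> None:
        old = self.rates[cell.index].sum()
        self.rates[cell.index] = channel_rates
        self._total += channel_rates.sum() - old

    def iter_alive(self):
        return (c for c in self.cells if c is not None)

    def iter_viable(self):
        return (c for c in self.cells if c is not None and c.is_viable)

    @property
    def n_alive(self) -> int:
        return sum(1 for _ in self.iter_alive())

    def counts(self) -> dict:
        out = {s.name: 0 for s in CellState if s != CellState.LYSED}
        for c in self.iter_alive():
            out[c.state.name] += 1
        return out

    @property
    def total_rate(self) -> float:
        return self._total

    def recompute_total(self) -> float:
        """Rate audit: exact total from the rate table."""
        alive = [c.index for c in self.iter_alive()]
        t = float(self.rates[alive].sum()) if alive else 0.0
        self._total = t
        return t


# -- stochastic kernel -----------------------------------------------------


def gillespie_draw(rates, rng: np.random.Generator):
    """One draw of the stochastic simulation algorithm.

    ``rates`` may be a dict (name -> rate) or an array.  Returns
    ``(event, dt)`` where ``event`` is the key/index of the chosen event,
    or ``None`` if the total rate is zero (no enabled events: halt).
    """
    if isinstance(rates, dict):
        keys = list(rates)
        vals = np.asarray([rates[k] for k in keys], dtype=float)
    else:
        keys = None
        vals = np.asarray(rates, dtype=float).ravel()
    if np.any(vals < 0):
        raise ValueError("negative event rate")
    total = vals.sum()
    if total <= 0.0:
        return None
    dt = rng.exponential(1.0 / total)
    u = rng.uniform(0.0, total)
    i = int(np.searchsorted(np.cumsum(vals), u, side="right"))
    i = min(i, len(vals) - 1)
    return (keys[i] if keys is not None else i), dt


def select_event(population: Population, rng: np.random.Generator):
    """Draw (cell, channel, dt) from the population's rate table."""
    flat = population.rates.ravel()
    total = population.total_rate
    if total <= 0.0:
        return None
    dt = rng.exponential(1.0 / total)
    u = rng.uniform(0.0, total)
    cum = np.cumsum(flat)
    j = int(np.searchsorted(cum, u, side="right"))
    j = min(j, len(flat) - 1)
    idx, channel = divmod(j, N_CHANNELS)
    cell = population.cells[idx]
    if cell is None:  # numerically stale slot; renormalize and redraw
        population.recompute_total()
        return select_event(population, rng)
    return cell, channel, dt


# -- spatial actions -------------------------------------------------------


def grow(cell: Cell, lattice: Lattice, push_range: int = 30) -> bool:
    """Occupy a second site adjacent to the cell, pushing if necessary.

    Returns True on success.  If no free site is reachable within
    ``push_range`` hops the growth is deferred (False), never an error.
    Pushing moves each cell along the shortest free-site path outward by
    one site (ties broken by smallest site index).
    """
    if cell.state != CellState.CYCLING:
        raise ValueError("only cycling cells grow")
    if len(cell.sites) != 1:
        raise ValueError("cell already occupies two sites")
    base = cell.sites[0]
    path = path_to_nearest_free(lattice, base, push_range)
    if path is None:
        return False
    target_free = path[-1]
    if lattice.is_boundary[target_free] and len(path) > 1:
        # the chain would push a cell into the medium boundary layer
        raise CapacityError("growth pushed a cell onto the box boundary")
    if len(path) == 1:
        if lattice.is_boundary[target_free]:
            raise CapacityError("growth reached the box boundary")
        lattice.occupant[target_free] = cell.id
        cell.sites.append(target_free)
    else:
        # shift occupants of path[:-1] one step outward, far end first
        for k in range(len(path) - 1, 0, -1):
            src, dst = path[k - 1], path[k]
            occ_id = lattice.occupant[src]
            occ_cell = _cell_by_occupancy(lattice, cell, src)
            lattice.occupant[dst] = occ_id
            lattice.occupant[src] = EMPTY
            if occ_cell is not None:
                occ_cell.sites[occ_cell.sites.index(src)] = dst
        liberated = path[0]
        lattice.occupant[liberated] = cell.id
        cell.sites.append(liberated)
    cell.needs_growth = False
    return True


def _cell_by_occupancy(lattice: Lattice, grower: Cell, site: int):
    """Resolve the Cell object occupying ``site`` via the population
    registry attached to the lattice (set by the simulator)."""
    registry = getattr(lattice, "_registry", None)
    if registry is None:
        return None
    return registry.get(int(lattice.occupant[site]))


def divide(cell: Cell, population: Population, lattice: Lattice,
           p_div_fn, rng: np.random.Generator, t: float = 0.0
           ) -> tuple[Cell, Cell]:
    """Split a two-site cell into two single-site daughters.

    ``p_div_fn(site) -> probability`` is evaluated per daughter at its own
    site; each daughter independently re-enters the cycle (M=0) with that
    probability, else becomes quiescent.  The exposure counter is
    inherited (it tracks the lineage's local history).
    """
    if len(cell.sites) != 2:
        raise ValueError("division requires a two-site cell")
    s0, s1 = cell.sites
    # mother becomes daughter A on s0
    cell.sites = [s0]
    cell.M = 0
    cell.needs_growth = False
    cell.t_birth = t
    daughter = population.new_cell(s1, t_birth=t, n_exp=cell.n_exp)
    lattice.occupant[s1] = daughter.id
    registry = getattr(lattice, "_registry", None)
    if registry is not None:
        registry[daughter.id] = daughter
    population.n_births += 1
    for d in (cell, daughter):
        p = float(p_div_fn(d.sites[0]))
        if rng.uniform() < p:
            d.state = CellState.CYCLING
        else:
            d.state = CellState.QUIESCENT
        d.M = 0
    return cell, daughter


def die(cell: Cell) -> None:
    """Viable -> DYING (sites retained; contributes to sigma_D)."""
    if not cell.is_viable:
        raise ValueError("only viable cells can die")
    cell.state = CellState.DYING


def lyse(cell: Cell, population: Population, lattice: Lattice) -> None:
    """DYING -> LYSED; the occupied sites are set free."""
    if cell.state != CellState.DYING:
        raise ValueError("only dying cells can lyse")
    registry = getattr(lattice, "_registry", None)
    for s in cell.sites:
        lattice.occupant[s] = EMPTY
    cell.sites = []
    cell.state = CellState.LYSED
    if registry is not None:
        registry.pop(cell.id, None)
    population.n_lysed += 1
    population.remove(cell)


def migration_rates(cell: Cell, lattice: Lattice, params: CellCycleParams
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-neighbor hop rates for a single-site cell.

    Unbiased: lambda/n to each free neighbor, lambda = 6 D / l^2 with l^2
    the mean squared adjacent-site distance of the lattice in use (so that
    free hopping reproduces MSD = 6 D t regardless of jitter).
    Biased: lambda/n * exp(-dE/F_T), dE = J * (lost - gained contacts).
    """
    if len(cell.sites) != 1 or params.migration_D <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    site = cell.sites[0]
    nbs = lattice.neighbors(site)
    free = nbs[(lattice.occupant[nbs] == EMPTY) & ~lattice.is_boundary[nbs]]
    if len(free) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    l2 = getattr(lattice, "_l2_cache", None)
    if l2 is None:
        l2 = lattice.mean_square_adjacent_distance()
        lattice._l2_cache = l2  # type: ignore[attr-defined]
    lam = 6.0 * params.migration_D / l2
    base = lam / len(nbs)
    if params.migration_mode == "unbiased" or params.adhesion_J == 0.0:
        return free, np.full(len(free), base)
    # biased: contacts = occupied neighbors (excluding own sites)
    occ_here = np.sum(lattice.occupant[nbs] != EMPTY) - 0
    rates = np.empty(len(free))
    for i, f in enumerate(free):
        f_nbs = lattice.neighbors(f)
        occ_there = np.sum((lattice.occupant[f_nbs] != EMPTY)
                           & (f_nbs != site))
        dE = params.adhesion_J * (occ_here - occ_there)
        rates[i] = base * np.exp(-dE)
    return free, rates


def migrate(cell: Cell, lattice: Lattice, params: CellCycleParams,
            rng: np.random.Generator) -> int | None:
    """Hop to a neighboring free site; returns the new site or None."""
    free, rates = migration_rates(cell, lattice, params)
    if len(free) == 0:
        return None
    total = rates.sum()
    u = rng.uniform(0.0, total)
    j = min(int(np.searchsorted(np.cumsum(rates), u, side="right")),
            len(free) - 1)
    target = int(free[j])
    src = cell.sites[0]
    lattice.occupant[target] = cell.id
    lattice.occupant[src] = EMPTY
    cell.sites[0] = target
    return target


def free_site_distance(lattice: Lattice, site: int, cap: int) -> float:
    """Graph distance to the nearest free site, inf when none in range."""
    d = distance_to_nearest_free(lattice, site, cap)
    return float("inf") if d is None else float(d)
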