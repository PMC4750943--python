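"""Orchestration of a full spheroid growth run.

The temporal evolution interleaves two layers: exact stochastic (Gillespie)
cell events within windows of fixed length, and deterministic steady-state
refreshes of the molecular fields at the window boundaries.  Per-cell event
rates are re-evaluated from the fresh fields after every refresh and after
any event that changes a cell's own state; the exposure counters of model
variant 4 are integrated per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cells as C
from . import variants as V
from .cells import (CellState, Population, CapacityError,
                    select_event, grow, divide, die, lyse, migrate,
                    migration_rates, free_site_distance,
                    STAGE, DEATH, LYSIS, MIGRATE, REENTER, N_CHANNELS)
from .config import SimulationConfig
from .fields import FieldSolver, FieldState, grid_from_lattice
from .lattice import build_lattice, EMPTY
from .metabolism import atp_production
from .observables import (GrowthCurve, RadialProfile, spheroid_radius,
                          radial_profile, compare_to_reference, FitResult)


@dataclass
class RunResult:
    """Outputs of one run with provenance."""

    growth: GrowthCurve
    profiles: dict                       # time h -> RadialProfile
    final_counts: dict
    config: SimulationConfig
    config_digest: str
    seed: int
    log: list = field(default_factory=list)
    max_rate_drift: float = 0.0

    def profile_frame(self):
        import pandas as pd
        frames = []
        for t, p in self.profiles.items():
            f = p.to_frame()
            f.insert(0, "time_h", t)
            frames.append(f)
        return pd.concat(frames, ignore_index=True) if frames else None


def initialize(config: SimulationConfig):
    """Lattice + compact central ball of N cycling cells + medium fields.

    Cycle stages are drawn uniformly in 0..m_d-1 (desynchronized start);
    cells drawn past the growth stage carry a pending second-site growth.
    """
    lattice = build_lattice(config.n_per_dim, config.spacing, config.jitter,
                            seed=config.seed)
    rng = np.random.default_rng([config.seed, 0xC311])
    interior = np.flatnonzero(~lattice.is_boundary)
    if config.initial_cells > len(interior):
        raise CapacityError(
            f"{config.initial_cells} initial cells exceed lattice capacity "
            f"({len(interior)} interior sites)")
    center = lattice.positions[interior].mean(axis=0)
    d = np.linalg.norm(lattice.positions[interior] - center, axis=1)
    chosen = interior[np.argsort(d)[:config.initial_cells]]

    population = Population()
    registry: dict[int, C.Cell] = {}
    lattice._registry = registry  # type: ignore[attr-defined]
    m_d = config.cycle.m_d
    for site in chosen:
        cell = population.new_cell(int(site), M=int(rng.integers(0, m_d)))
        if cell.M >= config.cycle.m_g:
            cell.needs_growth = True
        lattice.occupant[site] = cell.id
        registry[cell.id] = cell

    grid = grid_from_lattice(lattice, {"G": config.medium_G,
                                       "O": config.medium_O})
    state = FieldState.initial(grid)
    return lattice, population, state, grid


class Simulation:
    """Stateful engine; use :func:`run` for the one-call interface."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.rng = np.random.default_rng([config.seed, 0x51])
        self.lattice, self.population, self.state, self.grid = initialize(config)
        self.t = 0.0
        self._site_to_node = self.lattice.grid_index
        self.growth = GrowthCurve()
        self.profiles: dict[float, RadialProfile] = {}
        self.log: list[str] = []
        self.max_rate_drift = 0.0
        self._kmax = (config.model.k_div_max
                      if config.model.k_div_max is not None
                      else config.cycle.k_div_max)
        self._solver = FieldSolver(self.grid, config.metabolic,
                                   config.diffusion, tol=config.solver_tol,
                                   method=config.linear_solver)
        # pre-formed tissue carries ECM proportional to its age
        from .fields import rasterize_cells
        sigma, _ = rasterize_cells(self.population, self.lattice, self.grid)
        self.state.ECM = (config.diffusion.k_gen_ECM
                          * sigma * config.metabolic.cell_volume
                          * config.initial_tissue_age)

    # -- local environment -------------------------------------------------

    def _cell_nodes(self, cell_list) -> np.ndarray:
        return np.array([self._site_to_node[c.sites[0]] for c in cell_list],
                        dtype=np.int64)

    def _local_fields(self, cell_list):
        nodes = self._cell_nodes(cell_list)
        flat = lambda a: a.ravel()[nodes]
        return (flat(self.state.G), flat(self.state.O), flat(self.state.L),
                flat(self.state.ECM), flat(self.state.W))

    def ecm_at_cell(self, cell) -> float:
        return float(self.state.ECM.ravel()[self._site_to_node[cell.sites[0]]])

    # -- rates -------------------------------------------------------------

    def refresh_rates(self) -> None:
        """Global per-cell rate refresh from the current fields."""
        pop = self.population
        cfg = self.config
        alive = list(pop.iter_alive())
        if not alive:
            pop.recompute_total()
            return
        G, O, L, ECM, W = self._local_fields(alive)
        p_atp = atp_production(G, O, cfg.metabolic)
        kd = np.asarray(V.k_div(G, O, W, p_atp, cfg.model, self._kmax))
        kn = np.asarray(V.k_nec(G, O, L, p_atp, cfg.model))
        for i, cell in enumerate(alive):
            r = np.zeros(N_CHANNELS)
            if cell.state == CellState.CYCLING:
                r[STAGE] = cfg.cycle.m_d * float(kd[i])
                r[DEATH] = float(kn[i]) + cfg.cycle.k_apt
            elif cell.state == CellState.QUIESCENT:
                r[DEATH] = float(kn[i]) + cfg.cycle.k_apt
                if cfg.cycle.k_re > 0 and cfg.cycle.p_re > 0:
                    r[REENTER] = cfg.cycle.k_re
            elif cell.state == CellState.DYING:
                r[LYSIS] = cfg.cycle.k_lys
            if cfg.cycle.migration_D > 0 and cell.is_viable \
                    and len(cell.sites) == 1:
                _, mr = migration_rates(cell, self.lattice, cfg.cycle)
                r[MIGRATE] = mr.sum()
            pop.rates[cell.index] = r
        pop.recompute_total()

    def _refresh_cell(self, cell) -> None:
        """Single-cell rate refresh (after an event touching the cell)."""
        if cell.index < 0:
            return
        cfg = self.config
        r = np.zeros(N_CHANNELS)
        node = self._site_to_node[cell.sites[0]] if cell.sites else 0
        G = self.state.G.ravel()[node]
        O = self.state.O.ravel()[node]
        L = self.state.L.ravel()[node]
        W = self.state.W.ravel()[node]
        p_atp = atp_production(float(G), float(O), cfg.metabolic)
        if cell.state == CellState.CYCLING:
            r[STAGE] = cfg.cycle.m_d * V.k_div(float(G), float(O), float(W),
                                               p_atp, cfg.model, self._kmax)
            r[DEATH] = V.k_nec(float(G), float(O), float(L), p_atp,
                               cfg.model) + cfg.cycle.k_apt
        elif cell.state == CellState.QUIESCENT:
            r[DEATH] = V.k_nec(float(G), float(O), float(L), p_atp,
                               cfg.model) + cfg.cycle.k_apt
            if cfg.cycle.k_re > 0 and cfg.cycle.p_re > 0:
                r[REENTER] = cfg.cycle.k_re
        elif cell.state == CellState.DYING:
            r[LYSIS] = cfg.cycle.k_lys
        if cfg.cycle.migration_D > 0 and cell.is_viable \
                and len(cell.sites) == 1:
            _, mr = migration_rates(cell, self.lattice, cfg.cycle)
            r[MIGRATE] = mr.sum()
        self.population.set_rates(cell, r)

    def _refresh_migration_around(self, sites) -> None:
        if self.config.cycle.migration_D <= 0:
            return
        registry = self.lattice._registry  # type: ignore[attr-defined]
        touched = set()
        for s in sites:
            for nb in self.lattice.neighbors(s):
                occ = self.lattice.occupant[nb]
                if occ != EMPTY and occ in registry:
                    touched.add(occ)
        for cid in touched:
            self._refresh_cell(registry[cid])

    # -- event handling ----------------------------------------------------

    def _p_div_at(self, site: int, n_exp: float) -> float:
        cfg = self.config
        L_dist = free_site_distance(self.lattice, site, cfg.cycle.push_range)
        ecm = float(self.state.ECM.ravel()[self._site_to_node[site]])
        return float(V.p_div(L_dist, ecm, n_exp, cfg.model))

    def handle_event(self, cell, channel: int) -> None:
        cfg = self.config
        if channel == STAGE:
            self._stage_event(cell)
        elif channel == DEATH:
            die(cell)
            self._refresh_cell(cell)
        elif channel == LYSIS:
            freed = list(cell.sites)
            lyse(cell, self.population, self.lattice)
            self._refresh_migration_around(freed)
        elif channel == MIGRATE:
            src = cell.sites[0]
            dst = migrate(cell, self.lattice, cfg.cycle, self.rng)
            if dst is not None:
                self._refresh_cell(cell)
                self._refresh_migration_around([src, dst])
        elif channel == REENTER:
            p = self._p_div_at(cell.sites[0], cell.n_exp) * cfg.cycle.p_re
            if self.rng.uniform() < p:
                cell.state = CellState.CYCLING
                cell.M = 0
                self._refresh_cell(cell)

    def _stage_event(self, cell) -> None:
        cfg = self.config
        m_g, m_d = cfg.cycle.m_g, cfg.cycle.m_d
        if len(cell.sites) == 1 and cell.M >= m_g:
            # pending growth: retry before any further progression
            if grow(cell, self.lattice, cfg.cycle.push_range):
                self._refresh_migration_around(cell.sites)
            if not (len(cell.sites) == 2 and cell.M == m_d):
                return
        else:
            cell.M += 1
            if cell.M == m_g:
                if grow(cell, self.lattice, cfg.cycle.push_range):
                    self._refresh_migration_around(cell.sites)
                else:
                    cell.needs_growth = True
            if not (cell.M == m_d and len(cell.sites) == 2):
                return
        # completed the cycle with both sites: divide now
        n_exp = cell.n_exp
        a, b = divide(cell, self.population, self.lattice,
                      lambda s: self._p_div_at(s, n_exp), self.rng, t=self.t)
        self._refresh_cell(a)
        self._refresh_cell(b)
        self._refresh_migration_around(a.sites + b.sites)

    # -- exposure (variant 4) ----------------------------------------------

    def _update_exposure(self, elapsed: float) -> None:
        if self.config.model.variant != 4 or elapsed <= 0:
            return
        cfg = self.config
        viable = list(self.population.iter_viable())
        if not viable:
            return
        G, O, L, ECM, W = self._local_fields(viable)
        p_atp = atp_production(G, O, cfg.metabolic)
        # exposure ticks at the *ungated* cycle pace (no variant-4 halving)
        gate = V.heaviside(p_atp - cfg.model.p_atp_min) * self._kmax
        inc = V.exposure_increment(W, O, elapsed, cfg.model, gate, self._kmax)
        inc = np.atleast_1d(inc)
        for i, cell in enumerate(viable):
            cell.n_exp += float(inc[i])

    # -- main loop ----------------------------------------------------------

    def _record(self) -> None:
        pop = self.population
        if pop.n_alive == 0:
            return
        r = spheroid_radius(pop, self.lattice)
        self.growth.append(self.t, r, pop.counts())
        if self.config.record_profiles:
            self.profiles[self.t] = radial_profile(
                pop, self.lattice, ecm_at_cell=self.ecm_at_cell,
                bin_width=self.config.profile_bin_width)

    def _field_update(self) -> None:
        self._solver.update(self.state, self.population, self.lattice,
                            dt=self.config.field_interval)

    def run(self) -> RunResult:
        cfg = self.config
        pop = self.population
        self._field_update()
        self.refresh_rates()
        self._record()
        next_field = cfg.field_interval
        next_out = cfg.output_interval
        eps = 1e-12
        while self.t < cfg.t_end - eps:
            window_end = min(next_field, cfg.t_end)
            while self.t < window_end - eps:
                ev = select_event(pop, self.rng)
                if ev is None:
                    self.t = window_end
                    break
                cell, channel, dt = ev
                if self.t + dt >= window_end:
                    self.t = window_end
                    break
                self.t += dt
                self.handle_event(cell, channel)
            # window boundary: audit, exposure, field refresh, rate refresh
            before = pop.total_rate
            after = pop.recompute_total()
            if after > 0:
                self.max_rate_drift = max(self.max_rate_drift,
                                          abs(before - after) / after)
            self._update_exposure(cfg.field_interval)
            self._field_update()
            self.refresh_rates()
            next_field += cfg.field_interval
            if self.t >= next_out - eps:
                self._record()
                counts = pop.counts()
                self.log.append(
                    f"t={self.t:8.1f}h N={sum(counts.values()):6d} "
                    f"cyc={counts['CYCLING']} qui={counts['QUIESCENT']} "
                    f"dying={counts['DYING']} minO={self.state.O.min():.4f} "
                    f"maxL={self.state.L.max():.2f}")
                next_out += cfg.output_interval
            if pop.n_alive == 0:
                break
        if pop.n_alive and (not self.growth.times
                            or self.growth.times[-1] < self.t):
            self._record()
        return RunResult(
            growth=self.growth, profiles=self.profiles,
            final_counts=pop.counts(), config=cfg,
            config_digest=cfg.digest(), seed=cfg.seed, log=self.log,
            max_rate_drift=self.max_rate_drift)


def run(config: SimulationConfig) -> RunResult:
    """Run one spheroid growth simulation from a configuration."""
    return Simulation(config).run()


def compare(results: dict[str, RunResult], reference: dict,
            k_params: dict[str, int] | int) -> dict[str, FitResult]:
    """Score several runs' growth curves against reference curves.

    ``reference`` maps run name -> (times, mu, sigma); ``k_params`` is the
    per-model parameter count (int applies to all).
    """
    out = {}
    for name, res in results.items():
        if name not in reference:
            raise ValueError(f"no reference for run {name!r}")
        k = k_params if isinstance(k_params, int) else k_params[name]
        curves = {"radius": (res.growth.times, res.growth.radius)}
        out[name] = compare_to_reference(
            curves, {"radius": reference[name]}, k)
    return out
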