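"""Steady-state reaction-diffusion solves for the molecular fields.

Glucose (G), oxygen (O), lactate (L), extracellular matrix (ECM) and waste
(W) live on a regular cubic grid aligned with the cell lattice.  Because
molecular relaxation (seconds-minutes) is fast compared with cellular
dynamics (hours), each species is driven to the steady state of

    0 = div(D_u grad u) + r_u(sigma, u)

whenever the cell configuration is refreshed.  Glucose and oxygen are
coupled through their cross-inhibited uptake and are solved monolithically:
by default a damped inexact Newton iteration on the two-species system
(full 2x2 local uptake Jacobian, solved together), with semi-implicit
Picard sweeps — the nonlinear uptake frozen at the previous iterate in the
positivity-preserving form q_u(G_k, O_k)/u_k * u — as globalization and as
the alternative ``scheme="picard"``.  Lactate and waste are
single linear solves with frozen sources; ECM by default keeps memory (a
backward-Euler step per update) because matrix deposition is *slow*
compared with spheroid growth — the fast-equilibration argument that
justifies steady state for small solutes does not apply to collagen.  A
steady-state ECM variant is available for sensitivity checks.

Discretization: 7-point central differences, harmonic-mean diffusivity at
tumor/medium interfaces (preserves flux continuity), Dirichlet values on
the box faces (medium renewal), optionally Neumann on selected axes (used
by the 1D verification problems).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix, diags, bmat
from scipy.sparse.linalg import spsolve, bicgstab, LinearOperator

from .lattice import Lattice
from .metabolism import (MetabolicParams, DEFAULT_PARAMS, glucose_uptake,
                         oxygen_uptake, lactate_production, uptake_jacobian)

SPECIES = ("G", "O", "L", "ECM", "W")


class ConvergenceError(RuntimeError):
    """Raised when the nonlinear field solve does not converge."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class DiffusionParams:
    """Diffusion and ECM/waste kinetic constants.

    ``D_tum`` holds tumor-tissue diffusion coefficients in um^2/h; the
    coefficient in free medium is ``medium_ratio`` times larger.  The ECM
    and waste generation/decay constants are per-cell rates relative to
    the reference cell volume (1/h at confluent density).
    """

    D_tum: dict = field(default_factory=lambda: {
        "G": 2.5e5,      # glucose in tissue, ~70 um^2/s
        "O": 3.6e6,      # oxygen in tissue, ~1000 um^2/s
        "L": 2.5e5,      # lactate, glucose-like
        "ECM": 1.0,      # collagen is effectively immobile
        "W": 1.8e5,      # macromolecular debris, ~50 um^2/s
    })
    medium_ratio: float = 30.0
    #: ECM kinetics are slow (collagen turnover ~ weeks); the plateau
    #: k_gen/k_deg ~ 0.1 matches the Collagen-IV intensity scale on which
    #: the cycle-entry threshold 0.003 is defined, and the slow deposition
    #: leaves the freshly formed outer cell layer below that threshold.
    k_gen_ECM: float = 1.2e-3  # 1/h, deposition per confluent cell density
    k_deg_ECM: float = 1.2e-2  # 1/h, ECM turnover
    k_gen_W: float = 5.0      # 1/h, waste release per dead (unlysed) cell
    k_upt_W: float = 0.05     # 1/h, waste uptake by viable cells
    ecm_steady: bool = False  # literal per-step steady state instead of memory

    def D_medium(self, species: str) -> float:
        return self.D_tum[species] * self.medium_ratio


@dataclass
class FieldGrid:
    """Regular grid carrying the molecular fields.

    ``bc`` selects the boundary condition per axis: "dirichlet" (default;
    fixed medium value on both faces) or "neumann" (no flux).
    """

    shape: tuple[int, int, int]
    spacing: float
    boundary_values: dict = field(default_factory=lambda: {
        "G": 25.0, "O": 0.28, "L": 0.0, "ECM": 0.0, "W": 0.0,
    })
    bc: tuple[str, str, str] = ("dirichlet",) * 3
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    #: optional extra nodes clamped to the boundary value (e.g. a spherical
    #: far-field shell for verification against radial oracles)
    fixed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        for k, v in self.boundary_values.items():
            if v < 0:
                raise ValueError(f"boundary value for {k} must be >= 0")

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def node_volume(self) -> float:
        return self.spacing ** 3

    def dirichlet_mask(self) -> np.ndarray:
        """Boolean array of nodes clamped to the boundary value."""
        m = np.zeros(self.shape, dtype=bool)
        for ax in range(3):
            if self.bc[ax] == "dirichlet":
                sl = [slice(None)] * 3
                sl[ax] = 0
                m[tuple(sl)] = True
                sl[ax] = -1
                m[tuple(sl)] = True
        if self.fixed_mask is not None:
            m |= self.fixed_mask
        return m

    def node_positions(self) -> np.ndarray:
        ii = [np.arange(n) * self.spacing + self.origin[i]
              for i, n in enumerate(self.shape)]
        gx, gy, gz = np.meshgrid(*ii, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


def grid_from_lattice(lattice: Lattice, boundary_values: dict | None = None) -> FieldGrid:
    """Field grid congruent with the generating grid of the cell lattice."""
    g = FieldGrid(shape=(lattice.n_per_dim,) * 3, spacing=lattice.spacing)
    if boundary_values:
        g.boundary_values.update(boundary_values)
    return g


@dataclass
class FieldState:
    """Nodal concentration arrays plus rasterized cell densities."""

    G: np.ndarray
    O: np.ndarray
    L: np.ndarray
    ECM: np.ndarray
    W: np.ndarray
    sigma: np.ndarray      # viable cells per um^3
    sigma_D: np.ndarray    # dead, not-yet-lysed cells per um^3
    tumor_mask: np.ndarray

    @classmethod
    def initial(cls, grid: FieldGrid) -> "FieldState":
        z = lambda v=0.0: np.full(grid.shape, float(v))
        bv = grid.boundary_values
        return cls(G=z(bv["G"]), O=z(bv["O"]), L=z(bv.get("L", 0.0)),
                   ECM=z(bv.get("ECM", 0.0)), W=z(bv.get("W", 0.0)),
                   sigma=z(), sigma_D=z(), tumor_mask=np.zeros(grid.shape, bool))

    def species(self, name: str) -> np.ndarray:
        return getattr(self, name)


# -- rasterization ---------------------------------------------------------


def rasterize_cells(population, lattice: Lattice, grid: FieldGrid
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-node rasterization of the cell population.

    Each cell contributes a total of 1/node-volume, split evenly over the
    nodes nearest to its occupied sites (a grown cell spans two sites);
    viable (cycling + quiescent) cells feed ``sigma``, dying
    (not-yet-lysed) cells ``sigma_D``; total mass is conserved exactly.
    """
    sigma = np.zeros(grid.shape)
    sigma_d = np.zeros(grid.shape)
    inv_v = 1.0 / grid.node_volume
    shape = np.array(grid.shape)
    for cell in population.iter_alive():
        share = inv_v / len(cell.sites)
        for s in cell.sites:
            pos = lattice.positions[s]
            idx = np.rint((pos - grid.origin) / grid.spacing).astype(int)
            if np.any(idx < 0) or np.any(idx >= shape):
                raise ValueError(f"cell {cell.id} outside the field grid")
            if cell.is_viable:
                sigma[tuple(idx)] += share
            elif cell.is_dying:
                sigma_d[tuple(idx)] += share
    return sigma, sigma_d


def tumor_mask_from_sigma(sigma: np.ndarray, sigma_d: np.ndarray) -> np.ndarray:
    """Occupied nodes, morphologically closed to suppress speckle."""
    occ = (sigma + sigma_d) > 0
    if occ.any():
        occ = ndimage.binary_closing(occ, structure=np.ones((3, 3, 3), bool))
    return occ


# -- discrete operators ----------------------------------------------------


def build_diffusion_operator(grid: FieldGrid, D: np.ndarray
                             ) -> tuple[csr_matrix, np.ndarray]:
    """Sparse 7-point operator A ~ div(D grad .) with harmonic-mean
    face diffusivities.

    Returns ``(A, fixed)`` where ``fixed`` marks Dirichlet nodes; rows of
    fixed nodes are identity (the caller sets their RHS to the boundary
    value).
    """
    shape = grid.shape
    n = grid.n_nodes
    h2 = grid.spacing ** 2
    D = np.broadcast_to(np.asarray(D, dtype=float), shape)
    fixed = grid.dirichlet_mask().ravel()

    idx = np.arange(n).reshape(shape)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(None, -1)
        hi[ax] = slice(1, None)
        a = idx[tuple(lo)].ravel()
        b = idx[tuple(hi)].ravel()
        Da = D[tuple(lo)].ravel()
        Db = D[tuple(hi)].ravel()
        T = 2.0 * Da * Db / (Da + Db) / h2  # harmonic mean / h^2
        rows.extend([a, b])
        cols.extend([b, a])
        vals.extend([T, T])
        np.add.at(diag, a, -T)
        np.add.at(diag, b, -T)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    keep = ~(fixed[rows])          # fixed rows become identity
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    diag = np.where(fixed, 1.0, diag)
    rows = np.concatenate([rows, np.arange(n)])
    cols = np.concatenate([cols, np.arange(n)])
    vals = np.concatenate([vals, diag])
    A = csr_matrix((vals, (rows, cols)), shape=(n, n))
    return A, fixed


def _solve(M: csr_matrix, b: np.ndarray, method: str, x0=None) -> np.ndarray:
    if method == "direct":
        return spsolve(M.tocsc(), b)
    if method == "bicgstab":
        x, info = bicgstab(M, b, x0=x0, rtol=1e-12, atol=0.0, maxiter=5000)
        if info != 0:
            return spsolve(M.tocsc(), b)  # robust fallback
        return x
    raise ValueError(f"unknown linear solver {method!r}")


def solve_linear_reaction(grid: FieldGrid, D: np.ndarray, source: np.ndarray,
                          decay: np.ndarray | float, boundary_value: float,
                          method: str = "direct") -> np.ndarray:
    """Steady state of  0 = div(D grad u) + source - decay * u.

    ``source`` (units of u per hour) and ``decay`` (1/h, may be a field)
    are frozen.  Raises on a singular operator (no Dirichlet node and no
    decay anywhere).
    """
    A, fixed = build_diffusion_operator(grid, D)
    decay_arr = np.broadcast_to(np.asarray(decay, dtype=float), grid.shape).ravel()
    if not fixed.any() and np.all(decay_arr == 0):
        raise ConvergenceError("singular steady-state operator: no boundary "
                               "condition and no decay term")
    dec = np.where(fixed, 0.0, decay_arr)
    M = A - diags(dec)
    b = np.where(fixed, boundary_value,
                 -np.asarray(source, dtype=float).ravel())
    u = _solve(M, b, method)
    return u.reshape(grid.shape)


# -- species solves --------------------------------------------------------


def _D_field(grid: FieldGrid, diffusion: DiffusionParams, species: str,
             tumor_mask: np.ndarray) -> np.ndarray:
    D = np.full(grid.shape, diffusion.D_medium(species))
    D[tumor_mask] = diffusion.D_tum[species]
    return D


def solve_steady_glucose_oxygen(
    grid: FieldGrid,
    state: FieldState,
    metabolic: MetabolicParams = DEFAULT_PARAMS,
    diffusion: DiffusionParams | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    method: str = "direct",
    scheme: str = "picard",
) -> tuple[np.ndarray, np.ndarray]:
    """Monolithic semi-implicit solve of the coupled G/O steady state.

    The default scheme is the semi-implicit Picard iteration (uptake
    frozen at the previous iterate, linearized proportionally, the two
    species solved together per sweep); ``scheme="newton"`` uses the
    coupled-Jacobian Newton solver.  Both converge to the same discrete
    steady state, measured on the nonlinear residual.  See
    :class:`FieldSolver` for the cached, warm-started variant used inside
    simulations.
    """
    solver = FieldSolver(grid, metabolic, diffusion, tol=tol, method=method,
                         scheme=scheme)
    solver._operators(state.tumor_mask)
    return solver.solve_go(state, max_iter=max_iter)


def solve_steady_linear(species: str, grid: FieldGrid, state: FieldState,
                        metabolic: MetabolicParams = DEFAULT_PARAMS,
                        diffusion: DiffusionParams | None = None,
                        method: str = "direct") -> np.ndarray:
    """Steady state of one of the linear species {L, ECM, W} with sources
    frozen at the current G/O fields and cell densities."""
    diffusion = diffusion or DiffusionParams()
    D = _D_field(grid, diffusion, species, state.tumor_mask)
    sig_v = state.sigma * metabolic.cell_volume
    sigD_v = state.sigma_D * metabolic.cell_volume
    if species == "L":
        src = lactate_production(state.G, state.O, metabolic) * sig_v
        return solve_linear_reaction(grid, D, src, 0.0,
                                     grid.boundary_values.get("L", 0.0), method)
    if species == "ECM":
        src = diffusion.k_gen_ECM * sig_v
        return solve_linear_reaction(grid, D, src, diffusion.k_deg_ECM,
                                     grid.boundary_values.get("ECM", 0.0), method)
    if species == "W":
        src = diffusion.k_gen_W * sigD_v
        decay = diffusion.k_upt_W * sig_v
        return solve_linear_reaction(grid, D, src, decay,
                                     grid.boundary_values.get("W", 0.0), method)
    raise ValueError(f"unknown linear species {species!r}")


def step_transient_ecm(grid: FieldGrid, state: FieldState, dt: float,
                       metabolic: MetabolicParams = DEFAULT_PARAMS,
                       diffusion: DiffusionParams | None = None,
                       method: str = "direct") -> np.ndarray:
    """One backward-Euler step of the ECM equation (deposition with memory).

    Solves (1/dt + k_deg - div(D grad)) E' = E/dt + k_gen * sigma.
    """
    diffusion = diffusion or DiffusionParams()
    D = _D_field(grid, diffusion, "ECM", state.tumor_mask)
    A, fixed = build_diffusion_operator(grid, D)
    sig_v = state.sigma.ravel() * metabolic.cell_volume
    dec = np.where(fixed, 0.0, diffusion.k_deg_ECM + 1.0 / dt)
    M = A - diags(dec)
    bval = grid.boundary_values.get("ECM", 0.0)
    b = np.where(fixed, bval,
                 -(state.ECM.ravel() / dt + diffusion.k_gen_ECM * sig_v))
    u = _solve(M, b, method)
    return np.maximum(u.reshape(grid.shape), 0.0)


class FieldSolver:
    """Stateful field updater with operator caching and warm starts.

    The diffusion operators depend only on the tumor mask; they are
    rebuilt only when the mask changes.  Previous solutions seed the
    Krylov solves, which makes the per-step cost small once the fields
    track a slowly growing spheroid.
    """

    def __init__(self, grid: FieldGrid,
                 metabolic: MetabolicParams = DEFAULT_PARAMS,
                 diffusion: DiffusionParams | None = None,
                 tol: float = 1e-8, method: str = "bicgstab",
                 scheme: str = "newton"):
        self.grid = grid
        self.scheme = scheme
        self.metabolic = metabolic
        self.diffusion = diffusion or DiffusionParams()
        self.tol = tol
        self.method = method
        self._mask_key: bytes | None = None
        self._ops: dict[str, csr_matrix] = {}
        self._fixed: np.ndarray | None = None

    def _operators(self, mask: np.ndarray) -> None:
        key = np.packbits(mask).tobytes()
        if key == self._mask_key:
            return
        for sp in SPECIES:
            A, fixed = build_diffusion_operator(
                self.grid, _D_field(self.grid, self.diffusion, sp, mask))
            self._ops[sp] = A
        self._fixed = fixed
        self._mask_key = key

    def _krylov(self, M: csr_matrix, b: np.ndarray, x0: np.ndarray,
                rtol: float = 1e-11) -> np.ndarray:
        if self.method == "direct":
            return spsolve(M.tocsc(), b)
        dj = M.diagonal()
        dj = np.where(dj != 0, dj, 1.0)
        P = LinearOperator(M.shape, lambda x: x / dj)  # Jacobi
        x, info = bicgstab(M, b, x0=x0, rtol=rtol, atol=0.0, maxiter=2000,
                           M=P)
        if info != 0:
            return spsolve(M.tocsc(), b)
        return x

    def _go_residual(self, G, O, sig_v):
        met = self.metabolic
        fixed = self._fixed
        shape = self.grid.shape
        qg = glucose_uptake(np.maximum(G, 0).reshape(shape),
                            np.maximum(O, 0).reshape(shape),
                            met).ravel() * sig_v
        qo = oxygen_uptake(np.maximum(G, 0).reshape(shape),
                           np.maximum(O, 0).reshape(shape),
                           met).ravel() * sig_v
        rG = np.where(fixed, 0.0, self._ops["G"] @ G - qg)
        rO = np.where(fixed, 0.0, self._ops["O"] @ O - qo)
        res = max(
            np.linalg.norm(rG) / max(np.linalg.norm(qg),
                                     np.linalg.norm(self._ops["G"] @ G), 1e-30),
            np.linalg.norm(rO) / max(np.linalg.norm(qo),
                                     np.linalg.norm(self._ops["O"] @ O), 1e-30))
        return rG, rO, res

    def solve_go(self, state: FieldState, max_iter: int = 200
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Monolithic solve of the coupled G/O steady state.

        Default scheme "newton": damped inexact Newton on the coupled
        two-species system, with the full 2x2 block Jacobian of the
        cross-inhibited uptake assembled and solved together.  Scheme
        "picard" freezes the uptake at the previous iterate
        (positivity-preserving proportional linearization) and solves the
        two decoupled linearized problems per sweep; both schemes
        converge to the same discrete steady state (checked on the
        nonlinear residual at tolerance ``tol``).
        """
        grid, met = self.grid, self.metabolic
        A_G, A_O = self._ops["G"], self._ops["O"]
        fixed = self._fixed
        sig_v = state.sigma.ravel() * met.cell_volume
        bG = grid.boundary_values["G"]
        bO = grid.boundary_values["O"]
        G = state.G.ravel().copy()
        O = state.O.ravel().copy()
        if not np.any(sig_v > 0):
            G[:] = bG
            O[:] = bO
            return G.reshape(grid.shape), O.reshape(grid.shape)
        G[fixed] = bG
        O[fixed] = bO
        history: list[float] = []
        n = len(G)
        shape = grid.shape
        if self.scheme == "picard":
            omega = 1.0
            rhsG = np.where(fixed, bG, 0.0)
            rhsO = np.where(fixed, bO, 0.0)
            for it in range(max_iter):
                Gp = np.maximum(G, 0).reshape(shape)
                Op = np.maximum(O, 0).reshape(shape)
                qg = glucose_uptake(Gp, Op, met).ravel() * sig_v
                qo = oxygen_uptake(Gp, Op, met).ravel() * sig_v
                cG = np.where(fixed, 0.0, qg / np.maximum(G, 1e-12))
                cO = np.where(fixed, 0.0, qo / np.maximum(O, 1e-12))
                G_new = self._krylov(A_G - diags(cG), rhsG, G)
                O_new = self._krylov(A_O - diags(cO), rhsO, O)
                G = G + omega * (G_new - G)
                O = O + omega * (O_new - O)
                _, _, res = self._go_residual(G, O, sig_v)
                history.append(res)
                if res < self.tol:
                    break
                if len(history) >= 3 and history[-1] > history[-2] > 0 and \
                        history[-2] > history[-3] * 0.99:
                    omega = max(omega / 2.0, 0.125)
            else:
                raise ConvergenceError(
                    f"G/O Picard iteration did not reach tol={self.tol} in "
                    f"{max_iter} iterations (last residuals {history[-3:]})",
                    residuals=history)
        else:  # newton (with Picard sweeps as globalization far from root)
            rhsG = np.where(fixed, bG, 0.0)
            rhsO = np.where(fixed, bO, 0.0)
            _, _, res = self._go_residual(G, O, sig_v)
            for it in range(max_iter):
                history.append(res)
                if res < self.tol:
                    break
                if res > 0.05:
                    # Picard sweep: globally stable contraction
                    Gp = np.maximum(G, 0).reshape(shape)
                    Op = np.maximum(O, 0).reshape(shape)
                    qg = glucose_uptake(Gp, Op, met).ravel() * sig_v
                    qo = oxygen_uptake(Gp, Op, met).ravel() * sig_v
                    cG = np.where(fixed, 0.0, qg / np.maximum(G, 1e-12))
                    cO = np.where(fixed, 0.0, qo / np.maximum(O, 1e-12))
                    G = self._krylov(A_G - diags(cG), rhsG, G, rtol=1e-8)
                    O = self._krylov(A_O - diags(cO), rhsO, O, rtol=1e-8)
                    _, _, res = self._go_residual(G, O, sig_v)
                    continue
                rG, rO, _ = self._go_residual(G, O, sig_v)
                d11, d12, d21, d22 = uptake_jacobian(
                    np.maximum(G, 0).reshape(shape),
                    np.maximum(O, 0).reshape(shape), met)
                w = np.where(~fixed, sig_v, 0.0)
                J = bmat([[A_G - diags(w * d11.ravel()),
                           -diags(w * d12.ravel())],
                          [-diags(w * d21.ravel()),
                           A_O - diags(w * d22.ravel())]], format="csr")
                rhs = -np.concatenate([rG, rO])
                dj = J.diagonal()
                dj = np.where(dj != 0, dj, 1.0)
                P = LinearOperator(J.shape, lambda x: x / dj)
                inner_rtol = float(np.clip(0.01 * res, 1e-10, 1e-4))
                delta, info = bicgstab(J, rhs, x0=np.zeros(2 * n),
                                       rtol=inner_rtol, atol=0.0,
                                       maxiter=2000, M=P)
                if info != 0:
                    delta = spsolve(J.tocsc(), rhs)
                omega = 1.0
                while True:
                    G_try = G + omega * delta[:n]
                    O_try = O + omega * delta[n:]
                    _, _, res_t = self._go_residual(G_try, O_try, sig_v)
                    if res_t < res or omega <= 1.0 / 32.0:
                        G, O, res = G_try, O_try, res_t
                        break
                    omega /= 2.0
            else:
                raise ConvergenceError(
                    f"G/O Newton iteration did not reach tol={self.tol} in "
                    f"{max_iter} iterations (last residuals {history[-3:]})",
                    residuals=history)
        np.clip(G, 0.0, None, out=G)
        np.clip(O, 0.0, None, out=O)
        return G.reshape(grid.shape), O.reshape(grid.shape)

    def _linear(self, species: str, src: np.ndarray, decay, bval: float,
                x0: np.ndarray) -> np.ndarray:
        A = self._ops[species]
        fixed = self._fixed
        decay_arr = np.broadcast_to(np.asarray(decay, float),
                                    self.grid.shape).ravel()
        M = A - diags(np.where(fixed, 0.0, decay_arr))
        b = np.where(fixed, bval, -src.ravel())
        u = self._krylov(M, b, x0.ravel())
        return u.reshape(self.grid.shape)

    def update(self, state: FieldState, population, lattice,
               dt: float = 0.1) -> FieldState:
        grid, met, dif = self.grid, self.metabolic, self.diffusion
        sigma, sigma_d = rasterize_cells(population, lattice, grid)
        state.sigma, state.sigma_D = sigma, sigma_d
        state.tumor_mask = tumor_mask_from_sigma(sigma, sigma_d)
        self._operators(state.tumor_mask)
        state.G, state.O = self.solve_go(state)
        sig_v = sigma * met.cell_volume
        sigD_v = sigma_d * met.cell_volume
        state.L = np.maximum(self._linear(
            "L", lactate_production(state.G, state.O, met) * sig_v, 0.0,
            grid.boundary_values.get("L", 0.0), state.L), 0.0)
        if dif.ecm_steady:
            state.ECM = np.maximum(self._linear(
                "ECM", dif.k_gen_ECM * sig_v, dif.k_deg_ECM,
                grid.boundary_values.get("ECM", 0.0), state.ECM), 0.0)
        else:
            fixed = self._fixed
            A = self._ops["ECM"]
            dec = np.where(fixed, 0.0, dif.k_deg_ECM + 1.0 / dt)
            M = A - diags(dec)
            bval = grid.boundary_values.get("ECM", 0.0)
            b = np.where(fixed, bval,
                         -(state.ECM.ravel() / dt +
                           dif.k_gen_ECM * sig_v.ravel()))
            state.ECM = np.maximum(
                self._krylov(M, b, state.ECM.ravel()).reshape(grid.shape), 0.0)
        state.W = np.maximum(self._linear(
            "W", dif.k_gen_W * sigD_v, dif.k_upt_W * sig_v,
            grid.boundary_values.get("W", 0.0), state.W), 0.0)
        return state


def update_fields(grid: FieldGrid, state: FieldState, population, lattice,
                  dt: float = 0.1,
                  metabolic: MetabolicParams = DEFAULT_PARAMS,
                  diffusion: DiffusionParams | None = None,
                  tol: float = 1e-8, method: str = "direct") -> FieldState:
    """One-shot field refresh: rasterize, then G/O monolithically, then
    L, ECM, W.  (For repeated updates :class:`FieldSolver` caches the
    operators and warm-starts the solves.)"""
    solver = FieldSolver(grid, metabolic, diffusion, tol, method)
    return solver.update(state, population, lattice, dt)
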