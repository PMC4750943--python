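"""Unstructured 3D lattice populated by cell agents.

The tissue is discretized as a jittered cubic point set whose Delaunay
adjacency defines which sites are "in contact".  Each site can hold at most
one cell.  The same point set doubles as the geometric support for mapping
agents onto the regular finite-difference grid of the molecular fields: the
underlying (un-jittered) grid coordinates are retained so that every site
has a canonical grid node.

Distances come in two flavors and are deliberately kept distinct:

* graph distance in *sites* (hops), used for the pushing range of growing
  cells and for the distance-to-free-site entering the cycle-entry
  probability;
* Euclidean distance in micrometers, used for radial profiles that are
  compared against image-derived, micrometer-binned statistics.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

EMPTY = -1

#: reference cell volume in um^3 (estimated from the ~16.8 um cell diameter)
REFERENCE_CELL_VOLUME = 2700.0
#: default mean inter-site distance in um (the estimated cell diameter)
DEFAULT_SPACING = 16.8


class DegenerateLatticeError(ValueError):
    """Raised when the jittered point set cannot be triangulated."""


@dataclass
class Lattice:
    """Unstructured site graph.

    Attributes
    ----------
    positions : (N, 3) float array, um
    indptr, indices : CSR adjacency (symmetric, no self loops)
    occupant : (N,) int array, cell id or ``EMPTY``
    is_boundary : (N,) bool array
        Sites of the outermost grid layer.  They belong to the medium and
        are treated as permanently free: a cell may never be placed there.
    grid_index : (N,) int array
        Flat index of the regular grid node each site was jittered from.
    """

    positions: np.ndarray
    indptr: np.ndarray
    indices: np.ndarray
    spacing: float
    n_per_dim: int
    jitter: float
    seed: int
    occupant: np.ndarray = field(default=None)  # type: ignore[assignment]
    is_boundary: np.ndarray = field(default=None)  # type: ignore[assignment]
    grid_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.positions)
        if self.occupant is None:
            self.occupant = np.full(n, EMPTY, dtype=np.int64)
        if self.is_boundary is None:
            self.is_boundary = np.zeros(n, dtype=bool)
        if self.grid_index is None:
            self.grid_index = np.arange(n, dtype=np.int64)

    # -- basic queries -----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def neighbors(self, site: int) -> np.ndarray:
        return self.indices[self.indptr[site]:self.indptr[site + 1]]

    def is_free(self, site: int) -> bool:
        return self.occupant[site] == EMPTY

    @property
    def box_volume(self) -> float:
        lo = self.positions.min(axis=0)
        hi = self.positions.max(axis=0)
        return float(np.prod(hi - lo))

    @property
    def site_volume(self) -> float:
        """Volume represented by one occupied site: one reference cell.

        Sites are spaced one cell diameter apart, so a site stands for a
        cell body of ~2700 um^3 plus interstitial space; the cell volume
        is the meaningful per-site tissue volume for radii and densities.
        """
        return REFERENCE_CELL_VOLUME

    def mean_adjacent_distance(self) -> float:
        """Mean Euclidean length of the adjacency (Delaunay) edges."""
        src = np.repeat(np.arange(self.n_sites), np.diff(self.indptr))
        d = np.linalg.norm(self.positions[src] - self.positions[self.indices],
                           axis=1)
        return float(d.mean())

    def mean_square_adjacent_distance(self) -> float:
        """Mean squared adjacency edge length; calibrates the hop rate of
        the migration process so that unbiased hopping has MSD = 6 D t."""
        src = np.repeat(np.arange(self.n_sites), np.diff(self.indptr))
        d2 = np.sum((self.positions[src] - self.positions[self.indices]) ** 2,
                    axis=1)
        return float(d2.mean())

    def free_mask(self) -> np.ndarray:
        return self.occupant == EMPTY

    def mean_nearest_neighbor_distance(self) -> float:
        tree = cKDTree(self.positions)
        d, _ = tree.query(self.positions, k=2)
        return float(d[:, 1].mean())

    def adjacency_matrix(self) -> csr_matrix:
        n = self.n_sites
        data = np.ones(len(self.indices), dtype=np.int8)
        return csr_matrix((data, self.indices, self.indptr), shape=(n, n))

    def is_connected(self) -> bool:
        ncomp, _ = connected_components(self.adjacency_matrix(), directed=False)
        return ncomp == 1


def _regular_grid_adjacency(n: int) -> tuple[np.ndarray, np.ndarray]:
    """6-neighbor cubic adjacency for an n^3 grid, CSR form."""
    idx = np.arange(n ** 3).reshape(n, n, n)
    pairs = []
    for axis in range(3):
        a = np.moveaxis(idx, axis, 0)
        pairs.append(np.stack([a[:-1].ravel(), a[1:].ravel()], axis=1))
    edges = np.concatenate(pairs, axis=0)
    both = np.concatenate([edges, edges[:, ::-1]], axis=0)
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    counts = np.bincount(both[:, 0], minlength=n ** 3)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return indptr.astype(np.int64), both[:, 1].astype(np.int64)


def _delaunay_adjacency(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tri = Delaunay(points)
    indptr, indices = tri.vertex_neighbor_vertices
    # sort neighbor lists for reproducible tie-breaking
    indices = indices.copy()
    for i in range(len(indptr) - 1):
        indices[indptr[i]:indptr[i + 1]] = np.sort(indices[indptr[i]:indptr[i + 1]])
    return indptr.astype(np.int64), indices.astype(np.int64)


def build_lattice(
    n_per_dim: int,
    spacing: float = DEFAULT_SPACING,
    jitter: float = 0.25,
    seed: int = 0,
    max_rejitter: int = 5,
) -> Lattice:
    """Build a jittered cubic lattice with Delaunay adjacency.

    Parameters
    ----------
    n_per_dim : number of sites along each axis (>= 3).
    spacing : mean inter-site distance, um.
    jitter : jitter amplitude as a fraction of spacing, in [0, 0.5).
    seed : RNG seed; the construction is deterministic given the seed.

    With ``jitter == 0`` the point set is a perfect cubic grid, whose
    Delaunay triangulation is degenerate; in that case the canonical
    6-neighbor grid adjacency is used instead.
    """
    if n_per_dim < 3:
        raise ValueError(f"n_per_dim must be >= 3, got {n_per_dim}")
    if not (0.0 <= jitter < 0.5):
        raise ValueError(f"jitter must be in [0, 0.5), got {jitter}")

    ax = np.arange(n_per_dim) * spacing
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    base = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1).astype(float)

    if jitter == 0.0:
        indptr, indices = _regular_grid_adjacency(n_per_dim)
        positions = base
    else:
        rng = np.random.default_rng(seed)
        for attempt in range(max_rejitter):
            offsets = rng.uniform(-jitter * spacing, jitter * spacing, size=base.shape)
            positions = base + offsets
            try:
                indptr, indices = _delaunay_adjacency(positions)
            except Exception:
                continue  # degenerate realization: re-jitter, never accept silently
            break
        else:
            raise DegenerateLatticeError(
                f"could not triangulate jittered grid after {max_rejitter} attempts"
            )

    lat = Lattice(
        positions=positions,
        indptr=indptr,
        indices=indices,
        spacing=spacing,
        n_per_dim=n_per_dim,
        jitter=jitter,
        seed=seed,
    )
    # outermost layer of the generating grid = medium boundary
    ijk = np.stack(np.unravel_index(np.arange(n_per_dim ** 3),
                                    (n_per_dim,) * 3), axis=1)
    lat.is_boundary = ((ijk == 0) | (ijk == n_per_dim - 1)).any(axis=1)
    return lat


# -- graph searches --------------------------------------------------------


def distance_to_nearest_free(lattice: Lattice, site_id: int,
                             max_radius: int) -> int | None:
    """Breadth-first graph distance (hops) to the closest unoccupied site.

    Boundary (medium) sites count as free.  Returns ``None`` if no free
    site is found within ``max_radius`` hops.  The query site must be
    occupied (contract violation otherwise).
    """
    if lattice.occupant[site_id] == EMPTY:
        raise ValueError(f"site {site_id} is not occupied")
    occupant = lattice.occupant
    indptr, indices = lattice.indptr, lattice.indices
    visited = {site_id}
    frontier = [site_id]
    for depth in range(1, max_radius + 1):
        nxt = []
        for s in frontier:
            for nb in indices[indptr[s]:indptr[s + 1]]:
                if nb in visited:
                    continue
                if occupant[nb] == EMPTY:
                    return depth
                visited.add(nb)
                nxt.append(nb)
        if not nxt:
            return None
        frontier = nxt
    return None


def path_to_nearest_free(lattice: Lattice, site_id: int,
                         max_radius: int) -> list[int] | None:
    """Shortest path (list of site ids, excluding the start) from an
    occupied site to the nearest free site.

    BFS with neighbor lists visited in ascending site order, so ties are
    broken by smallest site index, reproducibly.
    """
    if lattice.occupant[site_id] == EMPTY:
        raise ValueError(f"site {site_id} is not occupied")
    occupant = lattice.occupant
    indptr, indices = lattice.indptr, lattice.indices
    parent: dict[int, int] = {site_id: -2}
    q: deque[tuple[int, int]] = deque([(site_id, 0)])
    while q:
        s, depth = q.popleft()
        if depth >= max_radius:
            continue
        for nb in indices[indptr[s]:indptr[s + 1]]:
            nb = int(nb)
            if nb in parent:
                continue
            parent[nb] = s
            if occupant[nb] == EMPTY:
                path = [nb]
                p = s
                while p != site_id:
                    path.append(p)
                    p = parent[p]
                path.reverse()
                return path
            q.append((nb, depth + 1))
    return None


def outside_free_mask(lattice: Lattice) -> np.ndarray:
    """Free sites connected to the box boundary through free space.

    Distinguishes the medium surrounding the spheroid from interior holes
    left by lysed cells; only the former defines the spheroid surface.
    """
    free = lattice.occupant == EMPTY
    outside = np.zeros(lattice.n_sites, dtype=bool)
    frontier = np.flatnonzero(free & lattice.is_boundary)
    outside[frontier] = True
    while len(frontier):
        starts = lattice.indptr[frontier]
        stops = lattice.indptr[frontier + 1]
        nbs = np.concatenate([lattice.indices[a:b]
                              for a, b in zip(starts, stops)])
        nbs = np.unique(nbs)
        nxt = nbs[free[nbs] & ~outside[nbs]]
        outside[nxt] = True
        frontier = nxt
    return outside


def border_sites(lattice: Lattice, outer_only: bool = True) -> np.ndarray:
    """Sites forming the spheroid surface: occupied sites with at least
    one free neighbor.

    With ``outer_only`` (default) only neighbors belonging to the outside
    medium count, so interior holes (lysed cells) do not masquerade as
    border — radial statistics are measured from the true surface.
    """
    occ = lattice.occupant != EMPTY
    if not occ.any():
        return np.empty(0, dtype=np.int64)
    free = (lattice.occupant == EMPTY)
    if outer_only:
        free = free & outside_free_mask(lattice)
    nb_free = free[lattice.indices].astype(np.int64)
    counts = np.add.reduceat(nb_free, lattice.indptr[:-1])
    counts[lattice.indptr[:-1] == lattice.indptr[1:]] = 0
    return np.flatnonzero(occ & (counts > 0))


def distance_to_border(lattice: Lattice, site_id: int) -> float:
    """Euclidean distance (um) from an occupied site to the nearest border
    site.  A border cell (or an isolated cell) is at distance 0."""
    if lattice.occupant[site_id] == EMPTY:
        raise ValueError(f"site {site_id} is not occupied by a spheroid cell")
    border = border_sites(lattice)
    if len(border) == 0:
        raise ValueError("population is empty")
    d = np.linalg.norm(lattice.positions[border] - lattice.positions[site_id],
                       axis=1)
    return float(d.min())


def distances_to_border(lattice: Lattice, site_ids: np.ndarray) -> np.ndarray:
    """Vectorized Euclidean border distances for many occupied sites."""
    border = border_sites(lattice)
    if len(border) == 0:
        raise ValueError("population is empty")
    tree = cKDTree(lattice.positions[border])
    d, _ = tree.query(lattice.positions[site_ids])
    return np.asarray(d, dtype=float)


# -- serialization ---------------------------------------------------------


def save_lattice_hdf5(lattice: Lattice, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=lattice.positions)
        f.create_dataset("indptr", data=lattice.indptr)
        f.create_dataset("indices", data=lattice.indices)
        f.create_dataset("occupant", data=lattice.occupant)
        f.create_dataset("is_boundary", data=lattice.is_boundary)
        f.create_dataset("grid_index", data=lattice.grid_index)
        for k in ("spacing", "n_per_dim", "jitter", "seed"):
            f.attrs[k] = getattr(lattice, k)


def load_lattice_hdf5(path: str) -> Lattice:
    import h5py

    with h5py.File(path, "r") as f:
        lat = Lattice(
            positions=f["positions"][...],
            indptr=f["indptr"][...],
            indices=f["indices"][...],
            spacing=float(f.attrs["spacing"]),
            n_per_dim=int(f.attrs["n_per_dim"]),
            jitter=float(f.attrs["jitter"]),
            seed=int(f.attrs["seed"]),
            occupant=f["occupant"][...],
            is_boundary=f["is_boundary"][...],
            grid_index=f["grid_index"][...],
        )
    return lat


def site_table(lattice: Lattice):
    """Plain site table (pandas DataFrame) for inspection / CSV export."""
    import pandas as pd

    return pd.DataFrame({
        "site": np.arange(lattice.n_sites),
        "x": lattice.positions[:, 0],
        "y": lattice.positions[:, 1],
        "z": lattice.positions[:, 2],
        "occupant": lattice.occupant,
        "boundary": lattice.is_boundary,
        "degree": np.diff(lattice.indptr),
    })
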