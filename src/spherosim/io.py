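"""Snapshot serialization: population tables (CSV) and field arrays
(HDF5), plus tidy exports of curves and profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cells import Population
from .fields import FieldState, SPECIES


def population_table(population: Population) -> pd.DataFrame:
    """Cell table: id, state, cycle stage, occupied sites, exposure."""
    rows = []
    for c in population.iter_alive():
        rows.append({
            "id": c.id,
            "state": c.state.name,
            "M": c.M,
            "site_0": c.sites[0] if c.sites else -1,
            "site_1": c.sites[1] if len(c.sites) > 1 else -1,
            "n_exp": c.n_exp,
            "t_birth": c.t_birth,
        })
    return pd.DataFrame(rows)


def save_population_csv(population: Population, path: str) -> None:
    population_table(population).to_csv(path, index=False)


def save_population_hdf5(population: Population, path: str) -> None:
    """Population snapshot as an HDF5 table (columns as datasets)."""
    import h5py

    df = population_table(population)
    with h5py.File(path, "w") as f:
        for col in df.columns:
            data = df[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S16")
            f.create_dataset(col, data=data)


def save_fields_hdf5(state: FieldState, path: str, t: float = 0.0) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["time_h"] = t
        for name in SPECIES:
            f.create_dataset(name, data=state.species(name),
                             compression="gzip")
        f.create_dataset("sigma", data=state.sigma, compression="gzip")
        f.create_dataset("sigma_D", data=state.sigma_D, compression="gzip")
        f.create_dataset("tumor_mask",
                         data=state.tumor_mask.astype(np.uint8),
                         compression="gzip")


def load_fields_hdf5(path: str) -> tuple[dict, float]:
    import h5py

    with h5py.File(path, "r") as f:
        arrays = {k: f[k][...] for k in f.keys()}
        t = float(f.attrs.get("time_h", 0.0))
    return arrays, t


def radial_average_csv(state: FieldState, spacing: float, path: str) -> None:
    """Radial (distance-from-grid-center) averages of every field, CSV."""
    shape = state.G.shape
    idx = np.indices(shape)
    ctr = (np.array(shape) - 1) / 2.0
    r = np.sqrt(((idx - ctr[:, None, None, None]) ** 2).sum(axis=0)) * spacing
    bins = (r // spacing).astype(int)
    out = {"radius_um": (np.arange(bins.max() + 1) + 0.5) * spacing}
    for name in SPECIES:
        vals = state.species(name).ravel()
        sums = np.bincount(bins.ravel(), weights=vals)
        counts = np.bincount(bins.ravel())
        out[name] = sums / np.maximum(counts, 1)
    pd.DataFrame(out).to_csv(path, index=False)
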