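"""Growth curves, virtual-staining radial profiles, and the Gaussian
likelihood / AIC comparison surface.

Radial statistics mirror the image analysis of spheroid cryosections:
distances are measured from the spheroid *border* inward (robust to
ellipsoidal shapes), cells in the cycle play the role of Ki67-positive
nuclei, dying (not-yet-lysed) cells the role of TUNEL-positive nuclei, and
the ECM field stands in for the Collagen IV intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lattice import Lattice, distances_to_border
from .cells import Population, CellState


@dataclass
class GrowthCurve:
    """Radius-vs-time series plus per-state population counts."""

    times: list = field(default_factory=list)        # h
    radius: list = field(default_factory=list)       # um
    counts: list = field(default_factory=list)       # dict per time point

    def append(self, t: float, r: float, counts: dict) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("times must be strictly increasing")
        if r < 0:
            raise ValueError("radius must be >= 0")
        self.times.append(t)
        self.radius.append(r)
        self.counts.append(dict(counts))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, r, c in zip(self.times, self.radius, self.counts):
            rows.append({"time_h": t, "radius_um": r, **c})
        return pd.DataFrame(rows)


def spheroid_radius(population: Population, lattice: Lattice,
                    estimator: str = "volume") -> float:
    """Spheroid radius in um.

    "volume": volume-equivalent sphere over occupied (non-lysed) sites,
    r = (3 N V_site / 4 pi)^(1/3).  "border": mean distance of border
    cells from the occupied-site centroid (alternative estimator).
    """
    occupied = np.flatnonzero(lattice.occupant >= 0)
    if len(occupied) == 0:
        raise ValueError("population is empty")
    if estimator == "volume":
        vol = len(occupied) * lattice.site_volume
        return float((3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0))
    if estimator == "border":
        from .lattice import border_sites
        border = border_sites(lattice)
        centroid = lattice.positions[occupied].mean(axis=0)
        return float(np.linalg.norm(lattice.positions[border] - centroid,
                                    axis=1).mean())
    raise ValueError(f"unknown estimator {estimator!r}")


@dataclass
class RadialProfile:
    """Border-distance-binned fractions of cycling / dying cells and mean
    ECM intensity.  Empty bins carry count 0 and NaN fractions (flagged,
    not zero-filled)."""

    bin_edges: np.ndarray          # um, contiguous
    count: np.ndarray              # non-lysed cells per bin
    count_cycling: np.ndarray
    count_dying: np.ndarray
    frac_cycling: np.ndarray       # Ki67-analogue
    frac_dying: np.ndarray         # TUNEL-analogue
    ecm_mean: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "border_distance_um": self.bin_centers,
            "count": self.count,
            "count_cycling": self.count_cycling,
            "count_dying": self.count_dying,
            "frac_cycling": self.frac_cycling,
            "frac_dying": self.frac_dying,
            "ecm_mean": self.ecm_mean,
        })


def radial_profile(population: Population, lattice: Lattice,
                   ecm_at_cell=None, bin_width: float = 16.8) -> RadialProfile:
    """Border-distance profile of the cycling and dying fractions.

    ``ecm_at_cell`` optionally maps a cell to its local ECM intensity
    (callable); if omitted the ECM column is NaN.  Bin i covers
    [i*h, (i+1)*h) — half-open, so a distance exactly on an edge belongs
    to the upper bin.
    """
    cells = [c for c in population.iter_alive()]
    if not cells:
        raise ValueError("population is empty")
    sites = np.array([c.sites[0] for c in cells])
    dist = distances_to_border(lattice, sites)
    states = np.array([c.state for c in cells])

    n_bins = max(1, int(np.floor(dist.max() / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width
    which = np.minimum((dist // bin_width).astype(int), n_bins - 1)

    count = np.bincount(which, minlength=n_bins).astype(float)
    cyc = np.bincount(which, weights=(states == CellState.CYCLING),
                      minlength=n_bins)
    dyg = np.bincount(which, weights=(states == CellState.DYING),
                      minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_c = np.where(count > 0, cyc / count, np.nan)
        frac_d = np.where(count > 0, dyg / count, np.nan)
    if ecm_at_cell is not None:
        ecm_vals = np.array([ecm_at_cell(c) for c in cells], dtype=float)
        ecm_sum = np.bincount(which, weights=ecm_vals, minlength=n_bins)
        ecm_mean = np.where(count > 0, ecm_sum / count, np.nan)
    else:
        ecm_mean = np.full(n_bins, np.nan)
    return RadialProfile(edges, count, cyc, dyg, frac_c, frac_d, ecm_mean)


def profile_replicates(profiles: list[RadialProfile]) -> pd.DataFrame:
    """Mean and across-replicate standard deviation of matching bins."""
    n = max(len(p.count) for p in profiles)

    def pad(a):
        out = np.full(n, np.nan)
        out[:len(a)] = a
        return out

    frames = []
    for stat in ("frac_cycling", "frac_dying", "ecm_mean"):
        stack = np.vstack([pad(getattr(p, stat)) for p in profiles])
        with np.errstate(invalid="ignore"):
            frames.append(pd.DataFrame({
                "bin": np.arange(n),
                "statistic": stat,
                "mean": np.nanmean(stack, axis=0),
                "sd": np.nanstd(stack, axis=0, ddof=1) if len(profiles) > 1
                      else np.full(n, np.nan),
            }))
    return pd.concat(frames, ignore_index=True)


# -- likelihood / AIC ------------------------------------------------------


def gaussian_loglik(x, mu, sigma) -> float:
    """Gaussian i.i.d. log-likelihood of model values x against data
    means mu with standard deviations sigma:

        lnL = sum_i [ -1/2 ln(2 pi sigma_i^2) - (x_i - mu_i)^2 / (2 sigma_i^2) ]

    Points with large sigma are weighted less.  sigma_i = 0 is an error.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if not (x.shape == mu.shape == sigma.shape):
        raise ValueError("x, mu, sigma must have equal lengths")
    bad = np.flatnonzero(sigma <= 0)
    if len(bad):
        raise ValueError(f"sigma must be > 0 (violated at index {bad[0]})")
    return float(np.sum(-0.5 * np.log(2.0 * np.pi * sigma ** 2)
                        - (x - mu) ** 2 / (2.0 * sigma ** 2)))


def aic(lnL: float, k: int) -> float:
    """Akaike information criterion, AIC = 2k - 2 lnL."""
    return 2.0 * k - 2.0 * lnL


@dataclass
class FitResult:
    """Likelihood summary for one model against a set of reference curves."""

    lnL: float
    k: int
    per_curve: dict

    @property
    def AIC(self) -> float:
        return aic(self.lnL, self.k)

    def to_dict(self) -> dict:
        return {"lnL": self.lnL, "k": self.k, "AIC": self.AIC,
                "per_curve": dict(self.per_curve)}


def delta_aic(a: FitResult, b: FitResult) -> float:
    """AIC(a) - AIC(b) = 2 dk - 2 dlnL; antisymmetric."""
    return a.AIC - b.AIC


def compare_to_reference(curves: dict, reference: dict, k: int) -> FitResult:
    """Score simulated curves against reference means/sds.

    ``curves`` maps name -> (x_grid, values); ``reference`` maps the same
    name -> (x_grid, mu, sigma).  Simulated values are linearly
    interpolated onto the reference grid.
    """
    if not reference:
        raise ValueError("empty reference")
    per = {}
    total = 0.0
    for name, (xr, mu, sd) in reference.items():
        if name not in curves:
            raise ValueError(f"missing simulated curve {name!r}")
        xs, vals = curves[name]
        x_model = np.interp(np.asarray(xr, float), np.asarray(xs, float),
                            np.asarray(vals, float))
        ll = gaussian_loglik(x_model, mu, sd)
        per[name] = ll
        total += ll
    return FitResult(lnL=total, k=k, per_curve=per)
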