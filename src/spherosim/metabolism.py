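"""Cross-linked glucose/oxygen consumption and the derived ATP and lactate
production rates.

The consumption model is an extended Michaelis-Menten form in which the
maximal uptake of each substrate is down-regulated by the availability of
the other (cells fed plenty of oxygen consume less glucose, and vice
versa):

    q_G  = V_G_max  * G / (G + k_G_G)
    q_O2 = V_O2_max * O / (O + k_O2_O2)

    V_G_max  = q_G_max  * (1 - (1 - q_G_min /q_G_max ) * O / (O + k_G_O2))
    V_O2_max = q_O2_max * (1 - (1 - q_O2_min/q_O2_max) * G / (G + k_O2_G))

ATP output combines the glycolytic yield (2 ATP per glucose) with the
oxidative yield (17 ATP per pyruvate, i.e. 17/3 per O2 consumed since three
O2 are used per pyruvate):

    p_ATP = 2 q_G + (17/3) q_O2        for G > G_crit, else 0.

Lactate arises from the anaerobically metabolized share of glucose.  With
6 O2 per fully oxidized glucose, the aerobic glucose flux is q_O2/6 and
each of the remaining (q_G - q_O2/6) glucose yields two lactate:

    p_L = max(0, 2 q_G - q_O2 / 3).

All rates are per unit tissue volume at confluent density (mM/h for the
reference cell volume of 2700 um^3); :func:`convert_rate_units` maps them
to per-cell molar rates.

Functions are vectorized: scalar or ndarray ``G``/``O`` inputs are
accepted symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .lattice import REFERENCE_CELL_VOLUME

#: liters per um^3 is irrelevant here: mM = mol/m^3, so a rate r in mM/h over
#: a cell volume V um^3 corresponds to r * (V * 1e-18 m^3) / 3600 mol/cell/s.
_M3_PER_UM3 = 1e-18
_S_PER_H = 3600.0


@dataclass
class MetabolicParams:
    """Consumption-model constants (EMT6/Ro-derived defaults).

    Units: half-saturation constants in mM, rates in mM/h, the reference
    cell volume in um^3.  ``atp_per_o2`` defaults to 17/3 (17 ATP per
    pyruvate, 3 O2 per pyruvate); the alternative 18-ATP bookkeeping is
    available by passing ``atp_per_o2=6.0``.
    """

    k_G_G: float = 0.068
    k_G_O2: float = 0.031
    k_O2_O2: float = 0.031
    k_O2_G: float = 0.100
    q_G_min: float = 186.67
    q_G_max: float = 706.67
    q_O2_min: float = 120.00
    q_O2_max: float = 306.66
    G_crit: float = 0.01
    atp_per_glycolysis: float = 2.0
    atp_per_o2: float = 17.0 / 3.0
    lactate_per_glucose: float = 2.0
    cell_volume: float = REFERENCE_CELL_VOLUME
    #: if True use the literal printed lactate source 2 q_G - q_O2/6
    lactate_printed_form: bool = False

    def __post_init__(self) -> None:
        for name in ("k_G_G", "k_G_O2", "k_O2_O2", "k_O2_G",
                     "q_G_min", "q_G_max", "q_O2_min", "q_O2_max", "G_crit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.q_G_min >= self.q_G_max:
            raise ValueError("q_G_min must be < q_G_max")
        if self.q_O2_min >= self.q_O2_max:
            raise ValueError("q_O2_min must be < q_O2_max")

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_PARAMS = MetabolicParams()


def _check_nonneg(G, O) -> tuple[np.ndarray, np.ndarray]:
    G = np.asarray(G, dtype=float)
    O = np.asarray(O, dtype=float)
    if np.any(G < 0) or np.any(O < 0):
        raise ValueError("concentrations must be non-negative")
    return G, O


def glucose_uptake(G, O, params: MetabolicParams = DEFAULT_PARAMS):
    """Glucose consumption rate q_G(G, O), mM/h."""
    G, O = _check_nonneg(G, O)
    vmax = params.q_G_max * (
        1.0 - (1.0 - params.q_G_min / params.q_G_max) * O / (O + params.k_G_O2)
    )
    out = vmax * G / (G + params.k_G_G)
    return out if out.ndim else float(out)


def oxygen_uptake(G, O, params: MetabolicParams = DEFAULT_PARAMS):
    """Oxygen consumption rate q_O2(G, O), mM/h."""
    G, O = _check_nonneg(G, O)
    vmax = params.q_O2_max * (
        1.0 - (1.0 - params.q_O2_min / params.q_O2_max) * G / (G + params.k_O2_G)
    )
    out = vmax * O / (O + params.k_O2_O2)
    return out if out.ndim else float(out)


def atp_production(G, O, params: MetabolicParams = DEFAULT_PARAMS):
    """ATP production rate p_ATP = 2 q_G + (17/3) q_O2, mM/h.

    Below the critical glucose concentration ``G_crit`` no pyruvate is
    available and the rate is zero.
    """
    G, O = _check_nonneg(G, O)
    q_g = np.asarray(glucose_uptake(G, O, params))
    q_o = np.asarray(oxygen_uptake(G, O, params))
    p = params.atp_per_glycolysis * q_g + params.atp_per_o2 * q_o
    p = np.where(G > params.G_crit, p, 0.0)
    return p if p.ndim else float(p)


def lactate_production(G, O, params: MetabolicParams = DEFAULT_PARAMS):
    """Lactate production rate p_L, mM/h (anaerobic glucose x 2)."""
    G, O = _check_nonneg(G, O)
    q_g = np.asarray(glucose_uptake(G, O, params))
    q_o = np.asarray(oxygen_uptake(G, O, params))
    divisor = 6.0 if params.lactate_printed_form else 3.0
    p = np.maximum(0.0, params.lactate_per_glucose * q_g - q_o / divisor)
    return p if p.ndim else float(p)


def aerobic_glucose_fraction(G, O, params: MetabolicParams = DEFAULT_PARAMS):
    """Fraction of consumed glucose fully oxidized, q_O2 / (6 q_G) in [0,1].

    Undefined when no glucose is consumed (raises ``ValueError`` for a
    scalar query; array queries return NaN at those entries).
    """
    G, O = _check_nonneg(G, O)
    q_g = np.asarray(glucose_uptake(G, O, params))
    q_o = np.asarray(oxygen_uptake(G, O, params))
    if q_g.ndim == 0:
        if q_g == 0:
            raise ValueError("aerobic fraction undefined at q_G = 0")
        return float(np.clip(q_o / (6.0 * q_g), 0.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(q_g > 0, q_o / (6.0 * q_g), np.nan)
    return np.clip(frac, 0.0, 1.0)


def uptake_jacobian(G, O, params: MetabolicParams = DEFAULT_PARAMS):
    """Partial derivatives of the uptake rates w.r.t. both substrates.

    Returns (dqG/dG, dqG/dO, dqO/dG, dqO/dO); used by the monolithic
    Newton solve of the coupled steady-state diffusion problem.
    """
    G = np.asarray(G, dtype=float)
    O = np.asarray(O, dtype=float)
    aG = 1.0 - params.q_G_min / params.q_G_max
    aO = 1.0 - params.q_O2_min / params.q_O2_max
    vG = params.q_G_max * (1.0 - aG * O / (O + params.k_G_O2))
    vO = params.q_O2_max * (1.0 - aO * G / (G + params.k_O2_G))
    sG = G / (G + params.k_G_G)
    sO = O / (O + params.k_O2_O2)
    dqG_dG = vG * params.k_G_G / (G + params.k_G_G) ** 2
    dqG_dO = -params.q_G_max * aG * params.k_G_O2 / (O + params.k_G_O2) ** 2 * sG
    dqO_dO = vO * params.k_O2_O2 / (O + params.k_O2_O2) ** 2
    dqO_dG = -params.q_O2_max * aO * params.k_O2_G / (G + params.k_O2_G) ** 2 * sO
    return dqG_dG, dqG_dO, dqO_dG, dqO_dO


def convert_rate_units(rate, cell_volume: float = REFERENCE_CELL_VOLUME,
                       to: str = "mol_per_cell_s"):
    """Convert between mM/h (tissue-volume rate) and mol/cell/s.

    For the 2700 um^3 reference volume, 1 mol/cell/s = 13.3e17 mM/h.

    Parameters
    ----------
    rate : scalar or array.
    to : "mol_per_cell_s" (input mM/h) or "mM_per_h" (input mol/cell/s).
    """
    if cell_volume <= 0:
        raise ValueError("cell_volume must be > 0")
    rate = np.asarray(rate, dtype=float)
    factor = cell_volume * _M3_PER_UM3 / _S_PER_H  # mM/h -> mol/cell/s
    if to == "mol_per_cell_s":
        out = rate * factor
    elif to == "mM_per_h":
        out = rate / factor
    else:
        raise ValueError(f"unknown conversion target {to!r}")
    return out if out.ndim else float(out)


def rate_surface(G_values, O_values, params: MetabolicParams = DEFAULT_PARAMS):
    """Tidy (G, O) -> {q_G, q_O2, p_ATP, p_L, aerobic_fraction} table."""
    import pandas as pd

    rows = []
    for g in np.atleast_1d(G_values):
        for o in np.atleast_1d(O_values):
            q_g = glucose_uptake(g, o, params)
            rows.append({
                "G_mM": g,
                "O_mM": o,
                "q_G_mM_h": q_g,
                "q_O2_mM_h": oxygen_uptake(g, o, params),
                "p_ATP_mM_h": atp_production(g, o, params),
                "p_L_mM_h": lactate_production(g, o, params),
                "aerobic_fraction": (
                    aerobic_glucose_fraction(g, o, params) if q_g > 0 else np.nan
                ),
            })
    return pd.DataFrame(rows)
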