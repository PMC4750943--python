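"""Division / quiescence / death rules of the four growth-control model
variants, as pure (vectorized) functions of the local state.

Variant 1  gates division and death on the glucose-oxygen product
           crossing a threshold p_oxyglc.
Variant 2  replaces the product by the local ATP production rate p_ATP
           (threshold p_ATP_min = 900 mM/h).
Variant 3  adds lactate-induced death through a Hill switch with
           half-maximal rate at L_max = 20 mM.
Variant 4  additionally reduces the division rate by one half per adverse
           flag (waste above W_max, oxygen below O_min) and permanently
           blocks cycle re-entry once the accumulated exposure n_exp
           exceeds n_exp_max cell cycles.

Heaviside convention: H(x) = 1 for x >= 0, else 0.  Death thresholds use
the complementary gate 1 - H(x) so that division and starvation death are
never simultaneously enabled at the same local state (variants 1-2).

The two hazards of variants 3-4 (ATP starvation and lactate toxicity) are
combined as a probabilistic OR, k = k_max * (s + hill - s*hill): lactate
death can occur even with ample ATP, matching the narrative that lactate
is an *additional* death trigger.  The literal product form is available
via ``nec_combination="product"`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


def heaviside(x):
    """H(x) = 1 for x >= 0, else 0 (vectorized)."""
    out = np.where(np.asarray(x, dtype=float) >= 0.0, 1.0, 0.0)
    return out if out.ndim else float(out)


@dataclass
class ModelSpec:
    """Variant id plus every threshold/rate entering the transition rules.

    ``k_div_max`` defaults to None, meaning "1/tau of the cell-cycle
    parameters in use"; thresholds without a printed source value
    (p_oxyglc, W_max, O_min) carry calibrated defaults documented in the
    methods note.
    """

    variant: int = 4
    delta_L: float = 3.0          # pushing range of the division probability, sites
    ecm_min: float = 0.003        # minimal ECM intensity for cycle entry
    p_oxyglc: float = 0.1         # mM^2, variant-1 threshold (calibrated)
    p_atp_min: float = 900.0      # mM/h
    L_max: float = 20.0           # mM, half-maximal lactate death
    hill_n: int = 2
    W_max: float = 5.0e-4         # dimensionless waste threshold (calibrated)
    O_min: float = 0.08           # mM hypoxia threshold (calibrated)
    n_exp_max: float = 8.0        # cell cycles of tolerated exposure
    k_div_max: float | None = None   # 1/h; None -> 1/tau
    k_nec_max: float = 0.1        # 1/h
    nec_combination: str = "noisy_or"   # or "product" (literal printed form)
    exposure_absolute_time: bool = False
    deterministic_pdiv: bool = False    # Heaviside gate instead of exp(-L/DL)

    def __post_init__(self) -> None:
        if self.variant not in (1, 2, 3, 4):
            raise ValueError(f"variant must be 1-4, got {self.variant}")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        for name in ("delta_L", "ecm_min", "p_oxyglc", "p_atp_min", "L_max",
                     "W_max", "O_min", "n_exp_max", "k_nec_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def p_div(L_dist, ECM, n_exp, spec: ModelSpec):
    """Probability that a daughter cell re-enters the cell cycle.

    ``L_dist`` is the graph distance (sites) to the closest free lattice
    site; ``np.inf`` (no free site found) gives probability 0.  The ECM
    gate requires the local matrix intensity to reach ``ecm_min``; variant
    4 additionally blocks over-exposed cells (n_exp >= n_exp_max).
    """
    L_dist = np.asarray(L_dist, dtype=float)
    if np.any(L_dist < 0):
        raise ValueError("L_dist must be >= 0")
    if spec.deterministic_pdiv:
        base = heaviside(spec.delta_L - L_dist)
    else:
        with np.errstate(over="ignore"):
            base = np.exp(-L_dist / spec.delta_L)
    p = base * heaviside(np.asarray(ECM, dtype=float) - spec.ecm_min)
    if spec.variant == 4:
        p = p * heaviside(spec.n_exp_max - np.asarray(n_exp, dtype=float))
    p = np.clip(p, 0.0, 1.0)
    return p if p.ndim else float(p)


def _k_max(spec: ModelSpec, k_div_max: float | None) -> float:
    k = spec.k_div_max if spec.k_div_max is not None else k_div_max
    if k is None:
        raise ValueError("k_div_max not set (neither in spec nor argument)")
    return k


def k_div(G, O, W, p_ATP, spec: ModelSpec, k_div_max: float | None = None):
    """Cell-cycle progression rate (1/h) under the active variant."""
    kmax = _k_max(spec, k_div_max)
    G = np.asarray(G, dtype=float)
    O = np.asarray(O, dtype=float)
    if spec.variant == 1:
        k = kmax * heaviside(G * O - spec.p_oxyglc)
    else:
        k = kmax * heaviside(np.asarray(p_ATP, dtype=float) - spec.p_atp_min)
        if spec.variant == 4:
            k = k * (1.0 - 0.5 * heaviside(np.asarray(W, dtype=float) - spec.W_max)) \
                  * (1.0 - 0.5 * heaviside(spec.O_min - O))
    k = np.asarray(k)
    return k if k.ndim else float(k)


def hill_lactate(L, spec: ModelSpec):
    """Hill switch L^n / (L_max^n + L^n); half-maximal at L = L_max."""
    L = np.asarray(L, dtype=float)
    h = L ** spec.hill_n / (spec.L_max ** spec.hill_n + L ** spec.hill_n)
    return h if h.ndim else float(h)


def k_nec(G, O, L, p_ATP, spec: ModelSpec):
    """Death (necrosis) rate, 1/h."""
    G = np.asarray(G, dtype=float)
    O = np.asarray(O, dtype=float)
    if spec.variant == 1:
        k = spec.k_nec_max * (1.0 - heaviside(G * O - spec.p_oxyglc))
    elif spec.variant == 2:
        k = spec.k_nec_max * (1.0 - heaviside(np.asarray(p_ATP, dtype=float)
                                              - spec.p_atp_min))
    else:
        starv = 1.0 - heaviside(np.asarray(p_ATP, dtype=float) - spec.p_atp_min)
        hill = hill_lactate(L, spec)
        if spec.nec_combination == "noisy_or":
            k = spec.k_nec_max * (starv + hill - starv * hill)
        elif spec.nec_combination == "product":
            k = spec.k_nec_max * starv * hill
        else:
            raise ValueError(f"unknown nec_combination {spec.nec_combination!r}")
    k = np.asarray(k)
    return k if k.ndim else float(k)


def exposure_increment(W, O, elapsed: float, spec: ModelSpec, k_div_local,
                       k_div_max: float | None = None):
    """Increment of the cumulative exposure counter n_exp over ``elapsed``
    hours.

    Exposure accrues whenever waste exceeds W_max OR oxygen falls below
    O_min, at the pace of the local cycle rate (cell-cycle units).  With
    ``exposure_absolute_time`` the maximal rate is used instead, i.e. the
    clock ticks in absolute time regardless of cycle slow-down.
    """
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    exposed = (np.asarray(W, dtype=float) > spec.W_max) | \
              (np.asarray(O, dtype=float) < spec.O_min)
    if spec.exposure_absolute_time:
        rate = _k_max(spec, k_div_max)
    else:
        rate = np.asarray(k_div_local, dtype=float)
    inc = np.where(exposed, rate * elapsed, 0.0)
    return inc if inc.ndim else float(inc)
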