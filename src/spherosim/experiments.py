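"""Pre-configured desk-scale experiments.

The reference study tracks spheroids of ~10^4 cells for up to 48 days
under the four nutrient media.  The desk-scale configurations reproduce
the same mechanisms on a smaller stage — a few hundred initial cells in a
~570 um box followed for 8 days with hourly field refreshes — so that a
full four-condition comparison runs on a laptop.  The methods note
documents the choices; the full experiment scale remains available by
overriding ``initial_cells``, ``n_per_dim``, ``t_end``, ``field_interval``
and ``model.n_exp_max``.
"""

from __future__ import annotations

from .config import SimulationConfig
from .simulator import RunResult, run


def desk_scale_config(condition: str, seed: int = 0, variant: int = 4,
                      **overrides) -> SimulationConfig:
    """Desk-scale run configuration for one nutrient condition.

    Scaled-down study conditions: 1000 initial cells (so the spheroid
    starts near the size at which nutrient gradients matter, as in the
    reference experiments), 34^3 lattice, 156 h horizon, 1.5 h field
    updates, solver tolerance 1e-5, and a 2-cycle exposure delay
    (shortened with the horizon).
    """
    cfg = SimulationConfig.for_condition(condition)
    cfg.seed = seed
    cfg.model.variant = variant
    cfg.n_per_dim = 34
    cfg.initial_cells = 1000
    cfg.t_end = 156.0
    cfg.field_interval = 1.5
    cfg.output_interval = 24.0
    cfg.solver_tol = 1e-5
    cfg.model.n_exp_max = 2.0
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def run_four_conditions(seed: int = 0, variant: int = 4,
                        conditions=("I", "II", "III", "IV"),
                        **overrides) -> dict[str, RunResult]:
    """Run the four-condition comparison at desk scale."""
    out = {}
    for name in conditions:
        out[name] = run(desk_scale_config(name, seed=seed, variant=variant,
                                          **overrides))
    return out
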