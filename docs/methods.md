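# Methods

`spherosim` simulates the growth of an avascular multicellular tumor
spheroid (MCTS) as a hybrid model: individual cells live on an
unstructured 3D lattice and evolve by an exact stochastic simulation
algorithm, while glucose, oxygen, lactate, extracellular matrix (ECM) and
a diffusible "waste" inhibitor are continuum fields solved to steady state
on a congruent regular grid. Four nested growth-control hypotheses
(model variants 1–4) map the local fields onto division, quiescence and
death decisions. This note records the model, its numerical treatment,
the parameter choices that were genuinely open, and what the desk-scale
test conditions do and do not demonstrate.

## Cell lattice

Cells occupy sites of a jittered cubic point set (pitch 16.8 µm — the
measured cell diameter — jitter amplitude 0.25·pitch) whose Delaunay
triangulation defines site adjacency; at most one cell per site, and a
cell occupies one or two sites. A zero-jitter lattice degenerates to the
6-neighbor cubic grid (the Delaunay triangulation of a perfect grid is
not unique, so the canonical grid adjacency is used there).

Two geometric caveats are inherent to this construction and are stated
rather than hidden. First, the mean *nearest-neighbor* distance of a
jittered grid is 0.80–0.95× the pitch (jitter-dependent), while the mean
*adjacent* (Delaunay-edge) distance is ≈1.45× the pitch; "lattice
spacing" in this package always means the pitch. Migration hop rates are
therefore calibrated with the measured mean-square adjacent-site
distance, `lambda = 6 D / <l²>`, which makes unbiased hopping reproduce
the free-diffusion law MSD = 6 D t on any jitter. Second, one site
represents one cell of the reference volume 2700 µm³ (a 16.8 µm sphere);
the cubic cell of the pitch (4742 µm³) additionally contains interstitial
space. Radius and density estimates use the 2700 µm³ per-cell volume.

The outermost lattice layer belongs to the medium and can never be
occupied; a pushing chain that would place a cell there aborts the run
(the box must be sized generously). The spheroid *surface* used by radial
statistics is the set of occupied sites adjacent to free space that is
connected to the box boundary — interior holes left by lysed cells do not
count as surface.

## Cell dynamics

All transitions are Poisson processes simulated exactly (Gillespie): the
waiting time is exponential at the summed rate, the event is chosen
proportionally to its rate. The cell cycle has `m_d` stages traversed at
rate `m_d·k_div`, so cycle times are Erlang(m_d) with mean `1/k_div` and
CV `1/sqrt(m_d)`; division occurs on completing the last stage. At stage
`m_g` the cell occupies a second adjacent site, liberating one by pushing
the chain of cells along the shortest path to the nearest free site (ties
broken by smallest site index) when necessary; if no free site is
reachable within the pushing cap the growth is deferred and retried at
the next stage event. Each daughter independently re-enters the cycle
with probability

    p_div = exp(-L / ΔL) · H([ECM] − [ECM]_min)   (variant 4: · H(n_exp_max − n_exp))

evaluated at its own site (`L` = hop distance to the nearest free site),
else it becomes permanently quiescent (re-entry is available through
`k_re, p_re` but disabled by default, matching the finding that re-entry
is negligible for this cell line). Dying cells retain their sites (they
are the TUNEL-positive population) until lysis (`k_lys = 0.01/h`,
i.e. ≈100 h — the slow in-vitro value; fast in-vivo lysis would erase the
necrotic core) frees them. Apoptosis is negligible (`k_apt = 0`).

Defaults `m_d = 10`, `m_g = 5`, `tau = 18 h` are plausible for a NSCLC
line in culture and are configurable; every statistical test uses the
Erlang moment laws so it holds for any `m_d`.

`H` is the Heaviside step with `H(0) = 1`. Death gates use the
complement `1 − H(x)` so division and starvation death are never enabled
simultaneously at one local state.

## Metabolism

Glucose and oxygen consumption follow the cross-inhibited
Michaelis–Menten model (constants fitted historically on EMT6/Ro
spheroids): each substrate's maximal uptake is reduced by the
availability of the other. ATP output is `p_ATP = 2 q_G + (17/3) q_O2`
(2 ATP per glycolytic glucose; 17 ATP per pyruvate with 3 O₂ each, the
17-ATP bookkeeping; 18 is a switch), zero below the critical glucose
concentration 0.01 mM. Lactate is produced by the anaerobically
metabolized glucose share: the aerobic flux is `q_O2/6` (6 O₂ per fully
oxidized glucose), so `p_L = max(0, 2 q_G − q_O2/3)`. The printed form
`2 q_G − q_O2/6` found in the source literature is stoichiometrically
inconsistent with "two lactate per anaerobic glucose" and is available
only as the `lactate_printed_form` switch. The aerobic glucose fraction
`q_O2/(6 q_G)` quantifies the Warburg phenotype (≈7.6% at 25 mM glucose,
0.28 mM O₂). Rates are tissue-volume rates (mM/h at confluent density);
per-cell molar rates use the 2700 µm³ reference volume
(1 mol/cell/s ≡ 13.3·10¹⁷ mM/h).

## Model variants

| variant | division gate | death hazard |
|---|---|---|
| 1 | H([G][O] − p_oxyglc) | complement of the division gate |
| 2 | H(p_ATP − 900 mM/h) | complement |
| 3 | as 2 | ATP-starvation OR lactate Hill switch |
| 4 | as 2, halved per adverse flag (waste, hypoxia) | as 3 |

The lactate switch is the standard Hill form `L^n/(L_max^n + L^n)` with
`L_max = 20 mM` (half-maximal death rate there) and `n = 2`. The two
death causes in variants 3–4 combine as a probabilistic OR
(`s + h − s·h`); the literal product form would abolish starvation death
at zero lactate and contradicts the intent that lactate is an
*additional* trigger (`nec_combination="product"` keeps it for
comparison). Variant 4 additionally accumulates an exposure counter
`n_exp` in cell-cycle units whenever local waste exceeds `W_max` or
oxygen falls below `O_min`; the clock ticks at the ATP-gated *unreduced*
cycle rate, and a cell whose counter passes `n_exp_max` becomes
permanently quiescent at its next division. Daughters inherit the
counter (it tracks the lineage's local history, making the arrest
spatially coherent); an absolute-time accounting is available as a
switch.

Thresholds with no printed source value are calibrations of this
package, chosen once and documented: `p_oxyglc = 0.1 mM²` (places the
variant-1 viability boundary at a ~150 µm depth under rich medium),
`W_max = 5·10⁻⁴` (waste units; the brake engages once a substantial
necrotic core has been shedding debris for a few days),
`O_min = 0.08 mM` (≈5.7% O₂; deliberately *above* the 0.07 mM hypoxic
medium, so that hypoxic-condition tissue is uniformly below threshold —
this is what makes the hypoxic condition stall almost immediately, as
observed), `k_nec_max = 0.1/h`, `ΔL = 3` sites (sets the ~50–100 µm
proliferating rim and a sustainable expected number of cycling daughters
at the front).

## Molecular fields

All five species obey reaction–diffusion equations on the regular grid
the lattice was jittered from (spacing = pitch), 7-point central
differences, harmonic-mean diffusivity at tumor/medium interfaces, and
Dirichlet box faces at medium values (G, O) or zero (L, W, ECM) — the
hanging-drop idealization with medium renewal. Because molecules relax in
seconds–minutes while cells act over hours, G, O, L and W are driven to
steady state at every field refresh. The cell density seen by the solver
spreads each cell evenly over its occupied sites' nodes; sinks scale with
the local cell-volume fraction.

The coupled G/O problem is solved monolithically. The production scheme
is a damped inexact Newton iteration on the two-species system with the
full 2×2 local Jacobian of the cross-inhibited uptake (inner solves:
Jacobi-preconditioned BiCGStab, warm-started; Picard sweeps with the
positivity-preserving proportional linearization serve as globalization
far from the root, and remain available as `scheme="picard"`). Both
schemes converge to the same discrete steady state; convergence is
measured on the relative nonlinear residual (default 10⁻⁸; desk-scale
runs use 10⁻⁶–10⁻⁵). Operators are rebuilt only when the tumor mask
changes, and previous fields seed all solves.

ECM deviates from the steady-state treatment deliberately: collagen
deposition and turnover (`k_deg = 0.012/h`, ~3.5 day time constant) are
*not* fast compared with growth, and a steady-state ECM field would give
the freshly formed outer cell layer the same matrix as the bulk, so no
border depression of proliferation could ever arise. ECM therefore keeps
memory via one backward-Euler step per refresh (`ecm_steady=True`
restores the literal steady-state variant for sensitivity checks).
Its scale is set so the bulk plateau is ≈0.05–0.1 on the Collagen-IV
fluorescence scale where the 0.003 cycle-entry threshold lives; new
tissue crosses the threshold after a few hours, so it is specifically
the outermost, youngest layer that is gated. Initial tissue is seeded
with 48 h worth of ECM (spheroids are pre-formed in hanging drops for
two days before tracking).

Diffusion constants are literature-typical tissue values (O₂ 1000 µm²/s,
glucose/lactate 70 µm²/s, waste 50 µm²/s, ECM ≈ immobile), 30× larger in
the medium; only that ratio has a stated source. All are configurable.

## Temporal evolution

Within each field interval (default 0.1 h; desk-scale runs use 1–1.5 h,
coarse but still ≪ the 18 h cycle time) cell events are simulated exactly
with frozen per-cell rates; at the boundary the exposure counters are
integrated, the fields are re-solved, and all rates are refreshed (they
are also refreshed immediately for cells touched by an event). The
incrementally maintained total event rate is audited against a full
recomputation at every refresh; runs are bitwise reproducible for a
fixed seed (single-threaded).

## Observables and model comparison

Growth curves use the volume-equivalent radius over occupied sites
(`(3 N V_site/4π)^{1/3}`); a border-distance estimator is provided as a
cross-check. Radial profiles bin all non-lysed cells by Euclidean
distance to the spheroid surface (default bin: one cell layer, 16.8 µm):
the cycling fraction is the Ki67-positive analogue, the dying fraction
the TUNEL analogue, and the mean ECM field value the Collagen-IV
intensity. Empty bins are flagged NaN, never zero-filled. Model-data
scoring is the i.i.d. Gaussian log-likelihood (standard negative
exponent) of simulated curves linearly interpolated onto reference
grids, and AIC = 2k − 2 lnL.

## Image analysis

The virtual-microscopy toolbox implements the quantification pipeline:
four 3×3 median passes (reflective edges), flooding watershed on the
inverted nuclear channel above the nuclear threshold (4-connectivity;
8 as option), per-nucleus marker classification by pixel intensity
threshold then positive-pixel fraction threshold (defaults: nuclear 0.15;
TUNEL 0.45/0.20; Ki67 0.35/0.05), lumen estimation by 3 dilations + hole
filling (zero-padded edges), confusion-matrix metrics (TPR, TNR, error
rate), Voronoi-based equivalent cell diameters (unbounded and
out-of-lumen cells excluded), and half-open 1 µm border-distance binning.
The synthetic section generator renders Gaussian-profile nuclei (blue),
marker-positive nuclei (red) and a radial ECM-like field (green) with
configurable noise and background gradient, returning pixel- and
nucleus-level ground truth; it is the benchmark for the pipeline, not a
model of real cryosection artifacts (no staining heterogeneity, optical
blur across z, or sectioning damage), so pipeline scores on it are upper
bounds for real data.

## Desk-scale study conditions

The packaged four-condition experiment
(`spherosim.experiments.run_four_conditions`) runs variant 4 under media
I (1 mM glucose / 0.28 mM O₂), II (5/0.28), III (25/0.28) and
IV (25/0.07) with 1000 initial cells in a 30³ box (≈500 µm across),
168 h horizon, 1.5 h field refreshes and a 2-cycle exposure delay —
roughly a tenth of the reference experiments in cell number and a third
in duration. At this scale the model expresses the qualitative
phenotype ordering: near-linear rim-driven expansion with eventual
slowdown; almost immediate stalling under hypoxic medium (IV); early
central necrosis, waste release and growth-brake under glucose-poor
medium (I); sustained growth with depth-decreasing proliferation, a
border proliferation dip from ECM gating, and late central death under
the richer media (II, III). Absolute radii and the reference study's
likelihood table are *not* reproduced: they require the unpublished
experimental profiles and the full 10⁴-cell, 48-day scale.

## Known limitations

- Two-site cells pushed by a growing neighbor relocate one site at a
  time and may transiently span non-adjacent sites; occupancy
  exclusivity is the guarded invariant.
- The desk-scale field interval (1–1.5 h) is coarse; rates are frozen
  between refreshes (the reference treatment refreshes every 0.1 h).
- The waste and hypoxia thresholds are desk-scale calibrations; at other
  domain sizes they should be re-examined (the brake timing scales with
  spheroid size).
- No mechanics beyond site exclusion and pushing; no detachment,
  necrotaxis, or pH dynamics (explicitly out of scope).
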