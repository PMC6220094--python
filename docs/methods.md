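# Methods

## Scope and model lineage

`vasowave` simulates agonist-driven Ca²⁺ dynamics in the coupled
endothelial (EC) and smooth-muscle (SMC) layers of a bifurcating artery.
The single-cell flux formulations are the published Koenigsberger-family
coupled EC/SMC equations — SMC ionic dynamics in the Parthimos form
(IP₃R release, CICR, SERCA, leak, VOCC, Na⁺/Ca²⁺ exchange, Cl⁻, K⁺, and a
first-order K⁺-gate), EC electrophysiology in the Schuster form (BK/SK
gating in log₁₀[Ca²⁺], residual current, non-selective cation influx) —
with the endothelial agonist limb replaced by an explicit
P2Y → G-protein → PLC → IP₃ cascade in the Lemon/Bennett style. SMC IP₃
has no intrinsic production: it is sourced exclusively from coupled ECs
and decays first order. NO/cGMP, EDH, EET and stretch-activated pathways
are deliberately out of scope: they act on slower timescales than the
store-cycle dynamics that drive the waves studied here.

Units throughout: concentrations µM, potentials mV, time s, lengths mm.

## Geometry and lattice

A bifurcation is three logically rectangular tubular segments (parent and
two daughters) of quadrilateral *domains*, periodic circumferentially and
joined watertight: the parent's terminal vertex ring splits into halves,
one per daughter, and the daughters share the flow-divider (carina)
half-ring whose endpoints are the two saddle points flanking the
bifurcation plane. Daughter radii obey Murray's law
r_p³ = r_d1³ + r_d2³ (symmetric daughters by default; an asymmetry ratio
is a constructor option). Daughter tubes loft smoothly from the shared
junction ring to circular cross-sections over a transition length of two
parent radii. Out-of-plane curvature is a circular-arc bend of the whole
assembly about the bifurcation-plane normal; curvature 0 is planar. The
default full-scale grid (34 axial × 40 circumferential domains per
segment) gives 4080 domains; the per-segment grid is configurable because
only the total is physically constrained.

Each domain holds 208 ECs (13 axial × 16 circumferential; ECs elongated
along the flow) and 80 SMCs (4 × 20; SMCs wrapped circumferentially) —
288 cells per domain. The factorisations are a design choice: only the
totals and the orthogonal cell orientations are constrained, and these
grids tile the same quadrilateral. Homocellular neighbourhoods are
4-connected, periodic circumferentially and stitched across the junction
(with a column mirror for the second daughter); the axial mesh ends are
open. Myoendothelial links are assigned by geometric overlap of the two
grids on the unit square, with weights normalised to sum to one over each
EC, so each EC carries one junction-equivalent of heterocellular coupling
and each SMC aggregates ≈ 2.6 (= 208/80) of them.

Region labels (apex, lateral_seam, inner/outer wall, uniform) derive from
distances to the carina and the saddle points, with thresholds exposed as
arguments; domains touching the landmarks are always labelled, so labels
exist at any valid resolution.

Unwrapping assigns each cell planar (u, v) coordinates with per-segment
column widths and row heights taken from the mean 3D quad dimensions, so
planar areas track surface areas (within 5% per segment); u is periodic.

## Agonist surrogate

The luminal ATP field is steady in time and parametric: a background
level (default 0.5 µM) plus a Gaussian bump at the carina (peak 1.0 µM,
width 0.8 r_p) minus Gaussian wells at the two saddle points (floor
0.2 µM), clipped to the configured [floor, peak]. The seam well width
scales as (80°/angle), making the low-ATP seam area strictly decreasing
in bifurcation angle. This surrogate emulates the *structure* of
CFD-derived surface-concentration maps — stagnation-enriched apex,
detachment-depleted seams, near-uniform elsewhere, values in the
physiological 0.2–1 µM window — but none of their flow physics: no wall
shear stress, no boundary-layer mass transport, no Reynolds/Womersley
dependence. Tests passing on the surrogate therefore validate the
*cellular response to a given agonist pattern*, not the hemodynamic
origin of the pattern; a real CFD map can be imported per cell from CSV.

## Parameter provenance and calibration

All constants live in `data/reference_params.yaml`. Three groups:

* **Single-cell and coupling constants** — published Koenigsberger /
  Parthimos / Schuster values (e.g. SMC CICR 55 µM/s, SERCA 2.025 µM/s,
  VOCC 1.29 × 10⁻³ µM mV⁻¹ s⁻¹, EC K⁺ pool 6927 pS; electrical couplings
  g = G/C_m: 30 nS/30 pF = 1000 s⁻¹ homocellular, ~50 s⁻¹
  myoendothelial from a 900 MΩ / 20 pF junction; Ca²⁺ and IP₃ couplings
  0.05 s⁻¹).
* **IP₃-pathway kinetics** — Lemon-model values where published
  (k_a = 0.017 s⁻¹, k_d = 0.15 s⁻¹, δ = 1.234 × 10⁻³, G_tot = 10⁵,
  K_Ca = 0.4 µM, PIP2_tot = 5 × 10⁷ molecules, V_EC = 1 pL, so
  ε·PIP2_tot ≈ 83 µM).
* **Calibrated gains** — the PLC signal gain α is, by its nature, a
  fitted constant; α = 2.8 × 10⁻⁷ s⁻¹ per G-protein molecule and the
  effective receptor constant K_ATP = 0.025 µM were set *once*, before
  the acceptance suite was written, so that the physiological ATP window
  [0.2, 1] µM spans the SMC oscillatory regime on the reference 288-cell
  domain: seam-level ATP lands just above oscillation onset (long-period
  sporadic spiking over a ~0.2 µM baseline) and apex-level ATP in the
  coherent ~17 s-period regime. K_ATP is low for a P2Y₂ receptor taken
  literally; it is an effective constant absorbing receptor reserve and
  downstream amplification, forced by the narrow (~15%) production
  contrast that fits both regimes inside the oscillatory window.
* **Phosphorylation cycle** — zero-order regime K₁ = K₂ = 0.01 with W_T
  normalised to 1, v_p = 1 s⁻¹, V_MK = 2.5 s⁻¹, K_a = 0.5 µM: a 0.2 µM
  baseline sits below the v_k/v_p = 1 switch and a ≥ 0.6 µM spike above
  it, with reaction rates fast against the ~20 s oscillation period.

The SMC oscillatory window under these couplings (measured by clamped
IP₃ sweeps) is ≈ 0.7–1.8 µM IP₃ for an isolated cell and shifts to
≈ 0.6–1.7 µM on the coupled domain, with the period falling monotonically
from ~20 s near onset to ~10 s — the frequency of oscillation is a
monotonically increasing function of the IP₃ production rate.

## Numerics

The network ODE (5 states per cell; a 288-cell domain is 1440 equations)
is integrated with SciPy's BDF using a block sparsity pattern built from
the lattice adjacency; defaults rtol 10⁻⁶, atol 10⁻⁹. Halving the
tolerances changes recorded traces by < 1% RMS. Initial conditions are
the numerically located zero-ATP rest state of a coupled EC/SMC pair,
tiled over the lattice, with seeded 1% multiplicative perturbations on
the concentration variables (the RNG seed is the experiment's only
randomness; identical seeds reproduce trajectories exactly). State is
recorded every 1 physiological second. An optional domain-decomposed
evaluation mode integrates each domain with ghost state refreshed every
0.01 s, reproducing the communication cadence of a distributed layout on
one process; it matches the monolithic trajectory on short horizons and
exists for that contract, not for speed. A guard floors Ca²⁺ at 10⁻¹²
µM inside the EC gating terms (which take log₁₀ of concentration).

Analysis choices: temporal averages are sample means with inclusive
endpoints (normalising by the sample count keeps the mean inside the
trace's range); dominant periods are median inter-peak intervals with
prominence 0.05 µM and an autocorrelation fallback; baselines are 10th
percentiles (histogram modes for the regime read-outs); wave-front speed
is the inverse slope of a least-squares fit of threshold-crossing time
against distance, with standing oscillations flagged rather than
reported; W̄* is a trapezoidal mean over the full trace by default.

## Reference experiments and problem sizes

The shipped experiments run one 288-cell domain for 500 physiological
seconds per regime (≈ 20 s wall each), wave and collision scenarios on
3-domain strips (~100 s physiological), and synchronization/monotonicity
scenarios on 2–5-cell chains. These sizes were chosen as the smallest
systems that exhibit the phenomena of interest — coherent oscillation,
near-onset sporadic spiking, propagating and annihilating fronts — while
keeping a full suite run in minutes.

## Known limitations

* **Spike amplitude.** With the published flux constants and the strong
  aggregated myoendothelial electrical load (≈ 2.6 × 50 s⁻¹ per SMC
  pulling its membrane toward the hyperpolarised endothelium and muting
  VOCC influx), SMC Ca²⁺ spikes cap near 0.66 µM on the reference
  domain — noticeably below the ~1 µM wave maxima reported for
  cluster-scale bifurcation simulations of this model family. We chose
  to keep the published constants rather than inflate CICR or cut
  extrusion to match the amplitude.
* **Synchronization requires the endothelium.** Isolated chains of
  SMC oscillators at the reference homocellular couplings settle into
  stable splay/antiphase states; with their EC partners present (or on a
  full domain) the SMC oscillations phase-synchronize. The five-cell
  synchronization scenario is therefore posed on EC/SMC units.
* The agonist surrogate carries no hemodynamics (above); heterocellular
  Ca²⁺ coupling strength is not separately constrained and defaults to
  the IP₃ value (0.05 s⁻¹, configurable).
* Intracellular ion concentrations other than Ca²⁺ are fixed in the
  drift term; the EC alignment is always axial, with exactly four
  homocellular neighbours per interior cell (real endothelium reaches
  up to six).
* W* is treated as a dimensionless fraction in [0, 1].
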