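# Methods

## Model overview

`nmpsim` simulates the posterior body of an elongating bird embryo as an
off-lattice agent model in 2D (dorso-ventral deformation is small over the
modelled window, ~10 h spanning somite stages HH8–HH12). Three fates
coexist: undetermined progenitors in the posterior progenitor zone (PZ),
neural tube (NT) cells in a medial column, and presomitic mesoderm (PSM)
cells in two lateral columns. The anterior boundary (somites, dense
neuroepithelium) and lateral boundaries (lateral plate) are blocked; the
posterior is open. One model unit is 150 µm.

A cell's state variable is its Sox2-to-Bra ratio R on a 0–2 scale.
Progenitors update R by an Euler–Maruyama step of an Ornstein–Uhlenbeck
process, dR = −κ(R − μ)dt + σ dW, clipped to [0, 2]; committed cells relax
deterministically to their pole (NT → 2, PSM → 0) at the same rate κ.
Commitment is a *noise-driven threshold crossing*: the first passage below
θ_low = 0.4 switches a progenitor to PSM, above θ_high = 1.6 to NT, both
irreversibly.

### Regimes: the spatial organisation of heterogeneity

The anchor field μ distinguishes three spatial organisations of the same
heterogeneity:

- **random** — each cell draws its own anchor uniformly over the
  (compressed) initial ratio range at birth and passes it to daughters:
  heterogeneity with no spatial structure.
- **gradient** — μ is a linear function of the cell's current
  antero-posterior position across the progenitor span, from 1.7 (anterior,
  Sox2-biased) to 0.3 (posterior, Bra-biased): pure positional identity.
- **mixed** — the positional gradient plus a per-cell offset drawn
  uniformly in ±0.35 at birth: the organisation observed in embryos
  (graded enrichment with strong cell-to-cell scatter).

All anchors are linearly compressed, centre-preserving, into
[θ_low + m, θ_high − m] (m = 0.05; 0.15 for the random regime, whose
uniform anchor distribution otherwise over-weights near-threshold cells).
Without the compression the nominal gradient end-points (1.7/0.3) lie
beyond the thresholds, edge progenitors commit deterministically, and the
progenitor pool collapses within hours — incompatible with the observed
homeostasis. With it, commitment rates are set by the distance from anchor
to threshold in units of the stationary SD σ/√(2κ).

### Calibration of κ and σ

The drift rate and noise amplitude are not observable directly; the tissue
constraint is that the mixed-regime progenitor count stays within ±20% of
its initial 1100 over 10 h while NT and PSM grow. A scripted grid search
under that constraint fixed κ = 1.0 h⁻¹ and σ = 0.25 h^(−1/2)
(stationary SD ≈ 0.18). Full-scale mixed runs then hold the pool within
[0.91, 1.01] × 1100 across seeds. Both parameters are config-exposed.

### Motility

Speed is a non-increasing function of R. Committed PSM cells and
sub-threshold ratios move at v_high = 60 µm/h, committed NT cells and
supra-threshold ratios at v_low = 12 µm/h. Inside the undetermined band the
default profile interpolates linearly (v_mid = 36 µm/h at the band centre),
so heterogeneous ratios translate into heterogeneous speeds — this is what
lets the spatial regimes differ in behaviour. A flat-band `step` profile is
available for comparison. Each step the cell attempts an isotropic
displacement of length speed × dt.

### Interactions

The interaction terms act as a bias of the random motion (a cell that makes
no move attempt is not displaced by neighbours either):

- hard-core repulsion inside r_core = 10 µm (velocity scale 240 µm/h at
  full overlap) — volume exclusion, and the engine that converts
  proliferation pressure into posterior flow;
- linear spring attraction in (r_core, r_adh = 30 µm], weighted by the
  fate-pair adhesion matrix (NT–NT 1.0 > progenitor 0.5 ≥ PSM–PSM 0.4,
  velocity scale 5 µm/h) — only the NT > PSM ordering is biologically
  constrained;
- cross-fate repulsion of the same range (weight 8.0) — the non-mixing
  property that keeps tissue boundaries sharp;
- a packing cap: a move is rejected if it raises the cell's neighbour count
  within r_pack = 20 µm above n_max = 18 (and above its current count, so
  over-packed regions can still relax). Moves crossing the anterior or
  lateral walls are rejected.

With n_max = 18 the cap binds inside the PZ, which rectifies fast cells'
isotropic motion toward the open posterior edge; this density ratchet is
what gives randomly organised progenitors their extra posterior drive.

### Proliferation

Each cell divides per step with probability dt·ln2/T_fate
(T = 11.49 / 10.83 / 8.75 h for progenitor / NT / PSM). Daughters inherit
state and ratio, are placed at r_core/2 from the mother (clamped inside the
walls, exempt from the packing cap to avoid birth deadlock), and draw their
anchor offset per regime. There is no cell death.

### Deregulation experiments

`bra_high` / `sox2_high` shift the SDE anchor of a configurable fraction of
progenitors to 0.2 / 1.8 — beyond the corresponding threshold — emulating
forced expression. The affected cohort commits and migrates accordingly;
the cohort's realised step speed (measured over the first 3 h, while cells
are still transiting) rises under bra_high and falls under sox2_high.

## Geometry

Default extents (model units, overridable): NT 1.0 × 4.0, each PSM column
1.3 × 4.0, PZ 2.4 wide × 2.25 long centred behind them. The PZ is narrower
than the full body so its medio-lateral extent is free to change — the
shape-conservation readout would otherwise be clamped by the walls.
`population_scale` scales initial counts and region areas together
(density-preserving) for cheap replicates. Because interaction radii are
physical (µm), behaviour is not exactly scale-invariant: in very wide
domains the growing PSM partly flows around the PZ through the lateral
gaps instead of pushing it, so regime comparisons are standardised at
`population_scale = 0.25`.

## Analysis definitions

- **Raw vs corrected tracks** — raw positions are relative to a per-frame
  reference point; correction subtracts the cumulative mean per-step
  displacement of an ROI's member tracks, leaving the ROI mean step exactly
  zero.
- **Motility** — per-track mean of step length / frame interval (mean step
  speed; net-displacement mode available).
- **Angle histogram** — step directions measured from posterior (+y), in
  (−180°, 180°], 16 bins by default, each step weighted by its speed;
  normalised to 1.
- **Time-averaged MSD** — squared displacements over all overlapping
  windows of all tracks, pooled with pair-count weighting; MSD(0) = 0 by
  construction. `fit_diffusion` fits MSD = 4Dτ through the origin and
  reports R² as a linearity score.
- **Elongation** — displacement of the 95th percentile of progenitor y
  (robust posterior edge) over the window.
- **Residents** — cells in the progenitor state at every snapshot,
  optionally restricted to those starting in the central AP third of the
  initial progenitor span.
- **Shape conservation** — with aspect = AP length / ML width from 5th–95th
  percentile spans, 100 × min(a₁/a₀, a₀/a₁): symmetric, 100 iff unchanged.
- **Tissue integrity** — fraction of cells with a strict majority of
  same-fate neighbours within 30 µm; restricted to progenitors it measures
  PZ coherence, the most sensitive readout because newly committed cells
  must leave the PZ.
- **Expression quantification** — channels divided by per-nucleus DAPI
  (depth compensation); ratios exclude zero-Bra nuclei (no pseudocount,
  exclusions counted); CV = 100·SD/mean; path profiles average normalised
  channels in 7 equal-arclength volumes along a posterior→anterior
  polyline; signed fold change reports +f for increases and −1/f for
  decreases (a halving is −2.0); transverse sections select |y − y₀| ≤
  20 µm.

## Synthetic data generator

The generator emulates the *structure* of the imaging data, not images:
per-nucleus intensities are log-normal (positive, right-skewed) with exact
configured means and CVs; the PZ carries a ±25% linear anterior-Sox2 /
posterior-Bra modulation and high cell-to-cell CVs (41.8% Sox2, 30.75% Bra
on the normalised channel — the variance contributed by the gradient and
by DAPI noise is discounted so the configured target is what the pipeline
measures); NT and PSM are homogeneous (10% CV) and polarised with ratios
near 1.8 and 0.11. All channels share an exponential depth attenuation
(e-folding 120 µm) which DAPI normalisation removes. Tracks are drift +
diffusion random walks with per-tissue parameters (common posterior drift,
PZ/PSM diffusive, NT slow). Everything is deterministic under a fixed
seed.

What passing tests on these tables show: the analysis formulas are correct
and recover known parameters. What they do not show: robustness to
segmentation error, photobleaching, uneven staining, tracking gaps, or
embryo-to-embryo variation — none of which the generator emulates.

## Numerical choices and degenerate inputs

dt = 0.1 h (the 6-min imaging cadence); Euler–Maruyama discretisation bias
on the OU variance is O(κdt) ≈ 5% and irrelevant to thresholds; division
probability per step gives doubling times biased by ln(1+p)/p ≈ +0.4%,
inside all tolerances. Zero-length steps carry no angle weight; zero-DAPI
and zero-Bra nuclei are excluded and counted; an all-zero MSD yields D = 0
with an undefined (NaN) linearity score; flat count series report an
infinite doubling time; empty slabs/ROIs return flagged empties or raise
named errors. All randomness flows through one `numpy.random.Generator`, so
a (config, seed) pair reproduces a run bit-for-bit.

## Known limitations

- The interaction scheme (core + spring adhesion + cross-fate repulsion +
  packing cap) is a minimal reconstruction; its strengths were calibrated
  against tissue-level behaviours (stable PZ, elongation and
  shape-conservation orderings across regimes, ablation effects), not
  against measured cell-mechanical quantities.
- Progenitor MSD in this model is dominated by collective, growth-driven
  flow and tissue deformation rather than by intrinsic motility diversity.
  As a consequence the mixed regime shows the largest progenitor MSD
  (≈10% above random), and the expected strict ordering
  random > mixed > gradient is not reproduced even though the elongation,
  resident-displacement and shape-conservation orderings are. A model
  whose PZ is internally fluid (frequent neighbour exchange) while keeping
  its envelope would be needed to separate the two.
- No cell death, no somitogenesis, no 3D mechanics, no molecular regulation
  of Sox2/Bra by signalling gradients; deregulation is a phenomenological
  anchor shift.
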