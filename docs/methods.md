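# Model and methods

## The community and the question

`crossfeed` simulates a three-strain engineered yeast community growing on
an agarose pad:

* **R** (cooperator) requires lysine and continuously releases adenine at
  rate γ_A per live cell;
* **G** (partner) requires adenine and releases a lysine payload β_L when
  it dies;
* **C** (cheater) requires lysine, releases nothing, and carries an
  intrinsic fitness advantage expressed as a multiplier on its maximum
  uptake rate (v_m,C = 1.02 v_m,R for a 2% advantage).

The question the simulations address: can purely local, recognition-free
interactions (release, diffusion, uptake) let cooperators outgrow a
cheater that is intrinsically fitter — and if so, through what spatial
mechanism?  The observable for the mechanism is the partner association
index A_RG/CG: the mean number of partner neighbors per focal cooperator
divided by the same mean per focal cheater, restricted to focal cells
bordering at least one other population.  A > 1 means self-organization
has given cooperators preferential partner access.

## Individual-based dynamics

Cells occupy a 3-D lattice of 5 μm sites above the agarose surface
(periodic laterally, open above).  Time advances in cell-update windows
of τ = 6 min, each containing ~103 physical diffusion timesteps of
t_u = 3.5 s.

**Uptake.**  Each live cell takes up its required metabolite at the
Michaelis–Menten rate v(S) = v_m S/(S+K) evaluated at its 15 μm voxel,
clamped so a voxel is never overdrawn (when co-located demand exceeds the
voxel's content, the content is split in proportion to unclamped demands)
and so no cell overshoots its quota.  v_m is tied to growth:
v_m = α r_max / ln 2, where α is the per-division quota.  A cell that has
met one quota stops consuming that metabolite and continues acquiring the
other (all strains also need a shared resource, glucose).

**Division.**  A cell divides in the first window where both quotas are
met; surplus stores carry over, daughters start empty.  Placement follows
the observed budding rules: bud in the horizontal plane, pushing the
chain of neighbors one site outward along the shortest lateral path
(breadth-first search through occupied sites, ties uniform at random) to
the nearest empty site within a five-cell radius; once fully enclosed,
bud straight up with probability 0.7 (displacing the column above) or
displace a random lateral neighbor's column upward with probability 0.3.
Whichever single cell ends up over empty air — the daughter or the far
end of a pushed chain — settles onto that column's top, so no cell ever
floats.  Without this settling rule, cells at the top of locally tall
stacks can never bud laterally, are treated as enclosed forever, and grow
pathological one-cell-wide towers; settling restores the intended lateral
spillover while keeping the support invariant exact.  A division whose
vertical push would cross the domain ceiling is deferred to a later
window (`overflow_policy="arrest"`); the strict-error mode is available.

**Death and release.**  Each live cell dies with probability d·τ per
window (binomial across cells).  Dying partners deposit β_L lysine at
their voxel, spread evenly over the following window's diffusion steps.
Dead cells remain in place, occupy volume, block pushing, and count
toward occupancy, but are excluded from focal/neighbor counts of the
association index by default.

**Diffusion.**  Each metabolite (lysine, adenine, glucose) lives on two
grids: 60 μm voxels in the agarose (D = 360 μm²/s) and 15 μm voxels over
the community and air.  Community diffusivity is proportional to voxel
occupancy, 0→20 μm²/s at 27 cells, and is refreshed after every cell
update; empty (air) voxels have D = 0, which makes the community–air
interface no-flux automatically.  Face diffusivities are harmonic means;
the grids exchange mass flux-conservatively through a series-resistance
interface coefficient.  The printed physical timestep t_u = 3.5 s
violates the explicit 3-D stability bound (D t_u/h² = 0.35 > 1/6 in
agarose), so each t_u is sub-stepped (3 sub-steps at default
diffusivities; more in the uniform-D variant) while the cell engine sees
whole t_u updates.  A mass ledger (initial + released − consumed = total)
is maintained per metabolite and holds to better than 1e-9 relative in
full runs.  The single-grid variant described for the model ("one 50 μm
grid, D = 360 everywhere") is realized as a uniform-D flag on the
existing dual grid rather than a second voxel size; it reproduces the
delocalized-diffusion physics of that variant.

**Stochasticity.**  Initial placement, initial metabolite stores (uniform
on [0, quota)), death, division order, tie-breaks, and budding direction
all draw from one seeded generator; diffusion and uptake are
deterministic.  Identical seeds give bit-identical trajectories.

## Parameter defaults and calibration

The published model defers its numeric kinetic table to a source-data
file, so this package's defaults are its own (flagged ASSUMED in the
config schema).  They were fixed once, by the following reasoning, and
define the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| r_max (all strains) | ln2/2 ≈ 0.347 /hr | minimum doubling time exactly 2 hr; also aligns the baseline division interval with the 6-min window grid, so interval rounding does not systematically mask a fitness multiplier |
| α_L, α_A, α_G | 2, 1, 30 fmole | order-of-magnitude cellular content per division; glucose quota sized so the shared resource is co-required but not limiting |
| K (lysine), K (adenine) | 1 μM, 0.2 μM | strong-affinity uptake keeps scarce metabolites in the demand-limited regime where benefits stay localized |
| γ_A | 0.22 fmol/cell/hr | below the partner population's maximum uptake capacity (≈0.5 v_m,G), so released adenine never accumulates into a community-wide pool; above the partner death rate, so partners persist next to cooperators |
| β_L, d_G | 3.5 fmole, 0.20 /hr | lysine flux d_G·β_L = 0.7 fmol/hr per partner supports ~3.5 hr effective doubling of the lysine-requiring strains; the payload is kept small so a death pulse is drunk by nearby cells within tens of μm instead of saturating uptake and spreading pad-wide |
| d_R = d_C | 0.01 /hr | slow death of lysine-starved cells |
| supplements | 650 μM lysine, 430 μM adenine | competition medium; the supplemented pad is deeper (2.52 mm) so the reservoir outlasts 7–8 generations |
| glucose | 111 mM in agarose | 2% glucose; non-limiting by design |

The localization constraints (γ_A below partner uptake capacity; small
β_L payloads) matter most: when either is violated the released benefit
becomes a well-mixed pool, partner growth decouples from cooperator
proximity, and self-organization vanishes — which is exactly the behavior
the delocalization variants (200× release, instant distribution) are
meant to produce on purpose, and do.

## Desk-scale study conditions

Simulations run on reduced domains chosen once: 300×300 μm periodic pads
for the random-lawn experiments (a scaled proxy for the centimetre-scale
pad), 360×180 μm for the symmetric periodic motif (the smallest domain
the 9×3-site motif and 60 μm agarose grid both divide), and a
240×240 μm pad with an 80 μm-diameter confluent spot for range
expansion.  The test suite uses 240×240 μm versions of the lawn
experiments.  Replicates use 2–6 seeds as stated per experiment.  At
these scales a lawn community reaches generation 6 in 70–85 simulated
hours (≈0.5–2 min of wall time per replicate).

Two desk-scale caveats follow from the small domains.  First, benefit
localization lengths (tens of μm) are only a few-fold smaller than the
domain, so association indexes are attenuated relative to a full-scale
pad; the package reproduces the directions and orderings of the effects,
with smaller margins than the original figures.  Second, early in growth
(sparse cells) uptake is slow everywhere and released metabolites are
effectively shared; differential association only builds once the
community is dense, so indexes are measured at generation ≥ 5–6.

## The quantification layer

* `association_index` — the partner association index on a 2-D section
  or 3-D lattice.  "Immediate neighborhood" connectivity is not pinned by
  the model description; the default is the 26-cell cube in 3-D and the
  8-cell square in 2-D (both switchable to 6/4-connectivity), recorded in
  the result.  Live cells only by default.
* `population_ratio` — live-cell count ratios (the flow-cytometry
  analog).
* `fitness_advantage` — least-squares slope of ln(ratio) against
  generations over a window (default generations 2–6), exponentiated
  minus one.  Note the unit: a rate-multiplier advantage s yields a
  per-generation ratio decline of exactly 2^s (independent of which
  population's doublings define a generation), so the estimator reports
  100·(1−2^−s), e.g. 3.4%/generation for s = 5%.
* `region_split_metrics` — center vs expanding-front metrics for the
  spot protocol, classifying columns by the inoculum footprint.
* `crossfeed.imaging` — the two-step pixel-classification rule for
  three-channel fluorescence rasters (30%-above-background gate on raw
  intensities, then argmax of 90th-percentile-normalized channels, ties
  R>G>C), plus a synthetic image generator so the rule is testable
  without microscopy data.  Background defaults to the histogram mode of
  the lowest-decile pixels; manual override supported.

## Mixing, liquid, and variants

* Periodic mixing permutes the cell multiset over the currently occupied
  sites (the occupied sites already form dense bottom-up columns) and
  sets adenine and lysine in occupied community voxels to their pre-mix
  mean; glucose and ledgers untouched.  Whether the average should
  include agarose voxels is ambiguous in the model description;
  community-only is the default, a flag includes agarose.
* The liquid coculture shares the uptake/quota/division/death/release
  rules with uniform concentrations, in a stochastic agent mode (default)
  and a deterministic expectation mode (per-capita division rate
  ln2·min(v_req/α, v_glu/α_G)) used for closed-form tests.
* Variant flags: `excess_release_factor` (scales γ_A and β_L, 200 for
  the delocalization variant), `instant_distribution` (fields replaced by
  their volume-weighted mean over community+agarose every t_u),
  `uniform_D`.

## Known limitations

* Fixed per-strain death rates (as in the model being reproduced) mean
  the partner dies at d_G even on supplemented medium, so partner counts
  shrink markedly during pure competition; the competition conclusions
  concern the two lysine-requiring strains.
* The 6-min division-check granularity quantizes division intervals;
  realized fitness differences depend slightly on where α/v_m falls on
  that grid (mitigated by the r_max alignment above).
* No starvation physiology (lag, arrest-tolerance differences), no
  mutation or adaptation, no off-lattice mechanics, no metabolite
  degradation.
* Cross-feeding behind delocalized transport at very small domains makes
  index magnitudes scale-dependent; values from different domain sizes
  should not be compared directly.
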