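# Methods

## Model

voxseg treats cell segmentation of imaging-based spatial transcriptomics
as posterior simulation of cell boundaries. Space is discretized into a
lattice of voxels; each voxel's state σ_i is either unassigned (∅) or one
of n cells, where n is fixed by an initial nuclear segmentation supplied
as per-transcript nuclear labels. Transcripts follow a Poisson point
process whose intensity for gene g at a point is

    λ_g(s) = τ_g^bg + τ_{g, σ(i(s))},      τ_{g,∅} := 0,

with a constant background rate τ_g^bg and a per-cell rate τ_gc that is
uniform over the cell's volume. Writing ν_c for cell volume and X_gc for
per-cell counts, the likelihood contributes an exposure term
−ν_c(τ_g^bg + τ_gc) per gene and cell plus a point term log λ_g(s_j) per
transcript. We additionally expose the background rate over unassigned
space (−τ_g^bg · ν_∅); without that term the background rate is not
identifiable and transcripts in unassigned space would contribute only
point terms. Since background exposure then sums to τ_g^bg times the
fixed total lattice volume, it cancels from all boundary updates.

Cell rates follow a hierarchical Gamma mixture with k components
("broad cell types"):

    τ_gc ~ Gamma(α_{g,z_c}, β_{g,z_c}),   z_c ~ Categorical(π),
    α_gt ~ Gamma(e0, h),  h ~ Gamma(e0, f0),  −log β_gt ~ Normal(0, γ⁻¹),
    π ~ Dirichlet(1).

Marginally the counts are negative binomial, X_gc ~ NB(α, ν_c/(ν_c+β)),
which is what makes exact conjugate updates available (below). Cell
volumes are LogNormal by component, ν_c ~ LogNormal(μ_{z_c}, σ_{z_c}),
with σ parameterized as a precision (a Gamma prior on a precision is
conjugate; on a standard deviation it is not). A nuclear prior puts
probability p_nuc = 0.8 on a transcript keeping its nuclear assignment,
with the remaining mass spread over all alternatives; only ratios enter
the sampler, so the ratio between two non-matching assignments is 1.

Transcript positions may be displaced from their cell of origin
("leaky cells"): the observed position s′ is related to a latent true
position s by a two-component Normal mixture,
s ~ ρ·N(s′, σ_a²I) + (1−ρ)·N(s′, σ_b²I) with ρ=0.2, σ_a=4 μm,
σ_b=0.5 μm. The latent positions are sampled alongside boundaries.

## Boundary sampling

Proposals copy a voxel's state across a face (von Neumann) mismatch
edge, drawn uniformly from an incrementally maintained edge pool; with
probability 0.05 the proposal writes ∅ instead ("bubble" moves, making
pocket formation and popping mutually reversible). Acceptance is
Metropolis–Hastings at temperature 1 with an explicit proposal-density
ratio: the number of edges that could produce the move (same-state face
neighbors of the target, plus the bubble branch when the new state is ∅)
over the phase's pool size, before and after the flip. Three hard rules
are applied before scoring:

* **Annihilation prohibition.** A cell reduced to a single voxel is
  never changed; cells cannot die (or be reborn), so the move would be
  irreversible.
* **Local connectivity.** A flip may not change the number of connected
  components of either affected cell within the flipped voxel's Moore
  neighborhood. Because the voxel is Moore-adjacent to every voxel of
  its own neighborhood, the test reduces to: the same-label Moore
  neighbors must form exactly one component (an empty set also rejects;
  it can only occur for single-voxel cells). The test is symmetric under
  the reverse flip, so rejection preserves detailed balance. The ∅ state
  is exempt.
* **Perimeter bound.** Per z-layer, the perceived perimeter ξ·(raw Moore
  mismatch count) must not exceed b·2√(π·area) with b = 1.3 — the
  perimeter of a circle of the same area, times b. This is a hard
  support restriction, not an energy penalty. ξ = 0.32437 was fitted
  once by rasterizing disks of radius 10–100 voxels and regressing the
  true perimeter 2πr on the raw mismatch count (the scaled count matches
  2πr within 5% across radii). The raw count uses the in-plane
  8-neighborhood only: z-resolution in these platforms is coarse and
  approximate, so compactness is enforced per layer.

Checkerboard phases partition voxels into four sub-quadrant classes by
bin parity; within a phase, proposals cannot touch the same cell
provided the bin edge exceeds the largest plausible cell diameter (the
default bin is twice the 90th-percentile nearest-neighbor distance of
the nuclei). The implementation evaluates phases sequentially — the
point of the machinery here is the proposal schedule and its q-ratio
bookkeeping (pool sizes are per-phase), and it keeps the door open to
parallel evaluation; results are identical to sequential evaluation when
no two same-phase proposals share a cell.

Sampling starts at 4 μm in-plane voxels and one z-layer and doubles the
resolution twice (each voxel splits into its 8 children, leaving every
cell's region and volume unchanged), ending at 1 μm and four z-layers.
Defaults run 200 sweeps per stage; a sweep is one pass over each phase's
current pool. Every sweep is followed by a full Gibbs parameter sweep
and every 5th sweep by a transcript-repositioning sweep.

**Perimeter repair at stage boundaries.** Refining the lattice scales
the bound's right side by 2 (area ×4) but inflates raw mismatch counts
by slightly more than 2 (staircase corners), so a freshly doubled state
can violate the bound the chain otherwise preserves; hard rejection
would then freeze those layers permanently. After each doubling (and
after nuclear initialization) a deterministic local search applies
single-voxel smoothing flips that strictly reduce a violating layer's
perimeter-to-√area ratio, under the same connectivity rules and without
pushing any compliant layer out of compliance. Layers of 3D-connected
cells can also contain disconnected in-plane islands that no
single-voxel move can repair; the search then detaches the smallest
island when that improves the ratio and keeps the cell connected.
Within a stage the constraint support is never left, so final states
satisfy every bound exactly (audited).

## Parameter inference

With boundaries fixed, all parameters have exact conditional draws:

* z_c ∝ π_t · Π_g NB(X_gc; α_gt, ν_c/(ν_c+β_gt)), sampled in log space
  by Gumbel-max.
* τ_gc ~ Gamma(α+X_gc, β+ν_c); τ_g^bg ~ Gamma(e0bg+ΣX^bg, f0bg+V_total)
  — the background is active over the whole lattice, so its exposure is
  the total lattice volume.
* α via Chinese-restaurant-table augmentation: ℓ_gc ~ CRT(X_gc, α), then
  α_gt ~ Gamma(e0 + Σℓ, h + Σ_c log((ν_c+β)/β)); the hyper-rate
  h ~ Gamma(e0 + mk, f0 + Σα) couples dispersion across components.
* φ_gt = −log β_gt via Polya-Gamma augmentation:
  ω_gc ~ PG(X_gc+α, log ν_c + φ), then φ_gt ~ Normal(μ*, σ*²) with
  σ*² = (γ + Σω)⁻¹ and μ* = σ*²·Σ[(X_gc−α_gt)/2 − ω_gc log ν_c] — the
  canonical PG update for the NB success-probability logit
  log ν − log β.
* Volume model: conjugate Normal (means) and Gamma (precisions) updates
  per component; π ~ Dirichlet(1 + occupancy). Resampling π is on by
  default and switchable (`PriorConfig.resample_pi`).

The z update conditions on counts only, not on the volume model — the
component's volume term is part of the boundary acceptance instead.

**Polya-Gamma sampling** uses the sum-of-Gammas series
ω = (2π²)⁻¹ Σ_k g_k/((k−½)² + c²/4π²) truncated at 200 terms, with the
omitted tail replaced by its expectation via the closed form
Σ_k ((k−½)²+a²)⁻¹ = π·tanh(πa)/(2a). One code path serves every shape
and the mean is exact for all (b, c); the truncation slightly
under-disperses the draw (missing tail variance ≲ b/(2π⁴K³)), which is
negligible at K=200 against the γ-precision prior. We preferred this to
a Devroye-type exact sampler plus a large-shape approximation: simpler,
shape-uniform, and moment-verified against (b/2c)·tanh(c/2).

**CRT sampling** sums Bernoulli(r/(r+i−1)) draws, vectorized over the
count matrix; means verified against r·(ψ(r+n)−ψ(r)).

## Transcript repositioning

A symmetric Gaussian random-walk kernel (sd 1 μm in-plane, 0.5 μm in z;
z is frozen for flat data) proposes latent positions; acceptance
multiplies the mixture-prior density ratio by the point-term ratio
(τ^bg + τ_{g,new cell})/(τ^bg + τ_{g,old cell}) and the nuclear-prior
ratio. Given fixed boundaries transcripts are independent, so a sweep is
fully vectorized. Proposals leaving the lattice are rejected. For flat
(single-plane) data the mixture density is evaluated over the two
in-plane axes only, so that generator and model agree on the
displacement law.

## Initialization

Each voxel holding nuclear-labelled transcripts is assigned to the label
with the plurality of them; ties break by the label's transcript count
in the voxel's Moore neighborhood, then by smaller label id (chosen for
determinism). Labels that win no voxel are dropped; a label with
disconnected voxels keeps only its largest Moore component. n is then
fixed for the rest of the run.

Component labels start from k-means on the cells' censored
log-proportions rather than at random, and the first half of the warm-up
Gibbs sweeps hold z fixed so α and β adapt to that partition before the
first z draw. Order matters: a sweep that resamples z first, while the
components are still identical at their initial values, scrambles any
initialization and can collapse two true components into a single mode
that the chain is then very slow to leave. With the warm start the
mixture is a refinement problem and recovery is stable across seeds.
The expression model is burned in for 20 such sweeps on the nuclear
counts before the first boundary sweep (and for 20 in the standalone
expression fitter).

## Evaluation metrics

**Spurious co-expression.** C_ij = |P_i ∩ P_j|/|P_j| over cells with
count ≥ 1; gene pairs whose C_ij inflates ≥ 1.5-fold from nuclear to
deliberately expanded segmentation are "spurious"; methods are scored by
C_ij on those pairs relative to nuclear segmentation, after keeping
cells with ≥ 50 transcripts and redrawing each as Multinomial(50,
observed proportions). Pairs with zero nuclear co-expression are
excluded from ratios and reported separately. C is computed
directionally, matching the defining formula.

**Proximity.** On the Delaunay graph of cell centroids (x, y; a fixed
1e-9 jitter guards degenerate geometry) with one type made absorbing,
the expected hitting time solves (I−Q)t = 1 sparsely; transient nodes
that cannot reach absorption are flagged ∞. The normalized score divides
t_i by the mean hitting time at the endpoint of a k-step shuffle walk
(defaults k=10, 100 repeats). The shuffle walk traverses the full
undirected graph — absorbing cells are ordinary waypoints — and only the
endpoint contributes 0 when absorbing. Terminating the walk at first
absorbing contact would, by optional stopping, give exactly
E[t(X_k)] = t_i − E[min(k, T_abs)], forcing every score above 1 and
destroying the metric's direction; pass-through restores ≈1 under random
organization and < 1 for types hugging the absorbing set. The
normalization is only informative when hitting times are long relative
to k (sparse absorbing sets).

**Censored log-proportions.** Per cell: divide by total, floor at 1e-4,
natural log — the distance basis used downstream of segmentation.

## Synthetic tissue

The generator draws what the model assumes, with known ground truth:
Poisson-disk nuclei (rejection sampling, minimum spacing 1.4·r̄), cell
regions as Voronoi cells clipped to disks whose areas are
LogNormal(log πr̄², 0.25), rasterized at 1 μm; per-cell components and
Gamma rates with block markers (each of k components has an m/k-gene
marker block, Gamma(6, 50) → mean rate 0.12 μm⁻³ against Gamma(0.5, 100)
→ 0.005 off-block); Poisson counts placed uniformly in the cell;
uniform background at 0.05 μm⁻³; mixture diffusion of observed
positions; and nuclear labels on the innermost 30% of each cell's
transcripts (emulating a nuclear mask rather than perfect labels). The
standard tissue is 50 cells of mean radius 6 μm in a 100×100 μm flat
domain with 30 genes and 3 components — densities (≈150 transcripts per
cell, ≈6% background) chosen to resemble a well-performing in-situ
panel. Clipped Voronoi regions are compact and convex-ish; the generator
does not emulate optical crowding, probe-efficiency differences,
platform noise signatures, or irregular (e.g., ameboid) morphologies —
passing tests show the sampler recovers boundaries when the model's
assumptions hold, not that it handles arbitrary real tissue.

## Numerical choices and degenerate inputs

0-based voxel indices, half-open voxel intervals (points on the outer
boundary clamp to the last voxel), μm everywhere. Flat transcript clouds
get a nominal 1 μm slab thickness so volumes stay finite; resolution
doubling still splits all three axes (the slab subdivides; volumes are
unchanged). Component weights are sampled in log space with the
Gumbel-max trick; all-−∞ weights raise rather than silently normalize.
Hyperparameter defaults (e0bg=f0bg=e0=f0=γ=1, μ0=log 200 μm³, σ0=1,
α0=β0=1, k=10) are weakly informative implementation choices, all
overridable. Empty transcript tables, non-finite coordinates, absent
nuclear labels, non-halving schedules and out-of-range probabilities
raise immediately.

## Problem sizes in the test suite

The acceptance checks run at the sizes their statements prescribe: the
detailed-balance audit uses 10⁶ proposals on the 6-voxel toy (TV < 0.02
against 15 enumerated states) plus negative controls on the 6-voxel and
3×2 toys; Gibbs recovery uses 500 cells × 10 genes × 3 components and
400 sweeps; the end-to-end run uses the standard 50-cell tissue at the
default 200-sweep schedule. The 3×2 toy's oracle restricts the
enumeration to states reachable from the initial configuration —
corner voxels whose face neighbors are same-cell can never be targeted
by a copy edge, so e.g. diagonal-only cell shapes are unreachable; the
reachable set is computed by breadth-first search over a
first-principles reimplementation of the move rules.

## Known limitations

Sequential execution only (the checkerboard machinery is in place but
no thread pool); final output is the last sample, not a posterior
average, and boundary uncertainty is not exported; the diffusion
parameters (ρ, σ_a, σ_b) are fixed, not inferred — fitting them is
poorly constrained and tends toward everything-is-diffused; the
perimeter constant ξ is calibrated on smooth disks, so highly textured
equilibrium boundaries sit closer to the bound than their smoothed
perimeter would suggest; MERSCOPE pixel-unit inputs need the reader's
affine scale (μm inputs are the default assumption).
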