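# Methods

This note documents the statistical and physical models implemented in
chromodyn, the parameter choices that matter, and what the synthetic
validation does and does not demonstrate.

## Trajectory model and MSD estimators

A track is an ordered sequence of 2D or 3D positions (μm) at a fixed
sampling interval dt (default 0.02 s, single-plane confocal imaging at
20 ms). Frames are uniformly spaced; files with a `time` column are
checked for uniformity (relative tolerance 1e-3) and rejected
otherwise. Missing frames split a track into independent pieces rather
than being interpolated: interpolation manufactures artificially smooth
displacements and biases the MSD downward at short delays.

The per-track MSD at delay τ = k·dt averages all N_i = n − k
overlapping squared displacements. Overlapping displacements are
statistically dependent; the estimator is nevertheless defined over
the full overlapping set, and the ensemble standard error accounts for
the weighting explicitly rather than assuming independence within a
track. The ensemble mean weights each track by N_i(τ), and its
variance is

    σ²⟨m⟩(τ) = (1/N) [ (1/N) Σ_i N_i (m_i² + s_i²) − ⟨m⟩² ],  N = Σ_i N_i,

where s_i²(τ) is the *population* variance of track i's individual
squared displacements at that delay (defined 0 when N_i = 1). Under
this reading — the only one for which the algebra closes — σ²⟨m⟩
equals the population variance of the pooled set of all squared
displacements divided by N, which the tests verify against a
brute-force pooling oracle, and reduces exactly to s_i²/N_i for a
single track.

### Power-law fits

m(τ) = a·τ^α is fit on delays 0 < τ ≤ 0.5 s by default. Beyond ~0.5 s
single-locus MSD curves are dominated by whole-nucleus and chromosome
movements, so longer delays are excluded; the bound is a parameter.
The objective is unweighted least squares on the (τ, m) pairs, with
τ = 0 never included. Stage one is a Nelder–Mead simplex search seeded
by log–log linear regression (robust to far-off starts); stage two
refines with gradient-based nonlinear least squares whose parameter
covariance supplies δα. For numerically exact fits δα is floored at
1e-6 so that downstream 1/δα² weights stay finite. Tracks for which
both stages fail are flagged and excluded from weighted summaries
(exclusion is a parameter).

### Exponent density and mixture description

The exponent density is estimated two ways, both weighted by 1/δα_i²:
a density-normalised histogram and a Gaussian-kernel KDE whose
bandwidth defaults to Silverman's rule on the weighted sample. The
one- or two-Gaussian model is fit to the *KDE curve* by least squares
(mixture weight w constrained to [0, 1]; components reported with
mean1 ≤ mean2; the "main" component is the one with the larger
weight). Fitting the smoothed curve rather than the raw sample follows
the analysis convention this package mirrors; a weighted EM fit to the
raw exponents is provided as an alternative (`fit_mixture_em`) and
cross-checked against scikit-learn's EM in the tests. The two-Gaussian
fit is multi-started (symmetric split plus dominant-peak/shoulder
configurations) because the least-squares surface has local optima in
which one broad component absorbs the tail of the other.

Model selection: "double" is chosen iff RSS_double/RSS_single < ρ
(default ρ = 0.5, exposed) *and* the component means are separated by
more than the first component's sd. The criterion is deliberately
simple; it is not a formal hypothesis test.

### Length of constraint

L_c = sqrt((1/n) Σ_t |r_t − r̄|²), all coordinate dimensions summed —
the standard deviation of the locus position about its time average
and an estimate of the radius of the explored region. For a stationary
mean-reverting process with per-axis sd s in d dimensions, L_c → s·√d
for long tracks, the closed form used in validation.

## Polymer scaling argument

A monomer cannot move without dragging the n(t) chain neighbours
within the distance it travels, so its effective friction grows in
time and ⟨r²(t)⟩ ~ t^(2ν/(1+2ν)) for a chain with R_g ~ N^ν. The
phantom chain (ν = 1/2) gives α = 1/2; good-solvent excluded-volume
chains (ν = 3/5 mean-field, ν ≈ 0.588 refined) give α ≈ 0.54 — the
more expanded chain drags fewer monomers per distance, hence less
friction and faster spreading. The semi-flexible value α = 3/4 is
stored as a cited literature constant, not derived here.

## Bead–spring simulator

Units: lengths in μm, energies in kT, friction ζ = 1; time is in
simulation units (the mapping to seconds is left symbolic — exponents,
not time scales, are the observables). The overdamped Langevin
equation is integrated by Euler–Maruyama with thermal noise variance
2·(kT/ζ)·dt per coordinate (fluctuation–dissipation).

Defaults and their rationale (all config-exposed):

| parameter | default | why |
|---|---|---|
| n_beads | 2436 (full) / 500 (reduced) | 3.6 Mb arm at 10 nucleosomes ≈ 1.5 kb per 25 nm bead; the reduced chain keeps desk-scale runs in minutes |
| bead radius | 25 nm | coarse-graining scale |
| bond rest length | 50 nm | bead diameter |
| bond stiffness | 4·10⁴ kT/μm² | bond-length sd √(kT/k) = 5 nm ≈ 10% of rest length |
| repulsion force | 200 kT/μm | constant force on overlap; thermal overlap depth kT/F = 5 nm ≈ 20% of radius — beads may ingress (a bead is ten nucleosomes, not a rigid sphere) |
| confinement | R = 4.5 μm, constant inward force 50 kT/μm outside | nuclear envelope; at this size it imposes almost no constraint on the chain (a reflecting boundary is available) |
| time step | 5·10⁻⁷ | RMS free step √(6·D·dt) ≈ 1.7 nm ≤ 2 nm, resolving the 5 nm overlap scale; k·dt/ζ = 0.02 ≪ 1 |
| equilibration | 10⁵ steps (0.05 time units) | longer than the relaxation time of the chain segments the fit window probes (~10–20 beads) |
| production | 2·10⁶ steps, sampled every 2000 | 1000 frames at 10⁻³ time units |

The measured MSD exponents are insensitive to the exact stiffness,
repulsion and step values within broad ranges; what they *are*
sensitive to is statistics: per-bead power-law fits on short
trajectories (≲ 300 frames) are biased downward by several hundredths,
which is why the production run records 1000 frames.

Initialization is a self-avoiding-biased random walk (step = bond rest
length, rejecting positions within 1.4 bead radii of the 20 preceding
beads or outside the sphere), deterministic under the seed. Pairwise
repulsion is O(n²) per step in a numba kernel; a displacement larger
than the bead radius in any single step aborts the run with advice to
reduce the time step.

**Fit window.** Monomer motion crosses over from free diffusion to
connectivity-dominated subdiffusion at roughly the time to diffuse one
bond length (τ_b = b²/6D ≈ 4·10⁻⁴ time units). The default window is
one decade starting at 10× the sampling interval, [10⁻², 10⁻¹] — i.e.
~25–250 τ_b, late enough that the phantom chain shows its asymptotic
slope, and far below the terminal (Rouse/whole-chain) time of the
default chains. Interior beads (middle 50% of the chain) are tracked;
chain ends relax differently and are excluded. With these settings the
reduced 500-bead phantom chain fits to mean α ≈ 0.51 and the
excluded-volume chain to ≈ 0.59 (3D and 2D-projected alike, the
projection only broadening the per-bead spread) — bracketing the
theoretical 0.5 / ≈0.54 values from above, as expected on a window
that is asymptotic for the phantom chain but still inside the slow
excluded-volume crossover.

2D projection draws one plane normal uniformly on the sphere per call
(seeded) and projects every track orthogonally, mimicking single-plane
image acquisition; for isotropic motion the projected MSD is 2/3 of
the 3D MSD.

## Hi-C statistics

Coordinates are 0-based half-open bins of fixed size, concatenated
over chromosomes; every bin belongs to the arm on whose side of the
centromere its midpoint lies. Contact files are triplet text
(bin1_start, bin2_start, value in genome-wide concatenated
coordinates); duplicate and mirrored entries are summed. Masked bins
(zero coverage, or user-set) are excluded from every statistic, never
zero-filled.

* **Balancing.** KR-style balancing finds a symmetric diagonal scaling
  with equal row sums (fixed-point iteration on the scaling vector,
  convergence rtol 1e-8 on row-sum uniformity, error on
  non-convergence); validated against an independent Sinkhorn
  alternating-scaling oracle and for idempotence. vc_sqrt divides each
  entry by √(c_i·c_j) of the raw coverages.
* **Classification.** Value-weighted proportions of intra-arm,
  inter-arm and trans contact, each unordered pair counted once; both
  raw-count and normalised-value weighting are available (the choice
  is the caller's, via which matrix is passed).
* **z-scores.** On vc_sqrt values by convention (any normalisation
  accepted and recorded). Bands are intra-arm diagonals at separation
  d ≥ 2 bins — the diagonal and adjacent bins never enter; bands with
  fewer than 15 unmasked pairs, or zero spread, are masked. Band
  statistics are per-arm by default with genome-wide pooling optional.
  Within every retained band the z values have mean 0 and sd 1 by
  construction. Interaction calling keeps pairs with z strictly
  greater than the threshold (default 2).
* **Aggregates.** ±8 kb windows (9×9 at 2 kb — odd and centred; the
  8×8 reading is available) around each called pair, each normalised
  by its own mean, averaged element-wise; windows truncated by arm
  edges are dropped.
* **Insulation.** The fine map is aggregated to 10 kb vectors: at each
  coarse position and each offset o ∈ {10, …, 100 kb}, the mean value
  over pairs separated by o whose midpoint falls in that coarse bin;
  coarse bins without full geometric support (edges) are masked rather
  than partially averaged. Border profiles take ±100 kb windows of
  each offset vector across border midpoints, normalise by the window
  mean, log2-transform, and average across borders.
* **Virtual 4C.** One matrix row over a region, smoothed by locally
  weighted polynomial regression (tricube weights, degree 2, span 0.3
  by default — span and band method exposed) with a pointwise 95%
  normal-approximation band from the equivalent-kernel variance; a
  degree-2 local fit reproduces any linear profile exactly.
* **Median interaction distance.** Per bin, the contact-value-weighted
  median of intra-chromosomal partner distances.

## Synthetic generators

Trajectories are built from *exact* fractional Gaussian noise
(circulant embedding of the fGn autocovariance; the embedding spectrum
is non-negative for all Hurst H ∈ (0,1), so no approximation is
involved), giving stationary-increment subdiffusion with ensemble MSD
exactly mobility·τ^α* (H = α*/2) — the assumption the downstream
estimators make. Mixtures assign each track to a component with the
component weights as probabilities. The default mobility scale
0.02 μm²·s^−α puts MSD(0.5 s) near 0.014 μm², a typical interphase
yeast locus; localization noise defaults to 0 (off) but is available
because real spot tracking has it. Confined fixtures are exact
Ornstein–Uhlenbeck discretizations started at stationarity.

For the two-population mixture experiment (components 0.9/α=0.60 and
0.1/α=0.78) the track length is 2000 frames (40 s at 20 ms): per-track
fit noise is ~0.15 at 100 frames, ~0.05 at 1000 and ~0.035 at 2000
frames, and the 0.18 exponent separation is only resolvable when it is
several times the per-track noise — at 2000 frames the separation is
~5σ and the mixture weight is recovered to within ±0.05. This mirrors
the tens-of-seconds recordings of real experiments.

Contact maps have expected value depth·max(|i−j|,1)^γ within
chromosomes (γ < 0), a flat trans level, multiplicative block and loop
enrichments, and Poisson counts, with the planted loop/border lists
returned as truth.

**What synthetic validation does not show.** fGn tracks have no
localization error by default, no blinking/gap structure, and exactly
power-law MSDs; real loci have measurement noise (which biases
exponents up at short delays), confinement, and heterogeneous
mobility. Poisson maps have no coverage biases for balancing to
remove (balancing is validated on synthetic row-sum heterogeneity
instead), no translocations, and independent counts. Passing tests
demonstrate correctness of the estimators under their stated
assumptions, not robustness to every artefact of real data.

## Problem sizes used in validation

The test suite and the reproduction script use the reduced 500-bead
chain (2·10⁶ production steps), 200–1000 synthetic tracks of 100–2000
frames, and 0.4–1 Mb synthetic genomes at 2 kb bins — sizes chosen so
the full suite runs on a laptop-class single core in well under half
an hour while every estimate remains comfortably inside its stated
tolerance. The full 2436-bead chain is available behind
`SimConfig()` / `--full-scale`.
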