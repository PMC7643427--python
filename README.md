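# chromodyn

Chromatin-mobility statistics, coarse-grained polymer dynamics, and
Hi-C contact-map statistics for interphase yeast chromatin — the
quantitative toolkit behind questions like *"does condensin confine
chromatin movement, and what kind of polymer does chromatin behave
like without it?"*

It is written for people analysing single-particle tracking of
chromosomal loci (e.g. LacO/LacI-GFP arrays imaged at 20 ms intervals)
together with binned Hi-C contact maps, and for people who want a
small, transparent bead–spring chromosome simulator to compare those
measurements against polymer theory.

## What it computes

**Locus mobility.** For each trajectory the time-averaged mean squared
displacement m_i(τ) over all overlapping displacement pairs
(N_i(τ) = n − k of them at lag k), the N_i-weighted ensemble mean

    ⟨m(τ)⟩ = Σ_i N_i(τ) m_i(τ) / Σ_i N_i(τ)

with its *exact* standard error

    σ²⟨m⟩(τ) = (1/N) [ (1/N) Σ_i N_i (m_i² + σ_i²) − ⟨m⟩² ],

per-track power-law fits m(τ) = a τ^α (Nelder–Mead start, refined by
nonlinear least squares giving α_i ± δα_i), the 1/δα²-weighted
histogram and Gaussian-kernel density of exponents, one- and
two-Gaussian descriptions of that density with model selection, and
the length of constraint L_c — the standard deviation of the locus
position about its time average, i.e. the radius of the region the
locus explores. Subdiffusion appears as α < 1: an ideal Rouse-polymer
monomer has α = 0.5, free diffusion α = 1.

**Polymer theory and simulation.** The closed-form monomer-MSD
prediction α = 2ν/(1+2ν) for a chain with Flory exponent ν (α = 0.5
for the phantom Rouse chain, α ≈ 0.54 for an excluded-volume chain in
good solvent with ν = 3/5 or 0.588), and an overdamped-Langevin
bead–spring chromosome-arm simulator (2436 beads of 25 nm radius by
default ≈ a 3.6 Mb arm at 10 nucleosomes/bead; harmonic bonds;
constant-force repulsion between overlapping beads; 4.5 μm confinement
sphere; Euler–Maruyama integration) with random-plane 2D projection to
mimic single-plane microscopy.

**Hi-C statistics.** KR (equal row sums) and vc_sqrt balancing,
intra-arm / inter-arm / trans contact classification, distance-decay
P(s) curves, per-distance-band z-scores (minimum separation 2 bins,
bands with < 15 pairs excluded) with strict z > 2 interaction calling,
common/specific comparison of two conditions, aggregate submatrices
around called interactions (±8 kb), insulation vectors at 10–100 kb
offsets with log2 border profiles, loess-smoothed virtual-4C viewpoint
profiles with 95% bands, and per-bin median interaction distances.

**Synthetic data.** Generators with known ground truth for every stage:
exact fractional-Gaussian-noise trajectories with prescribed MSD
exponents (and mixtures thereof), Ornstein–Uhlenbeck confined tracks,
and Poisson contact maps with power-law decay, block domains and
planted loops.

## Worked example

```python
import numpy as np
from chromodyn import msd
from chromodyn.synthetic import TrajectoryRecipe, generate_tracks

# 1000 synthetic loci, 40 s at 20 ms/frame: 90% of cells with MSD
# exponent 0.6, 10% with a more mobile 0.78 population
ts = generate_tracks(TrajectoryRecipe(
    n_tracks=1000, n_frames=2000,
    components=((0.9, 0.60, 0.02), (0.1, 0.78, 0.02)), seed=7))

fits = msd.fit_exponents(msd.msd_trackset(ts, tau_max=0.5))
dens = msd.exponent_density(fits)
single = msd.fit_gaussians(dens, 1)
double = msd.fit_gaussians(dens, 2)
print(msd.select_model(single, double))   # -> double
main = double.main_component
print(f"w={main['w']:.2f} mean={main['mean']:.2f}")  # -> w=0.86 mean=0.60
```

The two-Gaussian description is preferred (the single Gaussian leaves
> 2x the residual), and the dominant component recovers the planted
90%/0.60 population; the minority component sits at the planted 0.78.

The same fitting code runs on simulator output:

```python
from chromodyn.polymer import SimConfig, run_simulation

cfg = SimConfig.reduced(seed=1)          # 500-bead excluded-volume chain
tracks = run_simulation(cfg)             # 3D tracks of the mid-chain beads
lo, hi = cfg.fit_window()
fits = msd.fit_exponents(msd.msd_trackset(tracks, tau_max=hi),
                         tau_max=hi, tau_min=lo)
print(np.mean([f.alpha for f in fits]))  # -> 0.59 (phantom chain: 0.51)
```

A command-line interface mirrors the library
(`chromodyn --help`: synth-tracks, synth-hic, msd, exponents, lc,
simulate, project, hic-balance, hic-classify, hic-decay, hic-zscore,
hic-compare, hic-aggregate, hic-insulation, virtual4c, report); every
run writes a JSON manifest of its resolved parameters and seed.

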