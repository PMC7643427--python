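"""Synthetic trajectories and contact maps with known ground truth.

Every pipeline stage is testable without external data:

* :func:`generate_tracks` draws locus trajectories whose increments are
  exact fractional Gaussian noise (Hurst H = alpha*/2), so the ensemble
  MSD is exactly proportional to tau^alpha*; mixtures of mobility
  populations and localization noise are supported.
* :func:`generate_confined_tracks` draws mean-reverting
  (Ornstein-Uhlenbeck) trajectories with a prescribed stationary spread,
  the fixture for length-of-constraint checks (L_c -> sd * sqrt(d)).
* :func:`generate_contact_map` builds Poisson-sampled contact matrices
  with power-law distance decay, block domains and planted point loops,
  returning the ground-truth loop/border lists alongside.

Fractional Gaussian noise is generated by circulant embedding of the
exact autocovariance (Davies-Harte), not an approximate CTRW scheme,
because the downstream analyses assume stationary-increment
subdiffusion.  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .hic import ContactMatrix, GenomeLayout
from .trajectories import Track, TrackSet

__all__ = [
    "TrajectoryRecipe", "MapRecipe", "fractional_gaussian_noise",
    "generate_tracks", "generate_confined_tracks",
    "generate_contact_map", "generate_condition_pair", "demo_layout",
]


# ---------------------------------------------------------------------------
# fractional Gaussian noise


def fractional_gaussian_noise(
    n: int, hurst: float, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact stationary fGn samples, shape (n_samples, n), unit scale.

    Circulant embedding of the fGn autocovariance
    gamma(k) = 0.5 (|k+1|^2H - 2|k|^2H + |k-1|^2H); cumulative sums are
    fractional Brownian motion with Var B(k) = k^(2H).  The circulant
    spectrum of fGn is non-negative for all H in (0, 1), so the
    embedding is exact.
    """
    if not 0 < hurst < 1:
        raise ValueError(f"Hurst exponent must be in (0, 1), got {hurst}")
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    c = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    m = c.size
    lam = np.fft.fft(c).real
    lam = np.where(lam < 0, 0.0, lam)  # clip O(eps) negatives

    n_draws = (n_samples + 1) // 2
    out = np.empty((n_samples, n))
    for start in range(0, n_draws, 256):  # chunked to bound memory
        stop = min(start + 256, n_draws)
        nb = stop - start
        v = rng.standard_normal((nb, m)) + 1j * rng.standard_normal((nb, m))
        xi = np.sqrt(m) * np.fft.ifft(np.sqrt(lam)[None, :] * v, axis=1)
        re = xi[:, :n].real
        im = xi[:, :n].imag
        for b in range(nb):
            i = 2 * (start + b)
            out[i] = re[b]
            if i + 1 < n_samples:
                out[i + 1] = im[b]
    return out


# ---------------------------------------------------------------------------
# trajectory recipes


@dataclass(frozen=True)
class TrajectoryRecipe:
    """Conditions for a synthetic tracking experiment.

    ``components`` lists (weight, target MSD exponent alpha*, mobility
    scale) triples; weights are component probabilities summing to 1.
    The mobility scale c is defined so that the ensemble MSD (all
    spatial dimensions summed) is c * tau^alpha* um^2 with tau in
    seconds.  The default mobility 0.02 um^2 s^-alpha puts the MSD at a
    0.5 s delay near 0.014 um^2, a typical yeast interphase locus.
    Localization noise defaults to 0 (off).
    """

    n_tracks: int = 200
    n_frames: int = 100
    dt: float = 0.02
    components: tuple = ((1.0, 0.5, 0.02),)
    ndim: int = 2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        w = np.array([c[0] for c in self.components], dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("component weights must be >= 0 and sum to 1")
        for _, alpha, _ in self.components:
            if not 0 < alpha < 2:
                raise ValueError(f"target exponent must be in (0, 2), got {alpha}")


def generate_tracks(recipe: TrajectoryRecipe) -> TrackSet:
    """Draw a TrackSet from a mixture of fBm-like mobility populations.

    Each track is assigned to one component with the component weights
    as probabilities; its per-axis increments are exact fGn with
    H = alpha*/2 scaled so the d-dimensional ensemble MSD equals
    mobility * tau^alpha*.  Independent Gaussian localization noise of
    sd ``noise_sd`` is added to every frame.
    """
    rng = np.random.default_rng(recipe.seed)
    weights = np.array([c[0] for c in recipe.components])
    assignment = rng.choice(len(recipe.components), size=recipe.n_tracks, p=weights)
    n_inc = recipe.n_frames - 1
    tracks: list[Track] = [None] * recipe.n_tracks
    for ci, (_, alpha, mobility) in enumerate(recipe.components):
        members = np.nonzero(assignment == ci)[0]
        if members.size == 0:
            continue
        hurst = alpha / 2
        # per-axis Var of the position at time t = k*dt must be
        # (mobility/d) * t^alpha  =>  increment scale sigma = sqrt(mobility/d)*dt^H
        sigma = np.sqrt(mobility / recipe.ndim) * recipe.dt**hurst
        inc = fractional_gaussian_noise(n_inc, hurst, members.size * recipe.ndim, rng)
        inc = sigma * inc.reshape(members.size, recipe.ndim, n_inc)
        pos = np.concatenate(
            [np.zeros((members.size, recipe.ndim, 1)), np.cumsum(inc, axis=2)], axis=2
        ).transpose(0, 2, 1)  # (tracks, frames, dims)
        if recipe.noise_sd > 0:
            pos = pos + recipe.noise_sd * rng.standard_normal(pos.shape)
        for m, p in zip(members, pos):
            tracks[m] = Track(id=f"synth-{m:04d}", dt=recipe.dt, positions=p)
    return TrackSet([t for t in tracks if t is not None], condition="synthetic")


def generate_confined_tracks(
    stationary_sd: float,
    relaxation_time: float = 0.2,
    n_tracks: int = 50,
    n_frames: int = 2000,
    dt: float = 0.02,
    ndim: int = 2,
    seed: int = 0,
) -> TrackSet:
    """Mean-reverting (OU) tracks with a prescribed stationary per-axis sd.

    Exact discretization of the Ornstein-Uhlenbeck process started at
    stationarity; for long tracks the length of constraint converges to
    stationary_sd * sqrt(ndim) and the MSD plateaus at
    2 * ndim * stationary_sd^2.
    """
    rng = np.random.default_rng(seed)
    rho = np.exp(-dt / relaxation_time)
    innov_sd = stationary_sd * np.sqrt(1 - rho**2)
    tracks = []
    for i in range(n_tracks):
        pos = np.empty((n_frames, ndim))
        pos[0] = stationary_sd * rng.standard_normal(ndim)
        shocks = innov_sd * rng.standard_normal((n_frames - 1, ndim))
        for t in range(1, n_frames):
            pos[t] = rho * pos[t - 1] + shocks[t - 1]
        tracks.append(Track(id=f"ou-{i:04d}", dt=dt, positions=pos))
    return TrackSet(tracks, condition="confined")


# ---------------------------------------------------------------------------
# contact-map recipes


def demo_layout(
    n_chroms: int = 2,
    chrom_length: int = 600_000,
    centromere_frac: float = 0.45,
    binsize: int = 2000,
) -> GenomeLayout:
    """A small multi-chromosome layout for synthetic maps."""
    names = tuple(["I", "II", "III", "IV", "V"][:n_chroms])
    return GenomeLayout(
        chroms=names,
        lengths=(chrom_length,) * n_chroms,
        centromeres=(int(chrom_length * centromere_frac),) * n_chroms,
        binsize=binsize,
    )


@dataclass(frozen=True)
class MapRecipe:
    """Conditions for a synthetic Hi-C map.

    Expected counts: mu[i,j] = depth * max(|i-j|, 1)^gamma for
    intra-chromosomal pairs (gamma < 0), times any block enrichment
    (both bins inside the same block interval) and loop enrichment
    (planted bin pairs, fold f > 1); trans pairs get
    depth * trans_level.  Observed counts are Poisson(mu), symmetrised.
    """

    layout: GenomeLayout
    decay_gamma: float = -1.0
    depth: float = 200.0
    trans_level: float = 0.001
    blocks: tuple = ()      # (chrom, start_bp, end_bp, enrichment)
    loops: tuple = ()       # (chrom, pos1_bp, pos2_bp, fold)
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self):
        if self.decay_gamma >= 0:
            raise ValueError("decay exponent gamma must be negative")
        for *_, fold in self.loops:
            if fold <= 1:
                raise ValueError("planted loop fold enrichment must be > 1")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise model must be 'poisson' or 'none'")


def _expected_matrix(recipe: MapRecipe) -> np.ndarray:
    lay = recipe.layout
    n = lay.n_bins
    chrom_idx = lay.chrom_index()
    dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
    np.maximum(dist, 1.0, out=dist)
    mu = recipe.depth * dist**recipe.decay_gamma
    mu[chrom_idx[:, None] != chrom_idx[None, :]] = recipe.depth * recipe.trans_level
    for chrom, start, end, enrich in recipe.blocks:
        b0 = lay.bin_of(chrom, start)
        b1 = lay.bin_of(chrom, end - 1) + 1
        mu[b0:b1, b0:b1] *= enrich
    for chrom, p1, p2, fold in recipe.loops:
        i, j = lay.bin_of(chrom, p1), lay.bin_of(chrom, p2)
        mu[i, j] *= fold
        mu[j, i] *= fold
    return mu


def generate_contact_map(recipe: MapRecipe) -> tuple[ContactMatrix, dict]:
    """Sample a contact map and return it with its ground truth.

    Truth dict: ``loops`` (BEDPE-style frame of planted pairs),
    ``borders`` (BED-style frame of block boundaries), and the global
    bin-pair key set ``loop_keys``.
    """
    lay = recipe.layout
    mu = _expected_matrix(recipe)
    rng = np.random.default_rng(recipe.seed)
    if recipe.noise == "poisson":
        iu, ju = np.triu_indices(lay.n_bins)
        counts = rng.poisson(mu[iu, ju]).astype(float)
        mat = np.zeros_like(mu)
        mat[iu, ju] = counts
        mat[ju, iu] = counts
    else:
        mat = mu
    cm = ContactMatrix(lay, sp.csr_matrix(mat), normalization="raw")

    bs = lay.binsize
    loop_rows, loop_keys = [], set()
    for chrom, p1, p2, fold in recipe.loops:
        i, j = sorted((lay.bin_of(chrom, p1), lay.bin_of(chrom, p2)))
        loop_keys.add((i, j))
        s1, s2 = (i - lay.chrom_offsets[lay.chroms.index(chrom)]) * bs, \
                 (j - lay.chrom_offsets[lay.chroms.index(chrom)]) * bs
        loop_rows.append((chrom, s1, s1 + bs, chrom, s2, s2 + bs, fold))
    border_rows = []
    for chrom, start, end, _ in recipe.blocks:
        for p in (start, end):
            border_rows.append((chrom, p, p + 1))
    truth = {
        "loops": pd.DataFrame(loop_rows, columns=["chrom1", "start1", "end1",
                                                  "chrom2", "start2", "end2", "fold"]),
        "borders": pd.DataFrame(border_rows, columns=["chrom", "start", "end"]),
        "loop_keys": loop_keys,
    }
    return cm, truth


def generate_condition_pair(
    shared: tuple,
    a_only: tuple,
    b_only: tuple,
    recipe: MapRecipe,
) -> tuple[ContactMatrix, ContactMatrix, dict]:
    """Two condition maps sharing ``shared`` loops plus specific ones.

    ``shared``, ``a_only`` and ``b_only`` are loop tuples as in
    :class:`MapRecipe`; the specific lists must not overlap each other
    or the shared list.  Independent Poisson noise per condition
    (seeds derived from the recipe seed).
    """
    def keys(loops):
        return {tuple(sorted((recipe.layout.bin_of(c, p1), recipe.layout.bin_of(c, p2))))
                for c, p1, p2, _ in loops}

    ks, ka, kb = keys(shared), keys(a_only), keys(b_only)
    if (ks & ka) or (ks & kb) or (ka & kb):
        raise ValueError("shared and condition-specific loop lists overlap")

    from dataclasses import replace
    rec_a = replace(recipe, loops=tuple(shared) + tuple(a_only), seed=recipe.seed * 2 + 1)
    rec_b = replace(recipe, loops=tuple(shared) + tuple(b_only), seed=recipe.seed * 2 + 2)
    cm_a, truth_a = generate_contact_map(rec_a)
    cm_b, truth_b = generate_contact_map(rec_b)
    truth = {
        "shared_keys": ks, "a_only_keys": ka, "b_only_keys": kb,
        "loops_a": truth_a["loops"], "loops_b": truth_b["loops"],
    }
    return cm_a, cm_b, truth
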