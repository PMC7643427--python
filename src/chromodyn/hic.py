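"""Hi-C contact-map statistics on binned, genome-wide matrices.

The coordinate system is a :class:`GenomeLayout`: chromosomes with
lengths and centromere positions, partitioned into fixed-size 0-based
half-open bins ``[start, start + binsize)`` and concatenated into one
genome-wide bin index.  Every bin belongs to exactly one chromosome arm
(assignment by bin midpoint versus the centromere).

On top of a symmetric :class:`ContactMatrix` this module implements:
matrix balancing (KR-style equal row sums, and vc_sqrt coverage
normalisation), intra-arm / inter-arm / trans contact classification,
distance-decay curves, per-distance-band z-scores with the exclusion
rules (minimum separation of 2 bins, bands with < 15 pairs dropped),
z > 2 interaction calling and condition comparison, aggregate (APA-style)
submatrix averages around called interactions, insulation vectors at
10-100 kb offsets with log2 border profiles, virtual-4C viewpoint
profiles with loess smoothing, and per-bin median interaction distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GenomeLayout", "ContactMatrix", "ZScoreMap", "InteractionSet",
    "read_layout", "read_contacts", "write_contacts",
    "kr_balance", "vc_sqrt_balance", "classify_contacts", "contact_decay",
    "decay_exponent", "zscore_map", "call_interactions", "compare_sets",
    "aggregate_matrix", "insulation_vectors", "border_profile",
    "virtual_4c", "median_interaction_distance", "loess",
]


# ---------------------------------------------------------------------------
# layout


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths, centromere positions and the bin grid."""

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]
    centromeres: tuple[int, ...]
    binsize: int

    def __post_init__(self):
        if self.binsize <= 0:
            raise ValueError("binsize must be positive")
        for name, ln, cen in zip(self.chroms, self.lengths, self.centromeres):
            if not 0 < cen < ln:
                raise ValueError(f"centromere of {name} ({cen}) outside chromosome (0, {ln})")

    @classmethod
    def from_table(cls, df: pd.DataFrame, binsize: int) -> "GenomeLayout":
        return cls(
            tuple(str(c) for c in df["chrom"]),
            tuple(int(v) for v in df["length"]),
            tuple(int(v) for v in df["centromere"]),
            int(binsize),
        )

    @property
    def n_bins_per_chrom(self) -> np.ndarray:
        return np.array([-(-ln // self.binsize) for ln in self.lengths])

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Global bin index of the first bin of each chromosome."""
        return np.concatenate([[0], np.cumsum(self.n_bins_per_chrom)[:-1]])

    @property
    def n_bins(self) -> int:
        return int(self.n_bins_per_chrom.sum())

    def chrom_index(self) -> np.ndarray:
        """Per-bin chromosome index."""
        return np.repeat(np.arange(len(self.chroms)), self.n_bins_per_chrom)

    def arm_index(self) -> np.ndarray:
        """Per-bin arm id: 2*chrom for the left arm, 2*chrom+1 for the right.

        A bin is on the left arm iff its midpoint lies before the
        centromere.
        """
        out = np.empty(self.n_bins, dtype=int)
        for ci, (nb, off, cen) in enumerate(
            zip(self.n_bins_per_chrom, self.chrom_offsets, self.centromeres)
        ):
            mids = (np.arange(nb) + 0.5) * self.binsize
            out[off:off + nb] = np.where(mids < cen, 2 * ci, 2 * ci + 1)
        return out

    def arm_slices(self) -> list[tuple[str, slice]]:
        """Contiguous global-bin slice of every arm, with labels like 'I_L'."""
        arms = self.arm_index()
        out = []
        for ci, name in enumerate(self.chroms):
            for side, aid in (("L", 2 * ci), ("R", 2 * ci + 1)):
                idx = np.nonzero(arms == aid)[0]
                if idx.size:
                    out.append((f"{name}_{side}", slice(int(idx[0]), int(idx[-1]) + 1)))
        return out

    def bin_of(self, chrom: str, pos: int) -> int:
        ci = self.chroms.index(chrom)
        if not 0 <= pos < self.lengths[ci]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self.chrom_offsets[ci] + pos // self.binsize)

    def bin_start(self, gbin: int) -> tuple[str, int]:
        """(chrom, start-bp) of a global bin."""
        ci = int(np.searchsorted(self.chrom_offsets, gbin, side="right") - 1)
        local = gbin - self.chrom_offsets[ci]
        return self.chroms[ci], int(local * self.binsize)


def read_layout(path, binsize: int) -> GenomeLayout:
    """Read a whitespace-delimited layout file: ``chrom length centromere``."""
    df = pd.read_csv(path, sep=r"\s+", comment="#",
                     names=["chrom", "length", "centromere"], dtype={"chrom": str})
    if df.empty:
        raise ValueError("empty layout file")
    return GenomeLayout.from_table(df, binsize)


# ---------------------------------------------------------------------------
# contact matrix


@dataclass
class ContactMatrix:
    """Symmetric binned contact map with an explicit normalization state.

    ``matrix`` is scipy CSR over genome-wide bins; ``mask`` marks bins
    excluded from analysis (e.g. zero coverage); masked bins propagate
    through every downstream statistic rather than being zero-filled.
    """

    layout: GenomeLayout
    matrix: sp.csr_matrix
    normalization: str = "raw"
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        n = self.layout.n_bins
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != layout bins {n}")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        diff = abs(self.matrix - self.matrix.T)
        if diff.nnz and diff.max() > 1e-8 * max(self.matrix.max(), 1.0):
            raise ValueError("contact matrix is not symmetric")

    @property
    def binsize(self) -> int:
        return self.layout.binsize

    def toarray(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def block(self, sl: slice) -> np.ndarray:
        """Dense on-diagonal block with masked bins set to NaN."""
        out = np.asarray(self.matrix[sl, sl].todense(), dtype=float)
        m = self.mask[sl]
        out[m, :] = np.nan
        out[:, m] = np.nan
        return out


def read_contacts(path, layout: GenomeLayout) -> ContactMatrix:
    """Read a triplet text file ``bin1_start  bin2_start  value``.

    Bin columns are bin start coordinates (multiples of the bin size) in
    genome-wide concatenated coordinates; duplicate (i, j)/(j, i)
    entries are summed.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["b1", "b2", "value"])
    if df.empty:
        raise ValueError("empty contact file")
    bs = layout.binsize
    starts = df[["b1", "b2"]].to_numpy()
    if np.any(starts % bs != 0):
        raise ValueError(f"bin columns must be multiples of the bin size {bs}")
    i = (starts[:, 0] // bs).astype(int)
    j = (starts[:, 1] // bs).astype(int)
    n = layout.n_bins
    if np.any((i < 0) | (i >= n) | (j < 0) | (j >= n)):
        raise ValueError("bin out of range for layout")
    vals = df["value"].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative contact value")
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    upper = sp.coo_matrix((vals, (lo, hi)), shape=(n, n)).tocsr()
    upper.sum_duplicates()
    diag = sp.diags(upper.diagonal())
    full = upper + upper.T - diag
    return ContactMatrix(layout, full.tocsr())


def write_contacts(cm: ContactMatrix, path) -> None:
    """Write the upper triangle (incl. diagonal) as triplet text."""
    coo = sp.triu(cm.matrix).tocoo()
    bs = cm.binsize
    df = pd.DataFrame({"b1": coo.row * bs, "b2": coo.col * bs, "value": coo.data})
    df.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# balancing


def kr_balance(cm: ContactMatrix, rtol: float = 1e-8, max_iter: int = 5000) -> ContactMatrix:
    """Balance the matrix to equal row sums (KR/doubly-stochastic up to scale).

    Symmetric diagonal scaling ``D M D`` found by fixed-point iteration
    on the scaling vector; all-zero rows are masked and left out.
    Raises on non-convergence.
    """
    if cm.normalization != "raw":
        raise ValueError(f"kr_balance expects a raw matrix, got {cm.normalization!r}")
    A = cm.matrix.tocsr().astype(float)
    rows = np.asarray(A.sum(axis=1)).ravel()
    mask = cm.mask | (rows == 0)
    keep = ~mask
    sub = A[keep][:, keep]
    x = np.ones(int(keep.sum()))
    converged = False
    for _ in range(max_iter):
        s = x * (sub @ x)
        s_mean = s.mean()
        if np.max(np.abs(s / s_mean - 1)) < rtol:
            converged = True
            break
        x = x / np.sqrt(s / s_mean)
    if not converged:
        raise RuntimeError(f"KR balancing did not converge in {max_iter} iterations")
    d = np.zeros(cm.layout.n_bins)
    d[keep] = x / np.sqrt(s_mean)
    D = sp.diags(d)
    out = (D @ A @ D).tocsr()
    return ContactMatrix(cm.layout, out, normalization="KR", mask=mask.copy())


def vc_sqrt_balance(cm: ContactMatrix) -> ContactMatrix:
    """Vanilla-coverage square-root normalisation.

    M'[i,j] = M[i,j] / sqrt(c_i * c_j) with c_k the coverage (row sum)
    of bin k; zero-coverage bins are masked.
    """
    if cm.normalization != "raw":
        raise ValueError(f"vc_sqrt_balance expects a raw matrix, got {cm.normalization!r}")
    A = cm.matrix.tocsr().astype(float)
    cov = np.asarray(A.sum(axis=1)).ravel()
    mask = cm.mask | (cov == 0)
    inv = np.zeros_like(cov)
    inv[~mask] = 1.0 / np.sqrt(cov[~mask])
    D = sp.diags(inv)
    return ContactMatrix(cm.layout, (D @ A @ D).tocsr(), normalization="vc_sqrt", mask=mask.copy())


# ---------------------------------------------------------------------------
# classification & decay


def classify_contacts(cm: ContactMatrix, layout: GenomeLayout | None = None) -> dict:
    """Value-weighted proportions of intra-arm, inter-arm and trans contacts.

    Intra-arm: both bins on the same chromosome arm; inter-arm: same
    chromosome, different arms; trans: different chromosomes.  Each
    unordered bin pair counts once; proportions sum to 1.
    """
    layout = layout or cm.layout
    arms = layout.arm_index()
    chroms = layout.chrom_index()
    coo = sp.triu(cm.matrix).tocoo()
    keep = ~(cm.mask[coo.row] | cm.mask[coo.col])
    r, c, v = coo.row[keep], coo.col[keep], coo.data[keep]
    total = v.sum()
    if total == 0:
        raise ValueError("contact matrix has no unmasked contacts")
    intra = v[arms[r] == arms[c]].sum()
    inter = v[(arms[r] != arms[c]) & (chroms[r] == chroms[c])].sum()
    trans = v[chroms[r] != chroms[c]].sum()
    return {"intra_arm": intra / total, "inter_arm": inter / total, "trans": trans / total}


def contact_decay(cm: ContactMatrix, arm: str | None = None, n_bands: int = 25) -> pd.DataFrame:
    """Mean contact value per log-spaced genomic-distance band (P(s)).

    Restricted to intra-arm pairs of one arm (e.g. ``"I_L"``) or, when
    ``arm`` is None, all arms pooled.  Bands with no pairs are omitted.
    Columns: distance_bp (geometric band centre), mean_value, n_pairs.
    """
    arm_blocks = [sl for name, sl in cm.layout.arm_slices() if arm is None or name == arm]
    if not arm_blocks:
        raise ValueError(f"unknown arm {arm!r}")
    dists, vals = [], []
    for sl in arm_blocks:
        block = cm.block(sl)
        n = block.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        v = block[iu, ju]
        ok = ~np.isnan(v)
        dists.append((ju - iu)[ok] * cm.binsize)
        vals.append(v[ok])
    d = np.concatenate(dists)
    v = np.concatenate(vals)
    if d.size == 0:
        raise ValueError("no intra-arm pairs")
    edges = np.unique(np.geomspace(cm.binsize, d.max() + 1, n_bands + 1))
    idx = np.digitize(d, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not np.any(sel):
            continue
        rows.append({
            "distance_bp": float(np.sqrt(edges[b] * edges[b + 1])),
            "mean_value": float(v[sel].mean()),
            "n_pairs": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def decay_exponent(decay: pd.DataFrame, d_min: float = 0, d_max: float = np.inf) -> float:
    """Log-log slope of the P(s) curve over [d_min, d_max]."""
    sel = (decay["distance_bp"] >= d_min) & (decay["distance_bp"] <= d_max) & (decay["mean_value"] > 0)
    x = np.log(decay.loc[sel, "distance_bp"])
    y = np.log(decay.loc[sel, "mean_value"])
    if len(x) < 2:
        raise ValueError("need at least two bands to fit a decay exponent")
    return float(np.polyfit(x, y, 1)[0])


# ---------------------------------------------------------------------------
# z-scores and interaction calling


@dataclass
class ZScoreMap:
    """Per-arm dense z-score matrices (NaN where masked/excluded)."""

    layout: GenomeLayout
    arms: dict  # arm label -> (slice, dense z array)
    source_normalization: str
    min_separation: int
    min_band_pairs: int


def zscore_map(
    cm: ContactMatrix,
    min_separation: int = 2,
    min_band_pairs: int = 15,
    pooling: str = "per_arm",
) -> ZScoreMap:
    """Distance-band z-scores of intra-arm contact values.

    For each genomic-distance band d (in bins, d >= ``min_separation``;
    the diagonal and first off-diagonal never enter), the distribution
    of bin-pair values in that band yields z = (v - mean) / sd.  Bands
    with fewer than ``min_band_pairs`` unmasked pairs are excluded, as
    are bands with zero spread (with a warning).  Band statistics are
    per arm by default, or pooled genome-wide over arms
    (``pooling="genome"``).

    The paper's convention uses vc_sqrt-normalised values; any
    normalisation is accepted and recorded.
    """
    if pooling not in ("per_arm", "genome"):
        raise ValueError("pooling must be 'per_arm' or 'genome'")
    arm_list = cm.layout.arm_slices()
    blocks = {name: cm.block(sl) for name, sl in arm_list}
    zs = {name: np.full_like(b, np.nan) for name, b in blocks.items()}

    max_n = max(b.shape[0] for b in blocks.values())
    for d in range(min_separation, max_n):
        band_vals = {}
        for name, b in blocks.items():
            n = b.shape[0]
            if d >= n:
                continue
            v = np.diagonal(b, offset=d)
            band_vals[name] = v
        if pooling == "genome":
            pooled = np.concatenate([v[~np.isnan(v)] for v in band_vals.values()]) \
                if band_vals else np.array([])
            stats_for = {name: pooled for name in band_vals}
        else:
            stats_for = {name: v[~np.isnan(v)] for name, v in band_vals.items()}
        for name, vals in band_vals.items():
            ref = stats_for[name]
            if ref.size < min_band_pairs:
                continue
            mu, sd = ref.mean(), ref.std()
            if sd == 0:
                warnings.warn(f"zero spread in distance band {d} of arm {name}; band masked")
                continue
            z = (vals - mu) / sd
            n = blocks[name].shape[0]
            idx = np.arange(n - d)
            zs[name][idx, idx + d] = z
            zs[name][idx + d, idx] = z
    return ZScoreMap(
        layout=cm.layout,
        arms={name: (sl, zs[name]) for name, sl in arm_list},
        source_normalization=cm.normalization,
        min_separation=min_separation,
        min_band_pairs=min_band_pairs,
    )


@dataclass
class InteractionSet:
    """Called bin-pair interactions (i < j, intra-arm) with z-scores."""

    layout: GenomeLayout
    table: pd.DataFrame  # columns: arm, bin1, bin2, distance_bp, z
    condition: str = ""

    def __len__(self):
        return len(self.table)

    def pair_keys(self) -> set:
        return set(zip(self.table["bin1"], self.table["bin2"]))

    def to_bedpe(self, path=None) -> pd.DataFrame:
        bs = self.layout.binsize
        rows = []
        for _, r in self.table.iterrows():
            c1, s1 = self.layout.bin_start(int(r["bin1"]))
            c2, s2 = self.layout.bin_start(int(r["bin2"]))
            rows.append((c1, s1, s1 + bs, c2, s2, s2 + bs, float(r["z"])))
        df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1",
                                         "chrom2", "start2", "end2", "z"])
        if path is not None:
            df.to_csv(path, sep="\t", index=False, header=False)
        return df


def call_interactions(zmap: ZScoreMap, threshold: float = 2.0, condition: str = "") -> InteractionSet:
    """All unmasked intra-arm pairs with z strictly greater than ``threshold``."""
    rows = []
    bs = zmap.layout.binsize
    for name, (sl, z) in zmap.arms.items():
        iu, ju = np.triu_indices(z.shape[0], k=1)
        vals = z[iu, ju]
        hit = vals > threshold
        for i, j, v in zip(iu[hit], ju[hit], vals[hit]):
            rows.append((name, sl.start + int(i), sl.start + int(j), int(j - i) * bs, float(v)))
    table = pd.DataFrame(rows, columns=["arm", "bin1", "bin2", "distance_bp", "z"])
    return InteractionSet(zmap.layout, table, condition=condition)


def compare_sets(a: InteractionSet, b: InteractionSet) -> dict:
    """Partition two interaction sets by exact bin-pair identity.

    Returns counts and the bin-pair key sets under ``common``,
    ``a_specific`` and ``b_specific``.
    """
    if a.layout.binsize != b.layout.binsize or a.layout.chroms != b.layout.chroms:
        raise ValueError("interaction sets have different layouts/resolutions")
    ka, kb = a.pair_keys(), b.pair_keys()
    return {
        "common": ka & kb,
        "a_specific": ka - kb,
        "b_specific": kb - ka,
        "n_common": len(ka & kb),
        "n_a_specific": len(ka - kb),
        "n_b_specific": len(kb - ka),
    }


# ---------------------------------------------------------------------------
# aggregate (APA-style) matrices


def aggregate_matrix(
    cm: ContactMatrix,
    interactions: InteractionSet,
    half_window_bp: int = 8000,
    centered: bool = True,
) -> np.ndarray:
    """Mean normalised submatrix around called interactions.

    For each interaction (i, j) the (2w+1) x (2w+1) window centred on
    (i, j) with w = half_window_bp / binsize is extracted, divided by
    its own mean, and windows are averaged element-wise.  Windows
    truncated by arm edges are dropped; masked bins are excluded from
    the means, not zero-filled.  ``centered=False`` selects the even
    2w x 2w reading (rows/columns i-w .. i+w-1) instead.
    """
    w = half_window_bp // cm.binsize
    hi_off = w + 1 if centered else w
    arm_bounds = {name: (sl.start, sl.stop) for name, sl in cm.layout.arm_slices()}
    dense_cache: dict[str, np.ndarray] = {}
    acc = []
    for _, r in interactions.table.iterrows():
        name = r["arm"]
        lo, hi = arm_bounds[name]
        i, j = int(r["bin1"]), int(r["bin2"])
        if i - w < lo or j - w < lo or i + hi_off - 1 >= hi or j + hi_off - 1 >= hi:
            continue
        if name not in dense_cache:
            dense_cache[name] = cm.block(slice(lo, hi))
        blk = dense_cache[name]
        sub = blk[i - w - lo:i + hi_off - lo, j - w - lo:j + hi_off - lo]
        m = np.nanmean(sub)
        if not np.isfinite(m) or m == 0:
            continue
        acc.append(sub / m)
    if not acc:
        raise ValueError("no interaction windows fully inside arms")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.stack(acc), axis=0)


# ---------------------------------------------------------------------------
# insulation


def insulation_vectors(
    cm: ContactMatrix,
    vector_binsize: int = 10_000,
    offsets: tuple[int, ...] = tuple(range(10_000, 100_001, 10_000)),
) -> pd.DataFrame:
    """Aggregate a fine-binned map into 1D interaction vectors.

    For every coarse genomic position (``vector_binsize`` bins, default
    10 kb) and each offset o, the mean contact value between locus
    pairs separated by o whose midpoint falls in that coarse bin.
    Edge positions lacking full geometric support are NaN.  Returns a
    long-form frame with columns chrom, position (coarse-bin start) and
    one column per offset.
    """
    bs = cm.binsize
    for o in offsets:
        if o % bs:
            raise ValueError(f"offset {o} is not a multiple of the bin size {bs}")
    frames = []
    for ci, chrom in enumerate(cm.layout.chroms):
        off = cm.layout.chrom_offsets[ci]
        nb = cm.layout.n_bins_per_chrom[ci]
        block = cm.block(slice(int(off), int(off + nb)))
        n_coarse = int(cm.layout.lengths[ci] // vector_binsize)
        data = {"chrom": chrom, "position": np.arange(n_coarse) * vector_binsize}
        for o in offsets:
            ob = o // bs
            vals = np.diagonal(block, offset=ob)  # pairs (i, i+ob)
            i = np.arange(nb - ob)
            mid_bp = (i + ob / 2 + 0.5) * bs
            coarse = (mid_bp // vector_binsize).astype(int)
            col = np.full(n_coarse, np.nan)
            per_coarse = vector_binsize // bs
            for cbin in range(n_coarse):
                sel = coarse == cbin
                if sel.sum() < per_coarse:  # incomplete geometric support
                    continue
                v = vals[sel]
                v = v[~np.isnan(v)]
                if v.size:
                    col[cbin] = v.mean()
            data[f"offset_{o}"] = col
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def border_profile(
    vectors: pd.DataFrame,
    borders: pd.DataFrame,
    window_bp: int = 100_000,
    vector_binsize: int = 10_000,
) -> pd.DataFrame:
    """Mean log2 insulation profile across domain borders, per offset.

    Each border (BED-style frame with chrom/start/end; the border point
    is the interval midpoint) contributes a window of +/- ``window_bp``
    of each offset vector, normalised by the window mean and log2
    transformed; profiles are averaged across borders.  Rows indexed by
    position relative to the border.
    """
    w = window_bp // vector_binsize
    offset_cols = [c for c in vectors.columns if c.startswith("offset_")]
    rel = np.arange(-w, w + 1) * vector_binsize
    profiles = {c: [] for c in offset_cols}
    n_used = 0
    for _, b in borders.iterrows():
        chrom_vec = vectors[vectors["chrom"] == b["chrom"]].reset_index(drop=True)
        if chrom_vec.empty:
            continue
        point = (int(b["start"]) + int(b["end"])) // 2
        center = point // vector_binsize
        if center - w < 0 or center + w >= len(chrom_vec):
            continue
        used_any = False
        for c in offset_cols:
            win = chrom_vec[c].to_numpy()[center - w:center + w + 1]
            m = np.nanmean(win)
            if not np.isfinite(m) or m <= 0:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                profiles[c].append(np.log2(win / m))
            used_any = True
        n_used += used_any
    if n_used == 0:
        raise ValueError("no borders fall within the data")
    out = {"rel_position": rel}
    for c in offset_cols:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[c] = np.nanmean(np.stack(profiles[c]), axis=0)
    return pd.DataFrame(out)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


# ---------------------------------------------------------------------------
# virtual 4C and loess


def loess(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
    x_eval: np.ndarray | None = None,
) -> pd.DataFrame:
    """Locally weighted polynomial regression with tricube weights.

    At each evaluation point the nearest ``span`` fraction of the data
    is fit by weighted least squares of the given degree; the pointwise
    95% confidence band uses the normal approximation on the local
    linear smoother (variance sigma^2 * ||l(x0)||^2 with the residual
    variance estimated globally).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = x.size
    if n < degree + 2:
        raise ValueError("not enough points for loess")
    q = max(degree + 2, int(np.ceil(span * n)))
    q = min(q, n)
    if x_eval is None:
        x_eval = x
    fit = np.empty(x_eval.size)
    l2 = np.empty(x_eval.size)
    for k, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            dmax = 1.0
        wt = (1 - (d[idx] / dmax) ** 3) ** 3
        wt = np.clip(wt, 0, None)
        if wt.sum() == 0:
            wt[:] = 1.0
        X = np.vander((x[idx] - x0), degree + 1, increasing=True)
        W = np.sqrt(wt)
        beta, *_ = np.linalg.lstsq(X * W[:, None], y[idx] * W, rcond=None)
        fit[k] = beta[0]
        # equivalent-kernel weights for the intercept
        XtWX = X.T @ (wt[:, None] * X)
        try:
            e0 = np.linalg.solve(XtWX, np.eye(degree + 1)[:, 0])
        except np.linalg.LinAlgError:
            e0 = np.linalg.lstsq(XtWX, np.eye(degree + 1)[:, 0], rcond=None)[0]
        lvec = (wt * (X @ e0))
        l2[k] = np.sum(lvec**2)
    resid = y - np.interp(x, x_eval, fit) if x_eval is not x else y - fit
    dof = max(n - (degree + 1), 1)
    sigma2 = float(np.sum(resid**2) / dof)
    half = 1.96 * np.sqrt(sigma2 * l2)
    return pd.DataFrame({"x": x_eval, "fit": fit, "lo": fit - half, "hi": fit + half})


def virtual_4c(
    cm: ContactMatrix,
    chrom: str,
    viewpoint_bp: int,
    region: tuple[int, int] | None = None,
    span: float = 0.3,
) -> pd.DataFrame:
    """Viewpoint interaction profile (one matrix row) with loess smoothing.

    Returns position (bin midpoints, bp on ``chrom``), the raw row
    values, the smoothed curve and its pointwise 95% band.  The
    viewpoint bin must be unmasked.
    """
    ci = cm.layout.chroms.index(chrom)
    off = int(cm.layout.chrom_offsets[ci])
    nb = int(cm.layout.n_bins_per_chrom[ci])
    vbin = cm.layout.bin_of(chrom, viewpoint_bp)
    if cm.mask[vbin]:
        raise ValueError(f"viewpoint bin at {chrom}:{viewpoint_bp} is masked")
    if region is None:
        region = (0, cm.layout.lengths[ci])
    lo_bin = max(off + region[0] // cm.binsize, off)
    hi_bin = min(off + -(-region[1] // cm.binsize), off + nb)
    row = np.asarray(cm.matrix[vbin, lo_bin:hi_bin].todense()).ravel().astype(float)
    bins = np.arange(lo_bin, hi_bin)
    row[cm.mask[bins]] = np.nan
    pos = (bins - off + 0.5) * cm.binsize
    ok = ~np.isnan(row)
    sm = loess(pos[ok], row[ok], span=span)
    out = pd.DataFrame({"position": pos, "raw": row})
    return out.merge(sm.rename(columns={"x": "position", "fit": "smooth"}), on="position", how="left")


# ---------------------------------------------------------------------------
# median interaction distance


def median_interaction_distance(cm: ContactMatrix) -> pd.DataFrame:
    """Per-bin contact-weighted median intra-chromosomal interaction distance.

    For each genomic bin, the distribution of distances |j - i| *
    binsize to all unmasked intra-chromosomal partners, weighted by the
    contact value; the weighted median is reported (NaN where the bin
    has no contact weight).
    """
    bs = cm.binsize
    med = np.full(cm.layout.n_bins, np.nan)
    for ci in range(len(cm.layout.chroms)):
        off = int(cm.layout.chrom_offsets[ci])
        nb = int(cm.layout.n_bins_per_chrom[ci])
        block = cm.block(slice(off, off + nb))
        for i in range(nb):
            if cm.mask[off + i]:
                continue
            v = block[i].copy()
            v[i] = np.nan
            ok = ~np.isnan(v) & (v > 0)
            if not np.any(ok):
                continue
            dists = np.abs(np.arange(nb)[ok] - i) * bs
            med[off + i] = _weighted_median(dists, v[ok])
    chrom_idx = cm.layout.chrom_index()
    starts = [cm.layout.bin_start(g)[1] for g in range(cm.layout.n_bins)]
    return pd.DataFrame({
        "chrom": [cm.layout.chroms[c] for c in chrom_idx],
        "start": starts,
        "median_distance_bp": med,
    })


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    half = 0.5 * cum[-1]
    k = int(np.searchsorted(cum, half))
    if k < len(v) - 1 and np.isclose(cum[k], half):
        return 0.5 * (v[k] + v[k + 1])
    return float(v[k])


def subtract(cm_a: ContactMatrix, cm_b: ContactMatrix) -> ContactMatrix:
    """Element-wise difference map A - B (same layout and normalization)."""
    if cm_a.layout != cm_b.layout:
        raise ValueError("layouts differ")
    if cm_a.normalization != cm_b.normalization:
        raise ValueError("normalizations differ")
    diff = (cm_a.matrix - cm_b.matrix).tocsr()
    return ContactMatrix(cm_a.layout, diff, normalization=cm_a.normalization,
                         mask=cm_a.mask | cm_b.mask)
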