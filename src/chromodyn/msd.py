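"""Mean-squared-displacement statistics for locus trajectories.

Pipeline implemented here, in analysis order:

1. per-track time-averaged MSD  m_i(tau)  over all overlapping
   displacement pairs (:func:`msd_track`);
2. ensemble weighted mean  <m(tau)> = sum_i N_i m_i / sum_i N_i  with its
   *exact* standard error under that weighting (:func:`weighted_mean_msd`):

       sigma^2_<m> = (1/N) [ (1/N) sum_i N_i (m_i^2 + s_i^2) - <m>^2 ],

   where s_i^2 is the population variance of the individual squared
   displacements of track i at that delay and N = sum_i N_i.  This is
   the pooled population variance of all squared displacements divided
   by N;
3. per-track power-law fits  m_i(tau) = a tau^alpha  over a short-delay
   window, two-stage: a Nelder-Mead simplex start followed by a
   gradient-based least-squares refinement giving alpha_i +/- dalpha_i
   (:func:`fit_power_law`);
4. the 1/dalpha_i^2-weighted exponent density (histogram + Gaussian-kernel
   KDE, :func:`exponent_density`) and one- or two-Gaussian least-squares
   fits to the KDE curve (:func:`fit_gaussians`, :func:`select_model`);
5. the length of constraint L_c, the standard deviation of the locus
   position about its time-averaged position (:func:`length_of_constraint`).

Subdiffusion shows up as alpha < 1; an ideal Rouse-polymer monomer has
alpha = 0.5 and free diffusion alpha = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trajectories import Track, TrackSet

#: Default upper fit delay (s): beyond ~0.5 s measurement noise from
#: whole-nucleus motion dominates single-locus MSD curves.
DEFAULT_TAU_MAX = 0.5

#: Floor on dalpha for numerically perfect fits, keeping 1/dalpha^2 finite.
DALPHA_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# containers


@dataclass
class MSDCurve:
    """Per-track MSD: delays tau (s), m_i(tau) (um^2), the population
    variance s_i^2 of the individual squared displacements (um^4), and
    displacement counts N_i(tau)."""

    track_id: str
    delays: np.ndarray
    msd: np.ndarray
    var: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau": self.delays, "msd": self.msd, "var": self.var, "n": self.counts}
        ).assign(track_id=self.track_id)


@dataclass
class MeanMSD:
    """Ensemble weighted-mean MSD with exact standard error."""

    delays: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    counts: np.ndarray  # N(tau) = sum_i N_i(tau)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau": self.delays, "mean_msd": self.mean, "se": self.se, "n": self.counts}
        )


@dataclass
class ExponentFit:
    """Power-law fit m(tau) = a tau^alpha for one track."""

    track_id: str
    prefactor: float
    alpha: float
    dalpha: float
    tau_max: float
    converged: bool

    @property
    def weight(self) -> float:
        """Density weight 1/dalpha^2 (0 for non-converged fits)."""
        return 1.0 / self.dalpha**2 if self.converged else 0.0


@dataclass
class DensityModel:
    """Weighted density of fitted exponents and its Gaussian description.

    ``params`` is {} before fitting, {"mean","sd"} after a single-Gaussian
    fit, and {"w","mean1","sd1","mean2","sd2"} after a two-Gaussian fit
    (components ordered mean1 <= mean2; w is the weight of component 1).
    """

    grid: np.ndarray
    histogram: np.ndarray
    kde: np.ndarray
    bin_edges: np.ndarray
    n_components: int = 0
    params: dict = field(default_factory=dict)
    rss: float = np.nan

    @property
    def main_component(self) -> dict:
        """The component carrying the larger weight (two-Gaussian only)."""
        if self.n_components != 2:
            raise ValueError("main_component requires a two-Gaussian fit")
        p = self.params
        if p["w"] >= 0.5:
            return {"w": p["w"], "mean": p["mean1"], "sd": p["sd1"]}
        return {"w": 1 - p["w"], "mean": p["mean2"], "sd": p["sd2"]}


# ---------------------------------------------------------------------------
# MSD computation


def msd_track(track: Track, tau_max: float = DEFAULT_TAU_MAX) -> MSDCurve:
    """Time-averaged MSD of one track for delays k*dt <= tau_max.

    For each lag k the squared displacements |r(t+k dt) - r(t)|^2 over
    all n-k overlapping pairs are averaged; their population variance is
    kept for the exact ensemble standard error (0 when only one pair).
    """
    if tau_max < track.dt:
        raise ValueError(f"tau_max={tau_max} is below one frame interval dt={track.dt}")
    k_max = min(int(np.floor(tau_max / track.dt + 1e-9)), track.n_frames - 1)
    pos = track.positions
    lags = np.arange(1, k_max + 1)
    msd = np.empty(k_max)
    var = np.empty(k_max)
    counts = np.empty(k_max, dtype=int)
    for idx, k in enumerate(lags):
        sq = np.sum((pos[k:] - pos[:-k]) ** 2, axis=1)
        msd[idx] = sq.mean()
        var[idx] = sq.var() if sq.size > 1 else 0.0
        counts[idx] = sq.size
    return MSDCurve(track.id, lags * track.dt, msd, var, counts)


def msd_trackset(trackset: TrackSet, tau_max: float = DEFAULT_TAU_MAX) -> list[MSDCurve]:
    return [msd_track(t, tau_max) for t in trackset]


def weighted_mean_msd(curves: list[MSDCurve]) -> MeanMSD:
    """N_i-weighted ensemble mean MSD with the exact standard error.

    Longer tracks contribute more displacements and are weighted by
    N_i(tau).  The standard error follows from treating the pooled set
    of squared displacements as one sample:
    sigma^2 = (1/N)[(1/N) sum_i N_i (m_i^2 + s_i^2) - <m>^2].
    Curves are aligned on the intersection of their delay grids.
    """
    if not curves:
        raise ValueError("weighted_mean_msd needs at least one MSD curve")
    common = curves[0].delays
    for c in curves[1:]:
        common = common[np.isclose(common[:, None], c.delays[None, :], rtol=1e-9).any(axis=1)]
    if common.size == 0:
        raise ValueError("MSD curves share no delays")

    mean = np.empty(common.size)
    se = np.empty(common.size)
    ntot = np.empty(common.size, dtype=int)
    for j, tau in enumerate(common):
        m = np.array([c.msd[np.isclose(c.delays, tau, rtol=1e-9)][0] for c in curves])
        v = np.array([c.var[np.isclose(c.delays, tau, rtol=1e-9)][0] for c in curves])
        n = np.array([c.counts[np.isclose(c.delays, tau, rtol=1e-9)][0] for c in curves])
        N = n.sum()
        mbar = np.sum(n * m) / N
        sig2 = (np.sum(n * (m**2 + v)) / N - mbar**2) / N
        mean[j] = mbar
        se[j] = np.sqrt(max(sig2, 0.0))
        ntot[j] = N
    return MeanMSD(common, mean, se, ntot)


# ---------------------------------------------------------------------------
# power-law fits


def _power_law(tau, a, alpha):
    return a * np.power(tau, alpha)


def fit_power_law(
    curve: MSDCurve,
    tau_max: float = DEFAULT_TAU_MAX,
    tau_min: float = 0.0,
) -> ExponentFit:
    """Two-stage power-law fit of m(tau) = a tau^alpha on (tau_min, tau_max].

    Stage 1 is a robust Nelder-Mead simplex minimisation of the
    unweighted sum of squares; stage 2 refines with gradient-based
    nonlinear least squares, whose parameter covariance supplies
    dalpha.  tau = 0 never enters the objective.  Returns
    ``converged=False`` (weight 0 downstream) when both stages fail.
    """
    sel = (curve.delays > max(tau_min, 0)) & (curve.delays <= tau_max * (1 + 1e-9))
    tau = curve.delays[sel]
    m = curve.msd[sel]
    if tau.size < 3:
        raise ValueError(f"track {curve.track_id!r}: need >= 3 delays in (0, tau_max]")
    if np.all(m <= 0):
        return ExponentFit(curve.track_id, np.nan, np.nan, np.nan, tau_max, False)

    # log-log regression seed, robust scale-free start for the simplex
    pos = m > 0
    slope, intercept = np.polyfit(np.log(tau[pos]), np.log(m[pos]), 1) if pos.sum() >= 2 else (0.5, 0.0)
    x0 = np.array([np.exp(intercept), np.clip(slope, 0.01, 2.0)])

    def sse(p):
        a, alpha = p
        if a <= 0 or alpha <= 0 or alpha > 3:
            return np.inf
        return float(np.sum((m - _power_law(tau, a, alpha)) ** 2))

    nm = optimize.minimize(sse, x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    start = nm.x if np.isfinite(nm.fun) else x0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(_power_law, tau, m, p0=start, maxfev=10000)
        dalpha = float(np.sqrt(pcov[1, 1]))
        if not np.isfinite(dalpha):
            raise RuntimeError
        a_fit, alpha_fit = float(popt[0]), float(popt[1])
        converged = True
    except (RuntimeError, ValueError):
        if not nm.success:
            return ExponentFit(curve.track_id, np.nan, np.nan, np.nan, tau_max, False)
        a_fit, alpha_fit = float(start[0]), float(start[1])
        dalpha = np.nan
        converged = False
    dalpha = max(dalpha, DALPHA_FLOOR) if converged else dalpha
    return ExponentFit(curve.track_id, a_fit, alpha_fit, dalpha, tau_max, converged)


def fit_exponents(
    curves: list[MSDCurve],
    tau_max: float = DEFAULT_TAU_MAX,
    tau_min: float = 0.0,
    drop_nonconverged: bool = True,
) -> list[ExponentFit]:
    """Per-track power-law fits; non-converged fits optionally dropped."""
    fits = [fit_power_law(c, tau_max=tau_max, tau_min=tau_min) for c in curves]
    if drop_nonconverged:
        fits = [f for f in fits if f.converged]
    return fits


# ---------------------------------------------------------------------------
# exponent density and Gaussian description


def _weighted_silverman_bw(values, weights):
    w = weights / weights.sum()
    neff = 1.0 / np.sum(w**2)
    mu = np.sum(w * values)
    sd = np.sqrt(np.sum(w * (values - mu) ** 2))
    q75, q25 = _weighted_quantile(values, w, [0.75, 0.25])
    spread = min(sd, (q75 - q25) / 1.349) or sd or 1.0
    return 0.9 * spread * neff ** (-1 / 5)


def _weighted_quantile(values, w, qs):
    order = np.argsort(values)
    v, wt = values[order], w[order]
    cum = np.cumsum(wt) - 0.5 * wt
    cum /= wt.sum()
    return np.interp(qs, cum, v)


def exponent_density(
    fits: list[ExponentFit],
    grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    n_bins: int = 30,
) -> DensityModel:
    """Weighted histogram and Gaussian-kernel KDE of fitted exponents.

    Each track is weighted by 1/dalpha_i^2 so that precisely determined
    exponents dominate the density.  Both estimates are normalised to
    integrate to 1.  Bandwidth defaults to Silverman's rule on the
    weighted sample.
    """
    conv = [f for f in fits if f.converged and np.isfinite(f.weight) and f.weight > 0]
    if len(conv) < 10:
        raise ValueError(f"need >= 10 converged fits, got {len(conv)}")
    alphas = np.array([f.alpha for f in conv])
    weights = np.array([f.weight for f in conv])
    if not np.any(weights > 0):
        raise ValueError("all fit weights are zero or invalid")

    if bandwidth is None:
        bandwidth = _weighted_silverman_bw(alphas, weights)
    if grid is None:
        lo = alphas.min() - 4 * bandwidth
        hi = alphas.max() + 4 * bandwidth
        grid = np.linspace(lo, hi, 512)
    grid = np.asarray(grid, dtype=float)

    edges = np.linspace(alphas.min(), alphas.max(), n_bins + 1)
    hist, edges = np.histogram(alphas, bins=edges, weights=weights, density=True)

    wnorm = weights / weights.sum()
    wmu = np.sum(wnorm * alphas)
    wsd = np.sqrt(np.sum(wnorm * (alphas - wmu) ** 2))
    # scipy scales its kernel by the weighted sample sd; convert bandwidth
    kde = stats.gaussian_kde(alphas, bw_method=bandwidth / wsd, weights=weights)
    dens = kde(grid)
    return DensityModel(grid=grid, histogram=hist, kde=dens, bin_edges=edges)


def _gauss1(x, mu, sd):
    return np.exp(-((x - mu) ** 2) / (2 * sd**2)) / np.sqrt(2 * np.pi * sd**2)


def _gauss2(x, w, mu1, sd1, mu2, sd2):
    return w * _gauss1(x, mu1, sd1) + (1 - w) * _gauss1(x, mu2, sd2)


def fit_gaussians(model: DensityModel, n_components: int = 1) -> DensityModel:
    """Least-squares fit of one or two Gaussians to the KDE curve.

    The fit targets the smoothed density (the KDE values on the grid),
    not the raw exponent sample.  For two components the mixture weight
    w is constrained to [0, 1] and components are returned ordered
    mean1 <= mean2.
    """
    if model.kde is None or not np.any(model.kde > 0):
        raise ValueError("DensityModel has no KDE to fit")
    x, y = model.grid, model.kde
    mu0 = float(np.sum(x * y) / np.sum(y))
    sd0 = float(np.sqrt(np.sum((x - mu0) ** 2 * y) / np.sum(y)))
    sd0 = max(sd0, 1e-3)
    try:
        if n_components == 1:
            popt, _ = optimize.curve_fit(
                _gauss1, x, y, p0=[mu0, sd0],
                bounds=([x.min() - 1, 1e-4], [x.max() + 1, 10 * sd0]), maxfev=20000,
            )
            params = {"mean": float(popt[0]), "sd": float(popt[1])}
            resid = y - _gauss1(x, *popt)
        elif n_components == 2:
            peak = float(x[np.argmax(y)])
            # multi-start: symmetric split, dominant-peak + right shoulder,
            # dominant-peak + left shoulder, at two weight levels
            starts = [
                [0.7, mu0 - 0.7 * sd0, 0.7 * sd0, mu0 + 0.7 * sd0, 0.7 * sd0],
                [0.5, mu0 - sd0, 0.7 * sd0, mu0 + sd0, 0.7 * sd0],
                [0.9, peak, 0.6 * sd0, peak + 2 * sd0, 0.6 * sd0],
                [0.9, peak, 0.6 * sd0, peak - 2 * sd0, 0.6 * sd0],
                [0.75, peak, 0.5 * sd0, peak + 2.5 * sd0, 0.5 * sd0],
            ]
            bounds = ([0, x.min() - 1, 1e-4, x.min() - 1, 1e-4],
                      [1, x.max() + 1, 10 * sd0, x.max() + 1, 10 * sd0])
            best, best_rss = None, np.inf
            for p0 in starts:
                try:
                    cand, _ = optimize.curve_fit(_gauss2, x, y, p0=p0,
                                                 bounds=bounds, maxfev=40000)
                except RuntimeError:
                    continue
                rss = float(np.sum((y - _gauss2(x, *cand)) ** 2))
                if rss < best_rss:
                    best, best_rss = cand, rss
            if best is None:
                raise RuntimeError("all starts failed")
            popt = best
            w, mu1, sd1, mu2, sd2 = (float(v) for v in popt)
            if mu1 > mu2:
                w, mu1, sd1, mu2, sd2 = 1 - w, mu2, sd2, mu1, sd1
            params = {"w": w, "mean1": mu1, "sd1": sd1, "mean2": mu2, "sd2": sd2}
            resid = y - _gauss2(x, *popt)
        else:
            raise ValueError("n_components must be 1 or 2")
    except RuntimeError as exc:
        raise RuntimeError(
            f"{n_components}-Gaussian fit failed to converge (grid "
            f"[{x.min():.3g}, {x.max():.3g}], moment start mu={mu0:.3g}, sd={sd0:.3g})"
        ) from exc
    return DensityModel(
        grid=model.grid, histogram=model.histogram, kde=model.kde,
        bin_edges=model.bin_edges, n_components=n_components, params=params,
        rss=float(np.sum(resid**2)),
    )


def select_model(single: DensityModel, double: DensityModel, rho: float = 0.5) -> str:
    """Choose between the 1- and 2-Gaussian description of the density.

    Returns ``"double"`` iff the two-Gaussian fit reduces the residual
    sum of squares below ``rho`` times the single-Gaussian RSS *and* the
    component means are separated by more than the first component's sd
    (a separation sanity check); otherwise ``"single"``.
    """
    if single.n_components != 1 or double.n_components != 2:
        raise ValueError("pass a fitted single and a fitted double model")
    p = double.params
    separated = abs(p["mean2"] - p["mean1"]) > p["sd1"]
    improved = double.rss < rho * single.rss
    return "double" if (improved and separated) else "single"


def fit_mixture_em(
    fits: list[ExponentFit],
    n_components: int = 2,
    n_iter: int = 500,
    tol: float = 1e-10,
    seed: int = 0,
) -> dict:
    """Weighted EM Gaussian-mixture fit to the raw exponent sample.

    Alternative to the KDE-curve least squares (not the default
    pipeline): maximises the 1/dalpha^2-weighted log-likelihood.
    """
    conv = [f for f in fits if f.converged]
    x = np.array([f.alpha for f in conv])
    w = np.array([f.weight for f in conv])
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    qs = np.sort(rng.uniform(0.2, 0.8, n_components))
    mus = _weighted_quantile(x, w, qs)
    sds = np.full(n_components, x.std() / n_components)
    pis = np.full(n_components, 1 / n_components)
    for _ in range(n_iter):
        dens = np.array([pi * _gauss1(x, mu, sd) for pi, mu, sd in zip(pis, mus, sds)])
        dens_sum = dens.sum(axis=0)
        dens_sum[dens_sum == 0] = np.finfo(float).tiny
        resp = dens / dens_sum
        new_pis = np.array([np.sum(w * r) for r in resp])
        new_mus = np.array([np.sum(w * r * x) / max(p, 1e-300) for r, p in zip(resp, new_pis)])
        new_sds = np.array(
            [np.sqrt(np.sum(w * r * (x - mu) ** 2) / max(p, 1e-300))
             for r, mu, p in zip(resp, new_mus, new_pis)]
        )
        new_sds = np.maximum(new_sds, 1e-4)
        shift = np.max(np.abs(new_mus - mus))
        pis, mus, sds = new_pis, new_mus, new_sds
        if shift < tol:
            break
    order = np.argsort(mus)
    return {"weights": pis[order], "means": mus[order], "sds": sds[order]}


# ---------------------------------------------------------------------------
# length of constraint


def length_of_constraint(track: Track) -> float:
    """L_c: standard deviation of the locus position about its
    time-averaged position (um), the radius of the explored region.

    L_c = sqrt( (1/n) sum_t |r_t - rbar|^2 ), all coordinate dimensions
    summed; translation- and rotation-invariant.
    """
    pos = track.positions
    dev = pos - pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))


def lc_table(trackset: TrackSet) -> pd.DataFrame:
    return pd.DataFrame(
        {"track_id": [t.id for t in trackset],
         "lc_um": [length_of_constraint(t) for t in trackset]}
    )
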