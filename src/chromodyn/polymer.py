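"""Coarse-grained bead-spring chromosome-arm simulator.

A chromosome arm is a chain of beads (default 2436 beads of 25 nm
radius, one bead ~ 10 nucleosomes, approximating a 3.6 Mb arm).
Consecutive beads interact through linear elastic bonds; excluded
volume is a *constant-magnitude* repulsive force between any two
overlapping beads (beads may ingress, as a bead stands for a flexible
ten-nucleosome stretch, not a rigid body); the chain moves inside a
4.5 um confinement sphere, large enough to impose little constraint.
Dynamics are the overdamped Langevin equation integrated with the
Euler-Maruyama scheme:

    dr_i = (F_i / zeta) dt + sqrt(2 kT dt / zeta) * xi,   xi ~ N(0, I).

Time is expressed in simulation units (kT = zeta = 1 by default);
MSD *exponents*, not time scales, are the quantity of interest.
Mid-chain bead trajectories are exported as a 3D :class:`TrackSet`
and feed the msd module unchanged; :func:`project_to_plane` mimics 2D
microscope acquisition by orthogonal projection onto a random plane.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml
from numba import njit

from .trajectories import Track, TrackSet

__all__ = ["SimConfig", "ChainState", "initialize_chain", "run_simulation",
           "project_to_plane", "write_xyz"]


def write_xyz(positions: np.ndarray, path, comment: str = "bead-spring chain") -> None:
    """Dump a conformation (n_beads, 3) in XYZ format for visualization."""
    pos = np.asarray(positions)
    with open(path, "w") as fh:
        fh.write(f"{pos.shape[0]}\n{comment}\n")
        for x, y, z in pos:
            fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")


@dataclass(frozen=True)
class SimConfig:
    """All simulator parameters (lengths um, energies kT, time in
    simulation units with friction 1).

    Defaults follow the full-scale chain (2436 beads); the documented
    parameter choices not fixed by the physical picture are: bond rest
    length = bead diameter (50 nm); bond stiffness such that the bond
    length sd is ~10% of the rest length (kT / (0.1 b)^2); repulsion
    force such that the thermally sampled overlap depth kT/F is ~20% of
    the bead radius; time step such that the RMS free step is <= 2 nm.
    """

    n_beads: int = 2436
    bead_radius: float = 0.025          # um
    nucleosomes_per_bead: int = 10      # bookkeeping only
    confinement_radius: float = 4.5     # um
    bond_rest_length: float = 0.05      # um (bead diameter)
    bond_stiffness: float = 4.0e4       # kT / um^2  -> bond sd ~ 5 nm
    repulsion_force: float = 200.0      # kT / um    -> overlap depth ~ 5 nm
    confinement_force: float = 50.0     # kT / um, constant inward when outside
    friction: float = 1.0               # zeta
    thermal_energy: float = 1.0         # kT
    time_step: float = 5e-7
    n_steps: int = 2_000_000
    equilibration_steps: int = 100_000
    sampling_stride: int = 2000
    excluded_volume: bool = True
    confinement: bool = True
    confinement_reflecting: bool = False
    tracked_fraction: tuple[float, float] = (0.25, 0.75)
    seed: int = 0

    def __post_init__(self):
        if self.n_beads < 2:
            raise ValueError("need at least 2 beads")
        for name in ("bead_radius", "confinement_radius", "bond_rest_length", "time_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sampling_stride < 1:
            raise ValueError("sampling_stride must be >= 1")

    @property
    def diffusion_coefficient(self) -> float:
        """Single-bead free diffusion coefficient D = kT / zeta."""
        return self.thermal_energy / self.friction

    @property
    def sampling_interval(self) -> float:
        return self.sampling_stride * self.time_step

    def fit_window(self) -> tuple[float, float]:
        """Default intermediate-time fit window: one decade starting at
        10x the sampling interval (terminal plateau excluded by the run
        length)."""
        lo = 10 * self.sampling_interval
        return (lo, 10 * lo)

    @classmethod
    def reduced(cls, **overrides) -> "SimConfig":
        """Reduced-scale chain (500 beads) used for desk-scale runs; the
        full 2436-bead configuration is the plain constructor."""
        kw = dict(n_beads=500)
        kw.update(overrides)
        return cls(**kw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["tracked_fraction"] = list(self.tracked_fraction)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.update(overrides)
        if "tracked_fraction" in d:
            d["tracked_fraction"] = tuple(d["tracked_fraction"])
        return cls(**d)


@dataclass
class ChainState:
    """Bead positions (um) plus the step index and RNG provenance tag."""

    positions: np.ndarray  # (n_beads, 3)
    step: int = 0
    rng_tag: str = ""


def initialize_chain(config: SimConfig, rng: np.random.Generator | None = None) -> ChainState:
    """Self-avoiding-biased random walk inside the confinement sphere.

    Steps have length ``bond_rest_length``; each proposed step is
    rejected (up to a retry budget) when it leaves the sphere or comes
    closer than 1.4x the bead radius to any of the preceding 20 beads.
    Deterministic for a given seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    r_max = config.confinement_radius - config.bead_radius
    if r_max <= config.bond_rest_length:
        raise ValueError("confinement sphere too small to place the chain")
    pos = np.empty((config.n_beads, 3))
    pos[0] = rng.normal(size=3)
    pos[0] *= (0.25 * r_max * rng.random() ** (1 / 3)) / np.linalg.norm(pos[0])
    avoid2 = (1.4 * config.bead_radius) ** 2
    for i in range(1, config.n_beads):
        placed = False
        for _ in range(200):
            step = rng.normal(size=3)
            step *= config.bond_rest_length / np.linalg.norm(step)
            cand = pos[i - 1] + step
            if np.dot(cand, cand) > r_max**2:
                continue
            recent = pos[max(0, i - 21):i - 1]
            if recent.size and np.min(np.sum((recent - cand) ** 2, axis=1)) < avoid2:
                continue
            pos[i] = cand
            placed = True
            break
        if not placed:
            # fall back to any in-sphere step (dense regions near the wall)
            step = rng.normal(size=3)
            step *= config.bond_rest_length / np.linalg.norm(step)
            cand = pos[i - 1] + step
            if np.dot(cand, cand) > r_max**2:
                cand = pos[i - 1] - step
            if np.dot(cand, cand) > r_max**2:
                raise ValueError("cannot place chain inside the confinement sphere")
            pos[i] = cand
    return ChainState(positions=pos, step=0, rng_tag=f"seed={config.seed}")


@njit(cache=True)
def _integrate(pos, n_steps, dt, mobility, noise_sd, k_bond, b0, f_rep, r_cut2,
               ev_on, conf_on, reflecting, r_conf, f_conf, stride, record,
               max_step, seed):  # pragma: no cover - exercised via run_simulation
    np.random.seed(seed)
    n = pos.shape[0]
    frame = 0
    forces = np.zeros((n, 3))
    for step in range(n_steps):
        forces[:] = 0.0
        # harmonic bonds
        for i in range(n - 1):
            dx = pos[i + 1, 0] - pos[i, 0]
            dy = pos[i + 1, 1] - pos[i, 1]
            dz = pos[i + 1, 2] - pos[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 1e-12:
                f = k_bond * (r - b0) / r
                forces[i, 0] += f * dx
                forces[i, 1] += f * dy
                forces[i, 2] += f * dz
                forces[i + 1, 0] -= f * dx
                forces[i + 1, 1] -= f * dy
                forces[i + 1, 2] -= f * dz
        # constant-force repulsion between overlapping beads
        if ev_on:
            for i in range(n):
                xi_ = pos[i, 0]
                yi_ = pos[i, 1]
                zi_ = pos[i, 2]
                for j in range(i + 1, n):
                    dx = pos[j, 0] - xi_
                    if dx * dx > r_cut2:
                        continue
                    dy = pos[j, 1] - yi_
                    dz = pos[j, 2] - zi_
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 < r_cut2 and d2 > 1e-20:
                        inv = f_rep / np.sqrt(d2)
                        forces[i, 0] -= inv * dx
                        forces[i, 1] -= inv * dy
                        forces[i, 2] -= inv * dz
                        forces[j, 0] += inv * dx
                        forces[j, 1] += inv * dy
                        forces[j, 2] += inv * dz
        # confinement: constant inward radial force outside the sphere
        if conf_on and not reflecting:
            for i in range(n):
                rr = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
                if rr > r_conf:
                    f = f_conf / rr
                    forces[i, 0] -= f * pos[i, 0]
                    forces[i, 1] -= f * pos[i, 1]
                    forces[i, 2] -= f * pos[i, 2]
        # Euler-Maruyama update
        for i in range(n):
            for c in range(3):
                d = forces[i, c] * mobility * dt + noise_sd * np.random.normal()
                if d > max_step or d < -max_step:
                    return step  # numerical blow-up
                pos[i, c] += d
        if conf_on and reflecting:
            for i in range(n):
                rr = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
                if rr > r_conf:
                    scale = (2 * r_conf - rr) / rr
                    pos[i, 0] *= scale
                    pos[i, 1] *= scale
                    pos[i, 2] *= scale
        if (step + 1) % stride == 0 and frame < record.shape[0]:
            record[frame] = pos
            frame += 1
    return -1


def run_simulation(
    config: SimConfig,
    state: ChainState | None = None,
    return_all_beads: bool = False,
) -> TrackSet:
    """Run the overdamped Langevin dynamics and export bead tracks.

    After ``equilibration_steps`` unrecorded steps, positions are
    recorded every ``sampling_stride`` steps for ``n_steps`` steps.
    Interior beads (the ``tracked_fraction`` span of the chain, default
    the middle 50%) are exported as 3D tracks with dt equal to the
    sampling interval; chain-end beads relax differently and are
    excluded by default.

    Raises ``RuntimeError`` when any per-step displacement exceeds the
    bead radius, which signals a too-large time step.
    """
    if state is None:
        state = initialize_chain(config)
    pos = np.ascontiguousarray(state.positions, dtype=np.float64).copy()
    cfg = config
    noise_sd = np.sqrt(2 * cfg.diffusion_coefficient * cfg.time_step)
    mobility = 1.0 / cfg.friction
    # equilibration: same dynamics, nothing recorded
    dummy = np.empty((0, cfg.n_beads, 3))
    seed_eq = (cfg.seed * 7919 + 1) % 2**31
    bad = _integrate(pos, cfg.equilibration_steps, cfg.time_step, mobility, noise_sd,
                     cfg.bond_stiffness, cfg.bond_rest_length, cfg.repulsion_force,
                     (2 * cfg.bead_radius) ** 2, cfg.excluded_volume, cfg.confinement,
                     cfg.confinement_reflecting, cfg.confinement_radius,
                     cfg.confinement_force, cfg.sampling_stride, dummy,
                     cfg.bead_radius, seed_eq)
    if bad >= 0:
        raise RuntimeError(
            f"displacement exceeded the bead radius at equilibration step {bad}; "
            "reduce the time step")
    n_frames = cfg.n_steps // cfg.sampling_stride
    record = np.empty((n_frames, cfg.n_beads, 3))
    seed_run = (cfg.seed * 7919 + 2) % 2**31
    bad = _integrate(pos, cfg.n_steps, cfg.time_step, mobility, noise_sd,
                     cfg.bond_stiffness, cfg.bond_rest_length, cfg.repulsion_force,
                     (2 * cfg.bead_radius) ** 2, cfg.excluded_volume, cfg.confinement,
                     cfg.confinement_reflecting, cfg.confinement_radius,
                     cfg.confinement_force, cfg.sampling_stride, record,
                     cfg.bead_radius, seed_run)
    if bad >= 0:
        raise RuntimeError(
            f"displacement exceeded the bead radius at step {bad}; reduce the time step")

    if return_all_beads:
        beads = np.arange(cfg.n_beads)
    else:
        lo = int(np.floor(cfg.tracked_fraction[0] * cfg.n_beads))
        hi = int(np.ceil(cfg.tracked_fraction[1] * cfg.n_beads))
        beads = np.arange(lo, hi)
    tracks = [
        Track(id=f"bead-{b:04d}", dt=cfg.sampling_interval, positions=record[:, b, :])
        for b in beads
    ]
    return TrackSet(tracks, condition="simulation",
                    metadata={"excluded_volume": cfg.excluded_volume, "seed": cfg.seed})


def project_to_plane(
    tracks3d: TrackSet, seed: int = 0, normal: np.ndarray | None = None
) -> TrackSet:
    """Orthogonal projection of 3D tracks onto a uniformly random plane.

    One plane (normal uniform on the sphere, fixed by ``seed``) is drawn
    per call and applied to every track, mimicking single-plane 2D image
    acquisition of a 3D process; output coordinates are in the plane's
    orthonormal basis.  An explicit plane ``normal`` overrides the draw.
    """
    if tracks3d.ndim != 3:
        raise ValueError("project_to_plane expects 3D tracks")
    if normal is None:
        rng = np.random.default_rng(seed)
        normal = rng.standard_normal(3)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    # orthonormal in-plane basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    basis = np.stack([e1, e2], axis=1)  # (3, 2)
    out = [Track(id=t.id, dt=t.dt, positions=t.positions @ basis) for t in tracks3d]
    return TrackSet(out, condition=tracks3d.condition + "+2D",
                    metadata=dict(tracks3d.metadata, projection_seed=seed))
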