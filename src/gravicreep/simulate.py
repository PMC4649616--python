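"""Brownian-dynamics simulation of sedimenting, coalescing nuclear bodies.

Particles live in a 2-D (x, z) square box with reflecting walls.  Each
carries a 3-D volume: collision geometry is a disk of radius
``R = (3V / 4 pi)^(1/3)``, while buoyant weight and Stokes drag use the same
R, which is the only reading that keeps the 2-D dynamics, the volumetric
fusion rule and Stokes' law mutually consistent.  Per step the overdamped
Langevin update is

    dx = xi_x
    dz = -(V drho g_mult g0 / zeta) dt + xi_z,   zeta = 6 pi eta1 R

with xi drawn i.i.d. Gaussian, zero mean, variance 2 (kB T / zeta) dt per
axis.  Only the long-time network viscosity eta1 enters the drag: on the
timescales simulated the Kelvin-Voigt retardation has fully relaxed, so the
network acts as a viscous fluid.  Bodies that collide fuse into one body of
combined volume at the volume-weighted centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .rheology import G0_SI, kbt_at, stokes_drag
from .spatial import volume_to_radius

__all__ = [
    "SimConfig",
    "SimState",
    "SedimentationSummary",
    "sample_powerlaw_volumes",
    "init_state",
    "recommended_timestep",
    "step",
    "resolve_fusions",
    "run",
    "time_to_displacement",
]

#: (kg/m^3 * m/s^2 * um^3) -> pN
_WEIGHT_TO_PN = 1e-6


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (um / s / pN / Pa internal units).

    Defaults describe the giant-nucleus setting: a 400-um box (nucleus
    diameter), 1000 bodies with power-law volumes of exponent -1.5, drag
    from the measured long-time network viscosity (~2 Pa*s), a 50 kg/m^3
    body-nucleoplasm density mismatch, and thermal noise at 298 K.
    """

    box_side: float = 400.0  # um
    n_particles: int = 1000
    eta1: float = 2.0  # Pa*s, long-time network viscosity
    delta_rho: float = 50.0  # kg/m^3
    g_multiple: float = 1.0
    temperature: float = 298.0  # K
    dt: float | None = None  # s; None -> recommended_timestep
    t_end: float = 3600.0  # s
    v_min: float = 1.0  # um^3
    v_max: float = 4000.0  # um^3
    exponent: float = -1.5
    seed: int = 0
    enable_fusion: bool = True
    n_samples: int = 50
    record_snapshots: bool = False

    def __post_init__(self) -> None:
        if self.box_side <= 0 or self.t_end <= 0:
            raise ValueError("box_side and t_end must be positive")
        if not (0 < self.v_min < self.v_max):
            raise ValueError("need 0 < v_min < v_max")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive when given")
        if self.eta1 <= 0 or self.delta_rho < 0 or self.g_multiple < 0:
            raise ValueError("eta1 must be positive; delta_rho, g_multiple >= 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass
class SimState:
    """Mutable particle state: (x, z) positions, volumes, time and RNG."""

    positions: np.ndarray  # (n, 2) um, columns x and z
    volumes: np.ndarray  # (n,) um^3
    time: float
    rng: np.random.Generator

    @property
    def radii(self) -> np.ndarray:
        return volume_to_radius(self.volumes)

    @property
    def n_particles(self) -> int:
        return self.volumes.size


@dataclass(frozen=True)
class SedimentationSummary:
    """Recorded observables of one run."""

    sample_times: np.ndarray  # s
    delta_z: np.ndarray  # um, downward shift of the volume-weighted mean z vs t=0
    r_median: np.ndarray  # um, per sample
    particle_count: np.ndarray  # per sample
    config: SimConfig
    snapshots: list = field(default_factory=list)  # (positions, volumes) copies


def sample_powerlaw_volumes(
    n: int, exponent: float, v_min: float, v_max: float, seed
) -> np.ndarray:
    """Draw i.i.d. volumes from a truncated power law p(V) ~ V^exponent by
    inverse-CDF sampling.  ``seed`` may be an int or a Generator."""
    if not (0 < v_min < v_max):
        raise ValueError("need 0 < v_min < v_max")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    a1 = exponent + 1.0
    if abs(a1) < 1e-12:
        return v_min * (v_max / v_min) ** u
    return (v_min**a1 + u * (v_max**a1 - v_min**a1)) ** (1.0 / a1)


def init_state(config: SimConfig) -> SimState:
    """Place particles uniformly at random (respecting wall clearance) and
    fuse any initial overlaps, at time 0."""
    rng = np.random.default_rng(config.seed)
    vols = sample_powerlaw_volumes(
        config.n_particles, config.exponent, config.v_min, config.v_max, rng
    )
    radii = volume_to_radius(vols)
    if np.sum(np.pi * radii**2) > 0.8 * config.box_side**2:
        raise ValueError("particle area exceeds 80% of the box; packing infeasible")
    if 2.0 * radii.max() > config.box_side:
        raise ValueError("largest particle does not fit in the box")
    lo = radii[:, None]
    hi = config.box_side - radii[:, None]
    pos = lo + rng.random((config.n_particles, 2)) * (hi - lo)
    state = SimState(positions=pos, volumes=vols, time=0.0, rng=rng)
    if config.enable_fusion:
        state = resolve_fusions(state, config.box_side)
    return state


def _max_step_dt(radius: float, config: SimConfig, safety: float = 0.5) -> float:
    """Largest dt for which drift + 3 sigma Brownian motion of a particle of
    this radius stays below ``safety`` times its own diameter."""
    zeta = stokes_drag(radius, config.eta1)
    vol = (4.0 / 3.0) * np.pi * radius**3
    drift = vol * config.delta_rho * config.g_multiple * G0_SI * _WEIGHT_TO_PN / zeta
    diff = kbt_at(config.temperature) / zeta  # um^2/s
    target = safety * 2.0 * radius
    a, b = drift, 3.0 * np.sqrt(2.0 * diff)
    if a == 0 and b == 0:
        return np.inf
    if a == 0:
        return (target / b) ** 2
    s = (-b + np.sqrt(b**2 + 4.0 * a * target)) / (2.0 * a)
    return s**2


def recommended_timestep(config: SimConfig) -> float:
    """Timestep keeping per-step displacement below a particle diameter.

    Evaluated at both volume bounds (the smallest particle is
    diffusion-limited, the largest drift-limited) with a 0.5 safety factor,
    and capped at t_end.
    """
    dt = min(
        _max_step_dt(float(volume_to_radius(config.v_min)), config),
        _max_step_dt(float(volume_to_radius(config.v_max)), config),
        config.t_end,
    )
    return float(dt)


def step(state: SimState, config: SimConfig, dt: float) -> SimState:
    """One Langevin step: gravitational drift (-z), Brownian kicks,
    reflecting walls on particle centres, then fusion resolution."""
    radii = state.radii
    zeta = 6.0 * np.pi * config.eta1 * radii
    drift = (
        state.volumes * config.delta_rho * config.g_multiple * G0_SI * _WEIGHT_TO_PN / zeta
    )
    diff = kbt_at(config.temperature) / zeta
    sd = np.sqrt(2.0 * diff * dt)
    kicks = state.rng.normal(size=(state.n_particles, 2)) * sd[:, None]
    pos = state.positions + kicks
    pos[:, 1] -= drift * dt
    if not np.all(np.isfinite(pos)):
        raise RuntimeError("non-finite positions produced; reduce dt")
    _reflect(pos, radii, config.box_side)
    state.positions = pos
    state.time += dt
    if config.enable_fusion:
        state = resolve_fusions(state, config.box_side)
    return state


def _reflect(pos: np.ndarray, radii: np.ndarray, box_side: float) -> None:
    """Reflect particle centres into [R, L - R] per axis, in place."""
    lo = radii[:, None]
    hi = box_side - radii[:, None]
    width = hi - lo
    # fold into [lo, hi] (handles multiple reflections in one step)
    y = np.abs(np.mod(pos - lo, 2.0 * width))
    pos[:] = lo + np.where(y > width, 2.0 * width - y, y)


def resolve_fusions(state: SimState, box_side: float) -> SimState:
    """Merge every overlapping pair until none remain.

    Overlap = centre distance < R_i + R_j.  Pairs are merged in ascending
    distance order (deterministic tie-break); the merged body takes the
    combined volume and the volume-weighted centroid, re-clamped to wall
    clearance.  Iterated to a fixpoint so chains collapse fully.
    """
    pos, vols = state.positions, state.volumes
    while True:
        radii = volume_to_radius(vols)
        if vols.size < 2:
            break
        tree = cKDTree(pos)
        pairs = tree.query_pairs(2.0 * radii.max(), output_type="ndarray")
        if pairs.size == 0:
            break
        d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
        overlap = d < radii[pairs[:, 0]] + radii[pairs[:, 1]]
        if not np.any(overlap):
            break
        pairs, d = pairs[overlap], d[overlap]
        order = np.argsort(d, kind="stable")
        consumed = np.zeros(vols.size, dtype=bool)
        new_pos, new_vol = [], []
        for i, j in pairs[order]:
            if consumed[i] or consumed[j]:
                continue
            consumed[i] = consumed[j] = True
            v = vols[i] + vols[j]
            c = (vols[i] * pos[i] + vols[j] * pos[j]) / v
            r = float(volume_to_radius(v))
            c = np.clip(c, r, box_side - r)
            new_pos.append(c)
            new_vol.append(v)
        keep = ~consumed
        pos = np.vstack([pos[keep]] + [np.asarray(new_pos)])
        vols = np.concatenate([vols[keep], np.asarray(new_vol)])
    state.positions = pos
    state.volumes = vols
    return state


def _mass_mean_z(state: SimState) -> float:
    """Volume-weighted mean z: exactly invariant under fusion events (the
    merged body sits at the volume-weighted centroid), so it tracks net
    downward mass transport without coalescence artefacts."""
    return float(np.average(state.positions[:, 1], weights=state.volumes))


def run(config: SimConfig) -> SedimentationSummary:
    """Integrate to t_end, recording the downward shift of the
    volume-weighted mean body position, the median radius and the particle
    count at ~n_samples equally spaced times.  Deterministic given the
    config seed."""
    state = init_state(config)
    dt = config.dt if config.dt is not None else recommended_timestep(config)
    dt = min(dt, config.t_end)
    z0 = _mass_mean_z(state)

    sample_times = np.linspace(0.0, config.t_end, config.n_samples + 1)
    times, dzs, rmeds, counts, snaps = [], [], [], [], []

    def record():
        times.append(state.time)
        dzs.append(z0 - _mass_mean_z(state))
        rmeds.append(float(np.median(state.radii)))
        counts.append(state.n_particles)
        if config.record_snapshots:
            snaps.append((state.positions.copy(), state.volumes.copy()))

    record()
    next_sample = 1
    n_steps = int(np.ceil(config.t_end / dt))
    for k in range(1, n_steps + 1):
        this_dt = min(dt, config.t_end - (k - 1) * dt)
        if this_dt <= 0:
            break
        state = step(state, config, this_dt)
        while next_sample <= config.n_samples and state.time >= sample_times[next_sample] - 1e-9:
            record()
            next_sample += 1
    if times[-1] < config.t_end - 1e-9:
        record()
    return SedimentationSummary(
        sample_times=np.asarray(times),
        delta_z=np.asarray(dzs),
        r_median=np.asarray(rmeds),
        particle_count=np.asarray(counts),
        config=config,
        snapshots=snaps,
    )


def time_to_displacement(
    summary: SedimentationSummary, threshold: float = 200.0
) -> float | None:
    """First time the mean downward displacement crosses ``threshold`` um,
    by linear interpolation between samples; None if never crossed.

    200 um -- the nucleus radius -- marks severe disruption of nuclear
    organisation."""
    t, d = summary.sample_times, summary.delta_z
    above = np.nonzero(d >= threshold)[0]
    if above.size == 0:
        return None
    i = above[0]
    if i == 0:
        return float(t[0])
    f = (threshold - d[i - 1]) / (d[i] - d[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))
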