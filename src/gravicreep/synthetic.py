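"""Seeded generators for every input the analysis pipeline consumes.

Each generator draws from the physical model itself (linear viscoelastic
response for bead trajectories, Stokes creep for centrifugation cohorts,
tilted uniform sampling inside an ellipsoid for nuclear-body clouds) and
returns the generating ground truth alongside the data, so estimator
round-trips can be tested quantitatively.

What the generators emulate -- and what they do not: trajectories are exact
single-mode linear responses plus additive Gaussian noise (no tracking
artefacts, no force-calibration error); clouds place independent bodies (no
excluded volume, no correlation between size and depth); cohorts displace
every nucleus by the same mean Stokes creep (no nucleus-to-nucleus radius
variation unless asked for).  Passing round-trips therefore validate the
estimators, not the microscopy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .microrheology import BEAD_RADIUS_DEFAULT, BeadTrajectory
from .rheology import G0_SI, ViscoelasticParams, complex_moduli, creep_compliance
from .simulate import sample_powerlaw_volumes
from .spatial import (
    DELTA_RHO_DEFAULT,
    NucleolusCloud,
    NucleusGeometry,
    SedimentationSeries,
    align_gravity_axis,
    fit_ellipsoid,
    normalize_to_sphere,
    radius_to_volume,
    volume_to_radius,
)

__all__ = [
    "SyntheticTrajectory",
    "SyntheticCloud",
    "SyntheticCohort",
    "synth_oscillatory_trajectory",
    "synth_creep_trajectory",
    "synth_nucleolus_cloud",
    "synth_cohort",
    "synth_intensity_profile",
    "NUCLEUS_SEMI_AXES_DEFAULT",
]

#: default nucleus semi-axes, um (a ~400-um germinal vesicle, mildly prolate)
NUCLEUS_SEMI_AXES_DEFAULT = (220.0, 200.0, 180.0)

#: scaled force-time -> Pa*um conversion (matches spatial._U_TO_PA_UM)
_U_TO_PA_UM = 1e-6


@dataclass(frozen=True)
class SyntheticTrajectory:
    trajectory: BeadTrajectory
    truth: dict
    seed: int


@dataclass(frozen=True)
class SyntheticCloud:
    cloud: NucleolusCloud
    geometry: NucleusGeometry
    truth: dict
    seed: int


@dataclass(frozen=True)
class SyntheticCohort:
    series: list  # of SedimentationSeries
    clouds: dict = field(default_factory=dict)  # (g, t) -> list[NucleolusCloud]
    reference_mean_z: float = 0.0
    truth: dict = field(default_factory=dict)
    seed: int = 0


def synth_oscillatory_trajectory(
    params: ViscoelasticParams,
    frequency_hz: float = 0.1,
    F0: float = 1.0,
    bead_radius: float = BEAD_RADIUS_DEFAULT,
    n_periods: int = 5,
    points_per_period: int = 40,
    noise_sd: float = 0.0,
    offset: float = 0.0,
    drift: float = 0.0,
    seed: int = 0,
) -> SyntheticTrajectory:
    """Sinusoidal-force bead response of the extended Kelvin-Voigt medium.

    The amplitude and phase follow from the complex modulus:
    x0 = F0 / (6 pi R |G*|), delta = atan2(G'', G').  Additive Gaussian
    noise has standard deviation ``noise_sd * x0``.  Defaults stay inside
    the experimental envelope (0.02-1 Hz drive, 0.2-1.75 pN forces).
    """
    if F0 <= 0:
        raise ValueError(f"F0 must be positive, got {F0}")
    omega = 2.0 * np.pi * frequency_hz
    gs, gl = complex_moduli(omega, params)
    g_mag = float(np.hypot(gs, gl))
    delta = float(np.arctan2(gl, gs))
    x0 = F0 / (6.0 * np.pi * bead_radius * g_mag)
    rng = np.random.default_rng(seed)
    n = max(n_periods * points_per_period, 10)
    t = np.arange(n) * (1.0 / (frequency_hz * points_per_period))
    force = F0 * np.sin(omega * t)
    x = offset + drift * t + x0 * np.sin(omega * t - delta)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd * x0, size=n)
    traj = BeadTrajectory(times=t, displacement=x, force=force, bead_radius=bead_radius)
    truth = {
        "params": params,
        "x0_um": x0,
        "delta_rad": delta,
        "F0_pN": F0,
        "omega_rad_s": omega,
        "G_storage_Pa": gs,
        "G_loss_Pa": gl,
        "offset_um": offset,
        "drift_um_s": drift,
        "noise_sd": noise_sd,
    }
    return SyntheticTrajectory(trajectory=traj, truth=truth, seed=seed)


def synth_creep_trajectory(
    params: ViscoelasticParams,
    F0: float = 1.4,
    bead_radius: float = BEAD_RADIUS_DEFAULT,
    duration: float | None = None,
    dt: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticTrajectory:
    """Step-force creep response x(t) = F0 J(t) / (6 pi R).

    The default window covers five retardation times plus a linear-flow
    tail of at least ten retardation times (or 30 s, whichever is larger),
    so both E/eta2 and eta1 are identifiable.  Noise sd is
    ``noise_sd * max(x)``.
    """
    if F0 <= 0:
        raise ValueError(f"F0 must be positive, got {F0}")
    tau = params.retardation_time
    if duration is None:
        duration = max(15.0 * tau, 30.0)
    t = np.arange(0.0, duration + dt / 2, dt)
    x = F0 * creep_compliance(t, params) / (6.0 * np.pi * bead_radius)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd * x.max(), size=t.size)
    traj = BeadTrajectory(
        times=t, displacement=x, force=np.full_like(t, F0), bead_radius=bead_radius
    )
    truth = {"params": params, "F0_pN": F0, "noise_sd": noise_sd}
    return SyntheticTrajectory(trajectory=traj, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# clouds


def _tilt_mean_offset(lam: float, r: float) -> float:
    """Mean z (relative to centre) of density ~ A(z) exp(-(z+r)/lam) inside a
    sphere of radius r, with slice area A(z) = pi (r^2 - z^2)."""
    w = lambda z: (r**2 - z**2) * np.exp(-(z + r) / lam)
    num, _ = integrate.quad(lambda z: z * w(z), -r, r)
    den, _ = integrate.quad(w, -r, r)
    return num / den


def _solve_tilt(z0: float, r: float) -> float:
    """Decay length lam such that the expected mean-z offset equals -z0."""
    if z0 <= 0:
        return np.inf
    f = lambda lam: _tilt_mean_offset(lam, r) + z0
    lo, hi = 1e-3 * r, 1e3 * r
    if f(hi) < 0:  # even near-uniform density overshoots: z0 too small to need tilt
        return hi
    return optimize.brentq(f, lo, hi, xtol=1e-6 * r)


def synth_nucleolus_cloud(
    n_bodies: int = 500,
    semi_axes: tuple = NUCLEUS_SEMI_AXES_DEFAULT,
    center: tuple = (0.0, 0.0, 0.0),
    target_z0: float = 50.0,
    exponent: float = -1.5,
    r_min: float = 0.5,
    r_max: float = 10.0,
    plane_step: float = 2.0,
    seed: int = 0,
) -> SyntheticCloud:
    """Nuclear-body cloud inside an axis-aligned ellipsoidal nucleus.

    Positions are sampled in the volume-equivalent sphere from a uniform
    density tilted by exp(-(z + R)/lambda), with lambda solved so the
    expected mean-z offset equals ``target_z0``; the sphere is then mapped
    onto the requested ellipsoid (the inverse of the analysis pipeline's
    sphere normalisation).  Radii come from a truncated power law on
    volumes.  Per-plane geometry is synthesised by slicing the ellipsoid at
    ``plane_step`` intervals.
    """
    a, b, c = (float(s) for s in semi_axes)
    r_sphere = (a * b * c) ** (1.0 / 3.0)
    if target_z0 < 0 or target_z0 > 0.5 * r_sphere:
        raise ValueError(
            f"target_z0 must lie in [0, {0.5 * r_sphere:.1f}] um, got {target_z0}"
        )
    rng = np.random.default_rng(seed)
    lam = _solve_tilt(target_z0, r_sphere)

    pts = np.empty((0, 3))
    while pts.shape[0] < n_bodies:
        m = max(2 * (n_bodies - pts.shape[0]), 100)
        cand = rng.normal(size=(m, 3))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        cand *= r_sphere * rng.random(m)[:, None] ** (1.0 / 3.0)
        if np.isfinite(lam):
            accept = rng.random(m) < np.exp(-(cand[:, 2] + r_sphere) / lam)
            cand = cand[accept]
        pts = np.vstack([pts, cand])
    pts = pts[:n_bodies]

    # sphere -> ellipsoid (raw frame)
    scale = np.array([a, b, c]) / r_sphere
    raw = pts * scale + np.asarray(center, float)

    vols = sample_powerlaw_volumes(
        n_bodies, exponent, radius_to_volume(r_min), radius_to_volume(r_max), rng
    )
    radii = volume_to_radius(vols)
    cloud = NucleolusCloud(positions=raw, radii=radii, frame="raw")

    zs = np.arange(-c + plane_step, c, plane_step)
    frac = np.sqrt(np.clip(1.0 - (zs / c) ** 2, 1e-12, None))
    geom = NucleusGeometry(
        plane_z=zs + center[2],
        plane_center=np.tile(np.asarray(center[:2], float), (zs.size, 1)),
        plane_semi=np.column_stack([a * frac, b * frac]),
    )
    truth = {
        "target_z0_um": target_z0,
        "semi_axes_um": (a, b, c),
        "sphere_radius_um": r_sphere,
        "tilt_lambda_um": lam,
        "exponent": exponent,
        "r_min_um": r_min,
        "r_max_um": r_max,
    }
    return SyntheticCloud(cloud=cloud, geometry=geom, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# centrifugation cohorts


def _median_powerlaw_radius(exponent: float, r_min: float, r_max: float) -> float:
    """Analytic median radius of the truncated power law on volumes."""
    v_min, v_max = radius_to_volume(r_min), radius_to_volume(r_max)
    a1 = exponent + 1.0
    if abs(a1) < 1e-12:
        v_med = v_min * np.sqrt(v_max / v_min)
    else:
        v_med = (0.5 * (v_min**a1 + v_max**a1)) ** (1.0 / a1)
    return float(volume_to_radius(v_med))


#: the experimental centrifugation design: effective gravity -> durations (s)
CENTRIFUGE_SCHEDULE = {
    10.0: (1200.0, 10800.0, 28800.0, 50400.0),  # 20 min, 3 h, 8 h, 14 h
    100.0: (600.0, 1200.0, 1800.0, 3000.0, 6000.0),  # 10-100 min
    1000.0: (120.0, 300.0, 600.0, 1200.0),  # 2-20 min
}


def synth_cohort(
    viscosity: float = 1.7,
    delta_rho: float = DELTA_RHO_DEFAULT,
    schedule: dict | None = None,
    exponent: float = -1.5,
    r_min: float = 0.5,
    r_max: float = 10.0,
    n_nuclei: int = 9,
    scatter_um: float = 0.0,
    target_z0: float = 50.0,
    n_bodies: int = 200,
    include_clouds: bool = False,
    seed: int = 0,
) -> SyntheticCohort:
    """Centrifugation cohorts whose mean displacement follows Stokes creep.

    For each (g, t) condition the true displacement is
    ``dz = (2/9) drho g0 g R_med^2 t / eta`` (R_med = analytic median body
    radius); per-nucleus values add Gaussian scatter of sd ``scatter_um``.
    With ``include_clouds`` each nucleus also gets a gravity-aligned body
    cloud shifted down by its dz, bodies clamped at the nucleus floor
    (the fully sedimented phenotype at large dz).
    """
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    schedule = dict(CENTRIFUGE_SCHEDULE) if schedule is None else schedule
    rng = np.random.default_rng(seed)
    r_med = _median_powerlaw_radius(exponent, r_min, r_max)
    a, b, c = NUCLEUS_SEMI_AXES_DEFAULT
    r_sphere = (a * b * c) ** (1.0 / 3.0)
    ref_mean_z = r_sphere - target_z0  # native mean body z, aligned frame

    series, clouds = [], {}
    for g, times in sorted(schedule.items()):
        times = np.asarray(sorted(times), float)
        dz_true = (
            (2.0 / 9.0) * delta_rho * G0_SI * g * r_med**2 * times * _U_TO_PA_UM / viscosity
        )
        dz_obs = []
        for t, dz in zip(times, dz_true):
            per_nucleus = dz + (
                rng.normal(0.0, scatter_um, size=n_nuclei) if scatter_um > 0 else 0.0
            )
            per_nucleus = np.atleast_1d(per_nucleus)
            dz_obs.append(float(np.mean(per_nucleus)))
            if include_clouds:
                cs = []
                for dz_i in np.atleast_1d(per_nucleus)[:n_nuclei]:
                    sc = synth_nucleolus_cloud(
                        n_bodies=n_bodies,
                        target_z0=target_z0,
                        exponent=exponent,
                        r_min=r_min,
                        r_max=r_max,
                        seed=int(rng.integers(2**31)),
                    )
                    aligned = align_gravity_axis(
                        normalize_to_sphere(sc.cloud, fit_ellipsoid(sc.geometry))
                    )
                    pos = aligned.positions.copy()
                    pos[:, 2] = np.maximum(pos[:, 2] - dz_i, aligned.radii)
                    cs.append(
                        NucleolusCloud(
                            positions=pos,
                            radii=aligned.radii,
                            frame="gravity-aligned",
                            nucleus_center=aligned.nucleus_center,
                            nucleus_radius=aligned.nucleus_radius,
                        )
                    )
                clouds[(g, float(t))] = cs
        series.append(
            SedimentationSeries(
                g_multiple=float(g),
                times=times,
                delta_z=np.asarray(dz_obs),
                r_median=r_med,
                delta_rho=delta_rho,
            )
        )
    truth = {
        "viscosity_Pas": viscosity,
        "delta_rho": delta_rho,
        "r_median_um": r_med,
        "scatter_um": scatter_um,
        "target_z0_um": target_z0,
    }
    return SyntheticCohort(
        series=series,
        clouds=clouds,
        reference_mean_z=ref_mean_z,
        truth=truth,
        seed=seed,
    )


def synth_intensity_profile(
    radius: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    n_points: int = 201,
):
    """1-D Gaussian intensity profile of a body of the given radius.

    sigma = radius / sqrt(2 ln 2) so that half the FWHM equals the radius.
    Returns (positions, intensities, truth).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    sigma = radius / np.sqrt(2.0 * np.log(2.0))
    x = np.linspace(-4.0 * sigma, 4.0 * sigma, n_points)
    y = amplitude * np.exp(-(x**2) / (2.0 * sigma**2)) + baseline
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd * amplitude, size=n_points)
    return x, y, {"radius_um": radius, "sigma_um": sigma}
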