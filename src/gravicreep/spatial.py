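"""Nucleus geometry and nuclear-body spatial statistics.

The analysis chain for one imaged nucleus: per-plane segmentation summaries
are fitted as an ellipsoid; a linear map turns the nucleus into a sphere
(applied identically to all nuclear-body coordinates); a rotation aligns the
apparent gravitational axis (the vector from the nucleus centroid to the
mean body position) with -z; and z = 0 is relocated to the nucleus bottom.
On the aligned cloud we measure the asymmetry distance z0, 20-um density
profiles, cohort sedimentation displacements delta-z, creep velocities, the
force-time collapse viscosity, power-law size fits and Fisher-z correlation
intervals.

Coordinate convention throughout: gravity points along -z, z = 0 at the
nucleus bottom, lengths in um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .errors import FitError, InsufficientDataError
from .rheology import G0_SI

__all__ = [
    "NucleolusCloud",
    "NucleusGeometry",
    "DensityProfile",
    "PowerLawFit",
    "CorrelationResult",
    "SedimentationSeries",
    "fit_ellipsoid",
    "normalize_to_sphere",
    "align_gravity_axis",
    "asymmetry_z0",
    "density_profile",
    "delta_z",
    "creep_velocity",
    "force_time_collapse",
    "fit_power_law",
    "radius_from_profile",
    "correlation_with_ci",
    "fisher_ci",
    "volume_to_radius",
    "radius_to_volume",
]

_FRAMES = ("raw", "sphere-normalized", "gravity-aligned")

#: nucleoli are denser than the nucleoplasm by roughly this much, kg/m^3
DELTA_RHO_DEFAULT = 50.0

#: scaled force-time variable u = (2/9) drho g0 g R^2 t, in Pa*um after this
#: conversion (so delta-z [um] = u / eta [Pa*s])
_U_TO_PA_UM = 1e-6


def volume_to_radius(volume):
    """Sphere radius (um) from volume (um^3)."""
    return (3.0 * np.asarray(volume, float) / (4.0 * np.pi)) ** (1.0 / 3.0)


def radius_to_volume(radius):
    """Sphere volume (um^3) from radius (um)."""
    return (4.0 / 3.0) * np.pi * np.asarray(radius, float) ** 3


@dataclass(frozen=True)
class NucleolusCloud:
    """3-D positions and radii of the nuclear bodies in one nucleus."""

    positions: np.ndarray  # (n, 3), um
    radii: np.ndarray  # (n,), um
    frame: str = "raw"
    nucleus_center: np.ndarray | None = None  # (3,), um, in this frame
    nucleus_radius: float | None = None  # um, set once sphere-normalized
    degenerate_axis: bool = False

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.positions, float))
        r = np.atleast_1d(np.asarray(self.radii, float))
        if p.shape != (r.size, 3):
            raise ValueError("positions must be (n, 3) with one radius per body")
        if r.size < 1:
            raise ValueError("cloud must contain at least one body")
        if not np.all(np.isfinite(p)) or np.any(r <= 0):
            raise ValueError("positions must be finite and radii positive")
        if self.frame not in _FRAMES:
            raise ValueError(f"frame must be one of {_FRAMES}, got {self.frame!r}")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "radii", r)
        if self.nucleus_center is not None:
            object.__setattr__(
                self, "nucleus_center", np.asarray(self.nucleus_center, float)
            )

    @property
    def n_bodies(self) -> int:
        return self.radii.size

    @property
    def volumes(self) -> np.ndarray:
        return radius_to_volume(self.radii)


@dataclass(frozen=True)
class NucleusGeometry:
    """Per-plane nucleus segmentation summaries and the fitted ellipsoid.

    Each imaging plane carries its z position, its (x, y) centre and its
    in-plane semi-extents along x and y; the area follows as
    pi * semi_x * semi_y.  The ellipsoid (axis-aligned) is filled in by
    :func:`fit_ellipsoid`.
    """

    plane_z: np.ndarray  # (m,), um, sorted ascending
    plane_center: np.ndarray  # (m, 2), um
    plane_semi: np.ndarray  # (m, 2), um: in-plane semi-axes (x, y)
    ellipsoid_center: np.ndarray | None = None  # (3,), um
    ellipsoid_semi_axes: np.ndarray | None = None  # (3,), um
    ellipsoid_orientation: np.ndarray | None = None  # (3, 3) rotation

    def __post_init__(self) -> None:
        z = np.asarray(self.plane_z, float)
        c = np.asarray(self.plane_center, float)
        s = np.asarray(self.plane_semi, float)
        if z.ndim != 1 or c.shape != (z.size, 2) or s.shape != (z.size, 2):
            raise ValueError("plane arrays must be (m,), (m,2), (m,2)")
        if np.any(np.diff(z) <= 0):
            raise ValueError("planes must be sorted by strictly increasing z")
        if np.any(s <= 0):
            raise ValueError("plane semi-extents must be positive")
        object.__setattr__(self, "plane_z", z)
        object.__setattr__(self, "plane_center", c)
        object.__setattr__(self, "plane_semi", s)
        for name in ("ellipsoid_center", "ellipsoid_semi_axes", "ellipsoid_orientation"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, float))

    @property
    def plane_area(self) -> np.ndarray:
        """Cross-sectional area per plane, um^2."""
        return np.pi * self.plane_semi[:, 0] * self.plane_semi[:, 1]


@dataclass(frozen=True)
class DensityProfile:
    """Normalised number density of bodies along z (z = 0 at nucleus bottom)."""

    bin_edges: np.ndarray  # um
    normalized_counts: np.ndarray  # sums to 1

    def __post_init__(self) -> None:
        c = np.asarray(self.normalized_counts, float)
        if np.any(c < 0) or abs(c.sum() - 1.0) > 1e-9:
            raise ValueError("counts must be non-negative and sum to 1")
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(self, "normalized_counts", c)


@dataclass(frozen=True)
class PowerLawFit:
    """Truncated continuous power-law fit p(V) ~ V^alpha on [v_min, v_max]."""

    exponent: float
    v_min: float
    v_max: float
    ci95: tuple
    n: int
    n_excluded: int = 0
    log_bin_edges: np.ndarray | None = None
    log_bin_density: np.ndarray | None = None


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with a Fisher-z 95% confidence interval."""

    r: float
    n: int
    ci95: tuple
    degenerate: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (-1.0 <= lo <= self.r <= hi <= 1.0):
            raise ValueError("CI must bracket r within [-1, 1]")

    @classmethod
    def from_r(cls, r: float, n: int) -> "CorrelationResult":
        """Build the Fisher-z interval directly from a coefficient and n."""
        return cls(r=float(r), n=int(n), ci95=fisher_ci(r, n), degenerate=abs(r) >= 1.0)


@dataclass(frozen=True)
class SedimentationSeries:
    """delta-z versus centrifugation time at one effective gravity."""

    g_multiple: float
    times: np.ndarray  # s
    delta_z: np.ndarray  # um, positive downward
    r_median: float  # um, median body radius of the cohort
    delta_rho: float = DELTA_RHO_DEFAULT  # kg/m^3

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        d = np.asarray(self.delta_z, float)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("times and delta_z must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "delta_z", d)

    def scaled_force_time(self) -> np.ndarray:
        """u = (2/9) drho g0 g R_med^2 t in Pa*um (delta-z = u / eta)."""
        return (
            (2.0 / 9.0)
            * self.delta_rho
            * G0_SI
            * self.g_multiple
            * self.r_median**2
            * self.times
            * _U_TO_PA_UM
        )


# ---------------------------------------------------------------------------
# geometry pipeline


def fit_ellipsoid(geom: NucleusGeometry) -> NucleusGeometry:
    """Fit an axis-aligned ellipsoid to per-plane segmentation summaries.

    The in-plane semi-extents of a z-slice of an axis-aligned ellipsoid obey
    ``semi(z) = a * sqrt(1 - ((z - z0)/c)^2)``; both in-plane directions are
    fitted jointly with shared (z0, c) by least squares, initialised from a
    quadratic fit to semi^2(z).
    """
    z = geom.plane_z
    if z.size < 5:
        raise InsufficientDataError(f"need >= 5 planes, got {z.size}")
    sx, sy = geom.plane_semi[:, 0], geom.plane_semi[:, 1]

    # initial guesses from the quadratic z-profile of semi^2
    coef = np.polyfit(z, sx**2, 2)
    if coef[0] >= 0:
        raise FitError("plane extents do not decay away from a central plane")
    z0_0 = -coef[1] / (2 * coef[0])
    a2_0 = max(np.polyval(coef, z0_0), np.max(sx) ** 2)
    c_0 = np.sqrt(max(-a2_0 / coef[0], (z[-1] - z[0]) ** 2 / 4))
    b_0 = np.max(sy)

    def residual(p):
        a, b, c, z0 = p
        arg = np.clip(1.0 - ((z - z0) / c) ** 2, 0.0, None)
        s = np.sqrt(arg)
        return np.concatenate([a * s - sx, b * s - sy])

    sol = optimize.least_squares(
        residual,
        x0=[np.sqrt(a2_0), b_0, c_0, z0_0],
        xtol=1e-15,
        ftol=1e-15,
    )
    a, b, c, z0 = sol.x
    center = np.array([geom.plane_center[:, 0].mean(), geom.plane_center[:, 1].mean(), z0])
    return replace(
        geom,
        ellipsoid_center=center,
        ellipsoid_semi_axes=np.array([abs(a), abs(b), abs(c)]),
        ellipsoid_orientation=np.eye(3),
    )


def normalize_to_sphere(cloud: NucleolusCloud, geom: NucleusGeometry) -> NucleolusCloud:
    """Map the fitted ellipsoid onto a sphere and carry the bodies along.

    The target radius is the geometric mean of the semi-axes (the map is
    volume-preserving); the same linear map is applied to every body
    position.  Body radii are left unchanged.
    """
    if cloud.frame != "raw":
        raise ValueError(f"expected a raw-frame cloud, got {cloud.frame!r}")
    if geom.ellipsoid_semi_axes is None:
        raise ValueError("geometry has no fitted ellipsoid; run fit_ellipsoid first")
    axes = geom.ellipsoid_semi_axes
    center = geom.ellipsoid_center
    r = float(np.prod(axes) ** (1.0 / 3.0))
    scale = r / axes
    pos = (cloud.positions - center) * scale + center
    return replace(
        cloud,
        positions=pos,
        frame="sphere-normalized",
        nucleus_center=center,
        nucleus_radius=r,
    )


def _rotation_onto(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation (det +1) mapping unit vector u onto unit vector v
    (Rodrigues form)."""
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to u
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, helper)
        axis /= np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2.0 * K @ K
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def align_gravity_axis(cloud: NucleolusCloud, tol: float = 1e-9) -> NucleolusCloud:
    """Rotate so the apparent gravitational axis points along -z.

    The axis is the vector from the nucleus centroid to the mean body
    position (bodies concentrate downward).  After rotation the coordinates
    are re-origined so the nucleus bottom sits at z = 0 and its centre at
    (0, 0, R).  If the mean body position coincides with the centroid the
    rotation is the identity and ``degenerate_axis`` is set.
    """
    if cloud.frame != "sphere-normalized":
        raise ValueError(f"expected a sphere-normalized cloud, got {cloud.frame!r}")
    center = cloud.nucleus_center
    R = cloud.nucleus_radius
    mean_pos = cloud.positions.mean(axis=0)
    axis = mean_pos - center
    norm = np.linalg.norm(axis)
    degenerate = norm < tol
    rot = np.eye(3) if degenerate else _rotation_onto(axis / norm, np.array([0.0, 0.0, -1.0]))
    pos = (cloud.positions - center) @ rot.T
    pos[:, 2] += R  # nucleus bottom -> z = 0
    return replace(
        cloud,
        positions=pos,
        frame="gravity-aligned",
        nucleus_center=np.array([0.0, 0.0, R]),
        degenerate_axis=degenerate,
    )


def asymmetry_z0(cloud: NucleolusCloud) -> float:
    """Asymmetry distance z0 = |mean body z - nucleus centre z|, um."""
    if cloud.frame != "gravity-aligned":
        raise ValueError(f"expected a gravity-aligned cloud, got {cloud.frame!r}")
    return float(abs(cloud.positions[:, 2].mean() - cloud.nucleus_center[2]))


def mean_body_z(cloud: NucleolusCloud) -> float:
    """Signed mean body z in the gravity-aligned frame, um."""
    if cloud.frame != "gravity-aligned":
        raise ValueError(f"expected a gravity-aligned cloud, got {cloud.frame!r}")
    return float(cloud.positions[:, 2].mean())


def density_profile(cloud: NucleolusCloud, bin_width: float = 20.0) -> DensityProfile:
    """Normalised number density along z in fixed-width bins from z = 0."""
    if cloud.frame != "gravity-aligned":
        raise ValueError(f"expected a gravity-aligned cloud, got {cloud.frame!r}")
    z = cloud.positions[:, 2]
    top = max(2.0 * cloud.nucleus_radius, z.max() + 1e-9) if cloud.nucleus_radius else z.max() + 1e-9
    n_bins = int(np.ceil(top / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(z, bins=edges)
    return DensityProfile(bin_edges=edges, normalized_counts=counts / counts.sum())


def delta_z(reference_mean_z: float, cohort: list[NucleolusCloud]) -> dict:
    """Relative sedimentation displacement of a cohort versus the native
    reference: delta-z_i = reference mean z - cohort-nucleus mean z
    (positive = downward).  Returns per-nucleus values, mean and s.e.m."""
    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one cloud")
    per = np.array([reference_mean_z - mean_body_z(c) for c in cohort])
    sem = float(per.std(ddof=1) / np.sqrt(per.size)) if per.size > 1 else 0.0
    return {"per_nucleus": per, "mean": float(per.mean()), "sem": sem}


# ---------------------------------------------------------------------------
# sedimentation regression


def creep_velocity(series: SedimentationSeries, conf: float = 0.95) -> dict:
    """Creep velocity as the through-origin slope of delta-z vs t, with CI.

    The regression is forced through the origin because delta-z is defined
    relative to the native reference at t = 0.
    """
    t, d = series.times, series.delta_z
    if t.size < 3:
        raise InsufficientDataError(f"need >= 3 time points, got {t.size}")
    v = float(np.sum(t * d) / np.sum(t * t))
    resid = d - v * t
    s2 = float(np.sum(resid**2) / (t.size - 1))
    se = np.sqrt(s2 / np.sum(t * t))
    tcrit = stats.t.ppf(0.5 + conf / 2, df=t.size - 1)
    return {"velocity": v, "ci95": (v - tcrit * se, v + tcrit * se), "se": float(se)}


def force_time_collapse(series_set: list[SedimentationSeries]) -> dict:
    """Collapse delta-z data from all gravities onto the Stokes variable
    u = (2/9) drho g0 g R_med^2 t and read off the long-time viscosity.

    Pooled through-origin regression delta-z = u / eta; the inverse pooled
    slope is the apparent viscosity.  Per-condition viscosities are returned
    alongside for the within-error consistency check.
    """
    if not series_set:
        raise ValueError("need at least one series")
    rhos = {s.delta_rho for s in series_set}
    if len(rhos) > 1:
        raise ValueError(f"inconsistent delta_rho across series: {sorted(rhos)}")
    u_all, d_all, per_condition = [], [], {}
    for s in series_set:
        u = s.scaled_force_time()
        slope = float(np.sum(u * s.delta_z) / np.sum(u * u))
        per_condition[s.g_multiple] = 1.0 / slope if slope > 0 else np.inf
        u_all.append(u)
        d_all.append(s.delta_z)
    u_all = np.concatenate(u_all)
    d_all = np.concatenate(d_all)
    slope = float(np.sum(u_all * d_all) / np.sum(u_all * u_all))
    if slope <= 0:
        raise FitError("non-positive collapse slope; delta-z does not grow with u")
    return {"viscosity": 1.0 / slope, "per_condition": per_condition}


# ---------------------------------------------------------------------------
# size statistics


def _powerlaw_loglik(alpha: float, logs: np.ndarray, v_min: float, v_max: float) -> float:
    n = logs.size
    a1 = alpha + 1.0
    if abs(a1) < 1e-9:
        log_c = -np.log(np.log(v_max / v_min))
    else:
        log_c = np.log(abs(a1)) - np.log(abs(v_max**a1 - v_min**a1))
    return n * log_c + alpha * logs.sum()


def fit_power_law(
    volumes,
    v_min: float,
    v_max: float,
    n_display_bins: int = 12,
) -> PowerLawFit:
    """Maximum-likelihood truncated continuous power law p(V) ~ V^alpha.

    Values outside [v_min, v_max] are excluded (their count is reported).
    The 95% CI comes from the profile likelihood (chi-square with 1 dof);
    a log-binned histogram is attached for display parity with the
    conventional log-log size-distribution plot.
    """
    v = np.asarray(volumes, float)
    if v_min >= v_max or v_min <= 0:
        raise ValueError("need 0 < v_min < v_max")
    inside = v[(v >= v_min) & (v <= v_max)]
    n_excluded = v.size - inside.size
    if inside.size < 10:
        raise InsufficientDataError(f"need >= 10 in-range samples, got {inside.size}")
    logs = np.log(inside)

    nll = lambda a: -_powerlaw_loglik(a, logs, v_min, v_max)
    res = optimize.minimize_scalar(nll, bounds=(-6.0, 4.0), method="bounded")
    alpha = float(res.x)
    ll_max = -res.fun

    # profile-likelihood 95% CI: ll drops by chi2_1(0.95)/2 = 1.921
    drop = 0.5 * stats.chi2.ppf(0.95, df=1)
    f = lambda a: _powerlaw_loglik(a, logs, v_min, v_max) - (ll_max - drop)
    lo = optimize.brentq(f, -12.0, alpha) if f(-12.0) < 0 else -12.0
    hi = optimize.brentq(f, alpha, 10.0) if f(10.0) < 0 else 10.0

    edges = np.geomspace(v_min, v_max, n_display_bins + 1)
    counts, _ = np.histogram(inside, bins=edges)
    density = counts / (np.diff(edges) * inside.size)
    return PowerLawFit(
        exponent=alpha,
        v_min=float(v_min),
        v_max=float(v_max),
        ci95=(float(lo), float(hi)),
        n=int(inside.size),
        n_excluded=int(n_excluded),
        log_bin_edges=edges,
        log_bin_density=density,
    )


def radius_from_profile(positions, intensity) -> float:
    """Body radius from a 1-D intensity profile via a Gaussian fit.

    The radius is defined as half the full width at half maximum of the
    fitted Gaussian: radius = sigma * sqrt(2 ln 2).
    """
    x = np.asarray(positions, float)
    y = np.asarray(intensity, float)
    if x.shape != y.shape or x.size < 5:
        raise InsufficientDataError("need >= 5 profile samples")
    base = float(np.min(y))
    amp = float(np.max(y) - base)
    if amp <= 0:
        raise FitError("flat profile; no peak to size")
    mu0 = float(x[np.argmax(y)])
    w = np.clip(y - base, 0, None)
    sigma0 = float(np.sqrt(np.sum(w * (x - mu0) ** 2) / np.sum(w))) or (x[-1] - x[0]) / 4

    def gauss(x, a, mu, sigma, b):
        return a * np.exp(-((x - mu) ** 2) / (2 * sigma**2)) + b

    try:
        with warnings.catch_warnings():
            # the covariance is unused; it is singular on noise-free profiles
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                gauss, x, y, p0=[amp, mu0, sigma0, base], maxfev=10000
            )
    except RuntimeError as exc:
        raise FitError(f"Gaussian sizing fit did not converge: {exc}") from exc
    sigma = abs(popt[2])
    return float(sigma * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# correlation


def fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh(r) +/- z* / sqrt(n - 3))."""
    if n < 4:
        raise InsufficientDataError(f"need n >= 4 for a Fisher interval, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"r must be in [-1, 1], got {r}")
    if abs(r) >= 1.0:
        return (r, r)
    zcrit = stats.norm.ppf(0.5 + conf / 2)
    z = np.arctanh(r)
    half = zcrit / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def correlation_with_ci(x, y) -> CorrelationResult:
    """Pearson correlation of paired samples with a Fisher-z 95% CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 4:
        raise InsufficientDataError(f"need n >= 4, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    degenerate = abs(r) >= 1.0 - 1e-15
    ci = (r, r) if degenerate else fisher_ci(r, x.size)
    return CorrelationResult(r=r, n=int(x.size), ci95=ci, degenerate=degenerate)
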