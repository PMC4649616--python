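"""Viscoelastic property estimation from magnetic-bead trajectories.

Active microrheology with magnetic tweezers: a superparamagnetic bead
embedded in the network is driven either by a sinusoidal force (yielding
storage and loss moduli from the amplitude and phase of its response) or by
a step force (yielding the creep compliance).  Both routes are fitted with
the extended Kelvin-Voigt model from :mod:`gravicreep.rheology`, and for a
linear viscoelastic material must return the same parameters.

Conventions: displacement is modelled as
``x(t) = offset + drift*t + x0*sin(w t + phi_x)`` and the force as
``F(t) = F0*sin(w t + phi_F)``; the phase lag ``delta = phi_F - phi_x`` is
wrapped into [0, pi), so ``delta = 0`` is a purely elastic response and
``delta = pi/2`` purely viscous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InsufficientDataError, ProtocolError
from .rheology import ViscoelasticParams, complex_moduli, creep_compliance

__all__ = [
    "BeadTrajectory",
    "OscillatoryFit",
    "ModuliSpectrum",
    "CreepCurve",
    "ModelFitResult",
    "fit_sinusoid",
    "moduli_from_oscillation",
    "compliance_from_step",
    "fit_model_to_moduli",
    "fit_model_to_creep",
    "lissajous_ellipse",
    "calibrate_force",
]

#: Beads are 2.8 um diameter superparamagnetic spheres; radius preset in um.
BEAD_RADIUS_DEFAULT = 1.4
#: Alternative radius preset quoted for imaging of the same beads, um.
BEAD_RADIUS_IMAGING = 1.5


@dataclass(frozen=True)
class BeadTrajectory:
    """Timestamped bead displacement under a known force protocol.

    times (s, strictly increasing), displacement (um, along the force axis)
    and force (pN) are equal-length arrays with at least 10 samples;
    bead_radius is in um.
    """

    times: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    bead_radius: float = BEAD_RADIUS_DEFAULT

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        x = np.asarray(self.displacement, float)
        f = np.asarray(self.force, float)
        if not (t.shape == x.shape == f.shape) or t.ndim != 1:
            raise ValueError("times, displacement, force must be equal-length 1-D arrays")
        if t.size < 10:
            raise InsufficientDataError(f"need >= 10 samples, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.bead_radius <= 0:
            raise ValueError(f"bead_radius must be positive, got {self.bead_radius}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "displacement", x)
        object.__setattr__(self, "force", f)


@dataclass(frozen=True)
class OscillatoryFit:
    """Result of fitting one oscillation frequency."""

    omega: float  # rad/s
    amplitude_x0: float  # um
    phase_delta: float  # rad, lag of displacement behind force, in [0, pi)
    force_amplitude_F0: float  # pN
    offset: float  # um
    drift: float  # um/s


@dataclass(frozen=True)
class ModuliSpectrum:
    """Storage/loss moduli versus frequency with optional uncertainties."""

    frequencies: np.ndarray  # Hz, strictly increasing
    G_storage: np.ndarray  # Pa
    G_loss: np.ndarray  # Pa
    uncertainties: np.ndarray | None = None  # Pa, per point (shared G'/G'')

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, float)
        gs = np.asarray(self.G_storage, float)
        gl = np.asarray(self.G_loss, float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(gs < 0) or np.any(gl < 0):
            raise ValueError("moduli must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "G_storage", gs)
        object.__setattr__(self, "G_loss", gl)
        if self.uncertainties is not None:
            u = np.asarray(self.uncertainties, float)
            if u.shape != f.shape or np.any(u <= 0):
                raise ValueError("uncertainties must be positive, one per frequency")
            object.__setattr__(self, "uncertainties", u)

    @property
    def omegas(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequencies


@dataclass(frozen=True)
class CreepCurve:
    """Creep compliance J(t) since force onset (t in s, J in 1/Pa)."""

    times: np.ndarray
    compliance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        j = np.asarray(self.compliance, float)
        if t.shape != j.shape or t.ndim != 1:
            raise ValueError("times and compliance must be equal-length 1-D arrays")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "compliance", j)


@dataclass(frozen=True)
class ModelFitResult:
    """Fitted extended Kelvin-Voigt parameters with bootstrap 95% CIs."""

    params: ViscoelasticParams
    ci95: dict  # {"E": (lo, hi), "eta2": ..., "eta1": ...}
    residual_norm: float
    method: str  # "oscillatory" | "creep"
    flags: tuple = field(default_factory=tuple)


def _sin_cos_lsq(t, y, omega, drift=True):
    """Linear LS of y on [1, (t), sin wt, cos wt]; returns amp, phase, offset, drift."""
    cols = [np.ones_like(t)]
    if drift:
        cols.append(t)
    cols += [np.sin(omega * t), np.cos(omega * t)]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a, b = coef[-2], coef[-1]
    amp = float(np.hypot(a, b))
    phase = float(np.arctan2(b, a))  # y ~ amp*sin(wt + phase)
    off = float(coef[0])
    dr = float(coef[1]) if drift else 0.0
    return amp, phase, off, dr


def fit_sinusoid(traj: BeadTrajectory, omega: float, drift: bool = True) -> OscillatoryFit:
    """Fit a sinusoid at known drive frequency to displacement and force.

    The drive frequency is known from the force protocol, so the fit is
    linear in (offset, drift, sin, cos) components.  The phase lag is the
    force phase minus the displacement phase, wrapped into [0, pi).

    Raises
    ------
    InsufficientDataError
        If the trajectory spans fewer than two full periods.
    """
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    t = traj.times
    span = t[-1] - t[0]
    if span * omega < 2 * 2 * np.pi:
        raise InsufficientDataError(
            f"trajectory spans {span * omega / (2 * np.pi):.2f} periods; need >= 2"
        )
    x0, phi_x, off, dr = _sin_cos_lsq(t, traj.displacement, omega, drift=drift)
    F0, phi_F, _, _ = _sin_cos_lsq(t, traj.force, omega, drift=False)
    if x0 <= 0 or not np.isfinite(x0):
        raise FitError("degenerate displacement fit (zero amplitude)")
    delta = (phi_F - phi_x) % (2 * np.pi)
    if delta > np.pi:  # reflect into [0, pi)
        delta = 2 * np.pi - delta
    return OscillatoryFit(
        omega=float(omega),
        amplitude_x0=x0,
        phase_delta=float(delta),
        force_amplitude_F0=F0,
        offset=off,
        drift=dr,
    )


def moduli_from_oscillation(fit: OscillatoryFit, bead_radius: float) -> tuple[float, float]:
    """Storage and loss moduli from one oscillatory fit.

    G' = F0 cos(delta) / (6 pi R x0), G'' = F0 sin(delta) / (6 pi R x0).
    """
    if fit.amplitude_x0 <= 0:
        raise ZeroDivisionError("degenerate response: zero displacement amplitude")
    if bead_radius <= 0:
        raise ValueError(f"bead_radius must be positive, got {bead_radius}")
    scale = fit.force_amplitude_F0 / (6.0 * np.pi * bead_radius * fit.amplitude_x0)
    return scale * np.cos(fit.phase_delta), scale * np.sin(fit.phase_delta)


def compliance_from_step(
    traj: BeadTrajectory, F0: float, bead_radius: float | None = None, rtol: float = 1e-6
) -> CreepCurve:
    """Creep compliance from a step-force response: J(t) = 6 pi R x(t) / F0.

    The force trace must be constant (= F0) over the analysed window and the
    displacement is zeroed at force onset (first sample).
    """
    if F0 <= 0:
        raise ValueError(f"F0 must be positive, got {F0}")
    R = traj.bead_radius if bead_radius is None else bead_radius
    f = traj.force
    if np.max(np.abs(f - F0)) > rtol * abs(F0) + 1e-12:
        raise ProtocolError("force is not constant at F0 over the analysis window")
    x = traj.displacement - traj.displacement[0]
    J = 6.0 * np.pi * R * x / F0
    return CreepCurve(times=traj.times - traj.times[0], compliance=J)


# ---------------------------------------------------------------------------
# model fitting


def _init_from_spectrum(spec: ModuliSpectrum) -> np.ndarray:
    """Heuristic start: eta1 from low-w G''/w, eta2 from the high-w series
    limit G''/w -> eta1*eta2/(eta1+eta2), E from the G' plateau."""
    w = spec.omegas
    eta1 = max(spec.G_loss[0] / w[0], 1e-12)
    eta_series = max(spec.G_loss[-1] / w[-1], 1e-12)
    if eta_series < eta1:
        eta2 = eta1 * eta_series / (eta1 - eta_series)
    else:
        eta2 = eta_series
    eta2 = max(eta2, 1e-12)
    plateau = max(np.max(spec.G_storage), 1e-12)
    E = plateau * (eta1 + eta2) ** 2 / eta1**2
    return np.log([E, eta2, eta1])


def _fit_log_params(residual_fn, p0_log, restarts, rng) -> tuple[np.ndarray, float]:
    """Minimise a residual over log-parameters with random restarts."""
    tried, best, best_cost = [], None, np.inf
    starts = [p0_log] + [p0_log + rng.normal(0, 1.0, size=3) for _ in range(restarts)]
    for start in starts:
        try:
            sol = least_squares(residual_fn, start, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception as exc:  # pragma: no cover - scipy internal failure
            tried.append((start, repr(exc)))
            continue
        if sol.cost < best_cost and np.all(np.isfinite(sol.x)):
            best, best_cost = sol.x, sol.cost
        tried.append((start, sol.status))
    if best is None:
        raise FitError(f"model fit failed from all initialisations: {tried}")
    return best, best_cost


def fit_model_to_moduli(
    spectrum: ModuliSpectrum,
    n_bootstrap: int = 200,
    seed: int = 0,
    restarts: int = 3,
) -> ModelFitResult:
    """Simultaneous weighted fit of G'(w) and G''(w) to the model.

    Both moduli are fitted jointly with a single parameter set by minimising
    the weighted sum of squared residuals: inverse-variance weights when
    per-point uncertainties are supplied, otherwise uniform weights on
    log-moduli (which treats the decades of a rheology spectrum evenly).
    95% CIs come from a seeded parametric bootstrap.
    """
    w = spectrum.omegas
    if w.size < 3:
        raise InsufficientDataError("need >= 3 frequencies to constrain 3 parameters")
    rng = np.random.default_rng(seed)
    gs, gl, sig = spectrum.G_storage, spectrum.G_loss, spectrum.uncertainties

    def residual(log_p, gs=gs, gl=gl):
        E, eta2, eta1 = np.exp(log_p)
        ms, ml = complex_moduli(w, ViscoelasticParams(E, eta2, eta1))
        if sig is not None:
            return np.concatenate([(ms - gs) / sig, (ml - gl) / sig])
        eps = 1e-300
        return np.concatenate(
            [np.log(ms + eps) - np.log(gs + eps), np.log(ml + eps) - np.log(gl + eps)]
        )

    p0 = _init_from_spectrum(spectrum)
    best, cost = _fit_log_params(residual, p0, restarts, rng)
    params = ViscoelasticParams(*np.exp(best))

    # parametric bootstrap: perturb the fitted spectrum with the stated (or
    # residual-estimated) noise and refit from the solution
    ms, ml = complex_moduli(w, params)
    noise = sig if sig is not None else _residual_sd(np.concatenate([gs - ms, gl - ml]))
    reps = []
    for _ in range(n_bootstrap):
        gs_b = np.clip(ms + rng.normal(0, noise, size=w.size), 1e-12, None)
        gl_b = np.clip(ml + rng.normal(0, noise, size=w.size), 1e-12, None)
        try:
            sol = least_squares(
                lambda p: residual(p, gs=gs_b, gl=gl_b), best, xtol=1e-12, ftol=1e-12
            )
            reps.append(np.exp(sol.x))
        except Exception:
            continue
    ci = _bootstrap_ci(reps, params)
    return ModelFitResult(
        params=params, ci95=ci, residual_norm=float(np.sqrt(2 * cost)), method="oscillatory"
    )


def _residual_sd(res: np.ndarray) -> float:
    sd = float(np.std(res))
    return sd if sd > 0 else 1e-12


def _bootstrap_ci(reps, params: ViscoelasticParams) -> dict:
    est = np.array([params.E, params.eta2, params.eta1])
    if reps:
        arr = np.asarray(reps)
        lo = np.minimum(np.percentile(arr, 2.5, axis=0), est)
        hi = np.maximum(np.percentile(arr, 97.5, axis=0), est)
    else:  # no successful replicate: degenerate interval at the estimate
        lo = hi = est
    return {k: (float(lo[i]), float(hi[i])) for i, k in enumerate(("E", "eta2", "eta1"))}


def fit_model_to_creep(
    curve: CreepCurve,
    n_bootstrap: int = 200,
    seed: int = 0,
    restarts: int = 3,
) -> ModelFitResult:
    """Fit the creep compliance J(t) to the extended Kelvin-Voigt model.

    eta1 is anchored by the long-time slope, E by the intercept of the
    terminal flow line, and eta2 by the initial retardation.  Flags:
    ``degenerate_E`` when the elastic step 1/E is unresolvably small against
    the total compliance (pure-fluid limit; the E interval is unbounded
    above), ``eta1_unconstrained`` when the window is shorter than three
    retardation times.
    """
    t, J = curve.times, curve.compliance
    if t.size < 4:
        raise InsufficientDataError("need >= 4 points to constrain 3 parameters")
    rng = np.random.default_rng(seed)

    # heuristic start from the terminal line J ~ 1/E + t/eta1
    tail = t >= t[0] + 0.75 * (t[-1] - t[0])
    slope, intercept = np.polyfit(t[tail], J[tail], 1)
    eta1_0 = 1.0 / max(slope, 1e-12)
    E_0 = 1.0 / max(intercept, 1e-9)
    eta2_0 = max(E_0 * 0.1 * (t[-1] - t[0]), 1e-9)
    p0 = np.log([E_0, eta2_0, eta1_0])

    def residual(log_p, J=J):
        return creep_compliance(t, ViscoelasticParams(*np.exp(log_p))) - J

    best, cost = _fit_log_params(residual, p0, restarts, rng)
    params = ViscoelasticParams(*np.exp(best))

    flags = []
    span = t[-1] - t[0]
    if 1.0 / params.E < 1e-6 * max(np.max(J), 1e-300):
        flags.append("degenerate_E")
    if span < 3.0 * params.retardation_time:
        flags.append("eta1_unconstrained")

    model = creep_compliance(t, params)
    noise = _residual_sd(J - model)
    reps = []
    for _ in range(n_bootstrap):
        J_b = model + rng.normal(0, noise, size=t.size)
        try:
            sol = least_squares(lambda p: residual(p, J=J_b), best, xtol=1e-12, ftol=1e-12)
            reps.append(np.exp(sol.x))
        except Exception:
            continue
    ci = _bootstrap_ci(reps, params)
    if "degenerate_E" in flags:
        ci["E"] = (ci["E"][0], np.inf)
    return ModelFitResult(
        params=params,
        ci95=ci,
        residual_norm=float(np.sqrt(2 * cost)),
        method="creep",
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Lissajous analysis


def lissajous_ellipse(force, displacement) -> dict:
    """Algebraic least-squares ellipse through a force-displacement loop.

    For a linear viscoelastic response the loop is an ellipse whose enclosed
    area, pi*F0*x0*sin(delta), is the energy dissipated per cycle (pN*um).
    Collinear data (a purely elastic response) yields a degenerate result
    with zero area and ``degenerate=True``.

    Returns a dict with center, semi_axes (major, minor), tilt (rad) and
    enclosed_area.
    """
    x = np.asarray(displacement, float)
    y = np.asarray(force, float)
    if x.shape != y.shape or x.size < 6:
        raise InsufficientDataError("need >= 6 paired samples for a conic fit")
    xm, ym = x.mean(), y.mean()
    xc, yc = x - xm, y - ym
    scale = max(np.abs(xc).max(), np.abs(yc).max(), 1e-300)
    # collinearity check on the centred, scaled scatter
    s = np.linalg.svd(np.column_stack([xc, yc]) / scale, compute_uv=False)
    if s[-1] < 1e-8 * s[0]:
        return {
            "center": (float(xm), float(ym)),
            "semi_axes": (float(s[0] * scale / np.sqrt(len(x) / 2)), 0.0),
            "tilt": float(np.arctan2(yc[np.argmax(np.abs(xc))], xc[np.argmax(np.abs(xc))])),
            "enclosed_area": 0.0,
            "degenerate": True,
        }
    u, v = xc / scale, yc / scale
    # direct ellipse-specific fit, stable partitioned form (Halir-Flusser)
    D1 = np.column_stack([u**2, u * v, v**2])
    D2 = np.column_stack([u, v, np.ones_like(u)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    T = -np.linalg.solve(S3, S2.T)
    M = S1 + S2 @ T
    C1_inv = np.array([[0.0, 0.0, 0.5], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0]])
    eigval, eigvec = np.linalg.eig(C1_inv @ M)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2  # per eigenvector column
    ok = np.nonzero(np.isreal(eigval) & (np.real(cond) > 0))[0]
    if ok.size == 0:
        raise FitError("ellipse fit found no ellipse-type conic")
    a1 = np.real(eigvec[:, ok[0]])
    a_vec = np.concatenate([a1, T @ a1])
    A, B, Cc, Dd, Ee, F = a_vec
    # conic geometry (in scaled frame)
    den = B**2 - 4 * A * Cc
    cx = (2 * Cc * Dd - B * Ee) / den
    cy = (2 * A * Ee - B * Dd) / den
    num = 2 * (A * Ee**2 + Cc * Dd**2 + F * B**2 - B * Dd * Ee - 4 * A * Cc * F)
    root = np.sqrt((A - Cc) ** 2 + B**2)
    q1 = A + Cc + root
    q2 = A + Cc - root
    sa = np.sqrt(np.abs(num * q1)) / np.abs(den)
    sb = np.sqrt(np.abs(num * q2)) / np.abs(den)
    tilt = 0.5 * np.arctan2(B, A - Cc)
    area = np.pi * sa * sb * scale * scale
    return {
        "center": (float(cx * scale + xm), float(cy * scale + ym)),
        "semi_axes": (float(max(sa, sb) * scale), float(min(sa, sb) * scale)),
        "tilt": float(tilt),
        "enclosed_area": float(area),
        "degenerate": False,
    }


def calibrate_force(velocity: float, viscosity_cal: float, bead_radius: float) -> float:
    """Force from a terminal-velocity calibration in a fluid of known
    viscosity: F = 6 pi eta R v (pN for um/s, Pa*s, um)."""
    if viscosity_cal <= 0 or bead_radius <= 0:
        raise ValueError("viscosity and radius must be positive")
    return 6.0 * np.pi * viscosity_cal * bead_radius * velocity
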