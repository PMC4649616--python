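"""End-to-end orchestration: generate or ingest, analyse, report.

``run_pipeline`` wires the stages together for a demo/regression run:
synthetic microrheology -> model fits, synthetic cloud -> spatial
statistics, synthetic cohorts -> force-time collapse, and a short
Brownian-dynamics run.  Everything is driven by one seed, so re-running
with the same configuration reproduces the report bit for bit.
"""

from __future__ import annotations

import json

import numpy as np

from .microrheology import compliance_from_step, fit_model_to_creep, fit_model_to_moduli
from .microrheology import ModuliSpectrum
from .rheology import ViscoelasticParams, complex_moduli
from .simulate import SimConfig, run, time_to_displacement
from .spatial import (
    align_gravity_axis,
    asymmetry_z0,
    fit_ellipsoid,
    fit_power_law,
    force_time_collapse,
    normalize_to_sphere,
    radius_to_volume,
)
from .synthetic import synth_cohort, synth_creep_trajectory, synth_nucleolus_cloud

__all__ = ["run_pipeline", "DEFAULT_PIPELINE_CONFIG"]

DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "creep_truth": {"E_Pa": 0.14, "eta2_Pas": 0.15, "eta1_Pas": 1.7},
    "oscillatory_truth": {"E_Pa": 0.10, "eta2_Pas": 0.05, "eta1_Pas": 0.9},
    "noise_sd": 0.02,
    "n_frequencies": 10,
    "frequency_range_hz": (0.02, 1.0),
    "cloud": {"n_bodies": 500, "target_z0": 50.0},
    "cohort": {"viscosity": 1.7, "scatter_um": 0.0},
    "sim": {"g_multiple": 100.0, "t_end": 20000.0, "n_particles": 300},
    "bootstrap": 50,
}


def run_pipeline(config: dict | None = None) -> dict:
    """Run the full synthetic pipeline and return a JSON-serialisable report."""
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    report: dict = {"seed": seed, "stages": {}}

    # --- microrheology: creep route
    creep_truth = ViscoelasticParams.from_dict(cfg["creep_truth"])
    st = synth_creep_trajectory(creep_truth, noise_sd=cfg["noise_sd"], seed=int(rng.integers(2**31)))
    curve = compliance_from_step(st.trajectory, F0=st.truth["F0_pN"])
    creep_fit = fit_model_to_creep(curve, n_bootstrap=cfg["bootstrap"], seed=seed)
    report["stages"]["creep_fit"] = {
        "truth": creep_truth.to_dict(),
        "fit": creep_fit.params.to_dict(),
        "ci95": creep_fit.ci95,
        "flags": list(creep_fit.flags),
    }

    # --- microrheology: oscillatory route (moduli spectrum from the model)
    osc_truth = ViscoelasticParams.from_dict(cfg["oscillatory_truth"])
    f_lo, f_hi = cfg["frequency_range_hz"]
    freqs = np.geomspace(f_lo, f_hi, cfg["n_frequencies"])
    gs, gl = complex_moduli(2 * np.pi * freqs, osc_truth)
    noise = cfg["noise_sd"]
    if noise > 0:
        gs = gs * np.exp(rng.normal(0, noise, gs.size))
        gl = gl * np.exp(rng.normal(0, noise, gl.size))
    spec = ModuliSpectrum(frequencies=freqs, G_storage=gs, G_loss=gl)
    osc_fit = fit_model_to_moduli(spec, n_bootstrap=cfg["bootstrap"], seed=seed)
    report["stages"]["oscillatory_fit"] = {
        "truth": osc_truth.to_dict(),
        "fit": osc_fit.params.to_dict(),
        "ci95": osc_fit.ci95,
    }

    # --- spatial statistics on one synthetic nucleus
    sc = synth_nucleolus_cloud(seed=int(rng.integers(2**31)), **cfg["cloud"])
    aligned = align_gravity_axis(
        normalize_to_sphere(sc.cloud, fit_ellipsoid(sc.geometry))
    )
    pl = fit_power_law(
        aligned.radii**3 * (4 * np.pi / 3),
        v_min=radius_to_volume(sc.truth["r_min_um"]),
        v_max=radius_to_volume(sc.truth["r_max_um"]),
    )
    report["stages"]["spatial"] = {
        "target_z0_um": sc.truth["target_z0_um"],
        "z0_um": asymmetry_z0(aligned),
        "exponent_truth": sc.truth["exponent"],
        "exponent_fit": pl.exponent,
        "exponent_ci95": list(pl.ci95),
    }

    # --- centrifugation cohorts and force-time collapse
    cohort = synth_cohort(seed=int(rng.integers(2**31)), **cfg["cohort"])
    collapse = force_time_collapse(cohort.series)
    report["stages"]["collapse"] = {
        "viscosity_truth_Pas": cohort.truth["viscosity_Pas"],
        "viscosity_fit_Pas": collapse["viscosity"],
        "per_condition": {str(k): v for k, v in collapse["per_condition"].items()},
    }

    # --- short Brownian-dynamics run
    sim_cfg = SimConfig(seed=int(rng.integers(2**31)), **cfg["sim"])
    summary = run(sim_cfg)
    tau = time_to_displacement(summary)
    report["stages"]["simulation"] = {
        "g_multiple": sim_cfg.g_multiple,
        "final_delta_z_um": float(summary.delta_z[-1]),
        "final_count": int(summary.particle_count[-1]),
        "final_r_median_um": float(summary.r_median[-1]),
        "tau_star_s": tau,
    }

    report["report_hash"] = _hash_report(report)
    return report


def _hash_report(report: dict) -> str:
    import hashlib

    blob = json.dumps(report, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
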