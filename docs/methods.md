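# Methods

## Physical setting and units

The system is the giant nucleus (germinal vesicle, ~400 µm across) of a
large amphibian oocyte, in which liquid-like RNP bodies — nucleoli and
histone-locus bodies — are embedded in a soft nuclear actin meshwork.
Because the bodies are denser than the nucleoplasm (density mismatch Δρ on
the order of tens of kg/m³) and the nucleus is enormous, gravity is a
relevant force: the network does not support the bodies indefinitely but
only slows their creep downward.

All internal arithmetic uses **µm / s / pN / Pa** (1 Pa = 1 pN/µm²). In
these units every quantity of interest is within a few orders of magnitude
of 1, avoiding the underflow that SI values (forces ~10⁻¹³ N, moduli
~10⁻¹ Pa over µm³ volumes) would cause. Standard gravity g₀ = 9.81 m/s² is
a fixed constant; effective gravity is always expressed as a dimensionless
multiple (centrifugation at "100 g" means g_multiple = 100). Thermal
energy kB·T = 4.11×10⁻³ pN·µm at 298 K, scaled linearly for other
temperatures.

## The viscoelastic model

A single three-parameter family describes the network: a Kelvin-Voigt body
(spring E in parallel with dashpot η₂) in series with a dashpot η₁
("extended Kelvin-Voigt"). Its creep compliance is

    J(t) = (1/E)(1 − exp(−tE/η₂)) + t/η₁

— an initial retarded elastic response with retardation time τ = η₂/E,
crossing over to steady flow at rate 1/η₁. In the frequency domain the
complex compliance J*(ω) = 1/(E + iωη₂) + 1/(iωη₁) inverts to

    G′(ω) = Eω²η₁² / (E² + ω²(η₁+η₂)²)
    G″(ω) = (ωη₁E² + ω³η₁η₂(η₁+η₂)) / (E² + ω²(η₁+η₂)²)

These closed forms are implemented directly; the test suite retains an
independent numerical route (a discrete Fourier transform of sampled J(t),
with the non-decaying terminal rate split off analytically) and requires
agreement within 1% across 0.1–3 rad/s, and in practice observes ~10⁻⁶
relative agreement. Typical fitted values for nuclear actin are
E ≈ 0.1 Pa, η₂ ≈ 0.05–0.15 Pa·s, η₁ ≈ 1–2 Pa·s.

## Microrheology estimation

**Oscillatory route.** The drive frequency is known from the force
protocol, so the sinusoid fit is linear: displacement is regressed on
{1, t, sin ωt, cos ωt} (the drift term is on by default because
magnetic-bead experiments commonly drift; it can be disabled), the force
on {1, sin ωt, cos ωt}. The phase lag δ = φ_F − φ_x is wrapped into
[0, π) so δ = 0 is purely elastic and δ = π/2 purely viscous. Moduli
follow from G′ = F₀cosδ/(6πR x₀), G″ = F₀sinδ/(6πR x₀). A trajectory must
span at least two full periods.

**Creep route.** With a constant force F₀, J(t) = 6πR·x(t)/F₀ with
displacement zeroed at force onset. The model fit anchors η₁ on the
terminal slope and E on the terminal-line intercept; a pure-fluid curve
(no resolvable elastic step) is flagged `degenerate_E` with an unbounded
upper E interval, and a window shorter than three retardation times flags
`eta1_unconstrained`.

**Simultaneous weighted fit.** G′ and G″ are fitted jointly with one
parameter set in log-parameter space (positivity by construction), using
inverse-variance weights when per-point uncertainties are given and
uniform weights on log-moduli otherwise (treating the decades of a
spectrum evenly). Initialisation: η₁ from the low-frequency G″/ω, the
series viscosity η₁η₂/(η₁+η₂) from the high-frequency G″/ω, E from the G′
plateau; three random restarts guard against local minima. 95% CIs come
from a seeded parametric bootstrap (default 200 replicates) because the
interval-construction method behind published fit CIs is generally not
stated; the suite checks per-parameter coverage ≥ 90% under 10% noise.

**Bead radius.** The default is 1.4 µm (2.8-µm-diameter superparamagnetic
beads); a 1.5-µm imaging-based preset is also provided since both values
circulate for the same beads.

**Lissajous analysis.** The force-displacement loop is fitted with the
numerically stable partitioned direct ellipse fit (Halir–Flusser); the
enclosed area πF₀x₀sinδ is the energy dissipated per cycle. Collinear
loops (δ = 0) are returned as degenerate with zero area rather than an
error.

## Nucleus geometry and spatial statistics

The analysis chain mirrors how 3-D image stacks are reduced: per-plane
segmentation summaries → ellipsoid fit → sphere normalisation →
gravitational-axis alignment → statistics.

* **Ellipsoid fit**: the per-plane record carries z, centre and in-plane
  semi-extents; an *axis-aligned* ellipsoid is fitted by least squares on
  the slice-extent profile semi(z) = a√(1 − ((z−z₀)/c)²). Areas alone
  cannot separate the two equatorial semi-axes, which is why the plane
  record keeps extents (areas are available as πs₁s₂). The axis-aligned
  assumption matches imaging geometry (the optical axis defines z); an
  obliquely tilted nucleus would need a rotational pre-registration that
  is out of scope.
* **Sphere normalisation**: the ellipsoid is mapped to a sphere whose
  radius is the geometric mean of the semi-axes — a volume-preserving
  choice that avoids systematically inflating or shrinking distances —
  and the same linear map is applied to all body positions (body radii
  are not rescaled).
* **Axis alignment**: the apparent gravitational axis is the vector from
  the nucleus centroid to the mean body position; a proper rotation
  (Rodrigues form, det +1) maps it onto −z, and coordinates are
  re-origined so z = 0 is the nucleus bottom. A cloud whose mean
  coincides with the centroid (within 10⁻⁹ µm) gets the identity rotation
  and a degenerate-axis flag.
* **z₀** is reported as the absolute distance between mean body z and the
  nucleus centre; the signed mean is retained for Δz arithmetic, which
  needs direction (Δz = reference mean z − cohort mean z, positive
  downward).
* **Density profiles** use 20-µm bins from the nucleus bottom and are
  normalised to unit mass.
* **Creep velocity** is the through-origin slope of Δz versus time — Δz
  is defined as zero at t = 0 by construction, so a free intercept would
  only absorb noise — with a t-based CI.
* **Force–time collapse**: each condition's Δz is plotted against
  u = (2/9)Δρ·g₀·g·R²_med·t (units Pa·µm, so Δz = u/η); a pooled
  through-origin regression gives the apparent long-time viscosity, and
  per-condition viscosities are returned for the consistency check that
  centrifugation does not alter the material. The *median* body radius
  drives the scaling (robust to the heavy size tail); Δρ is a required
  parameter defaulting to 50 kg/m³, a value of the order measured for
  nucleoli against nucleoplasm — every result that scales with Δρ (the
  collapse viscosity does not; τ* does) must be read against this
  default.
* **Size distributions** are fitted as a truncated continuous power law
  p(V) ∝ V^α on [v_min, v_max] by maximum likelihood (binned least
  squares is biased and is kept only for display, in log-spaced bins);
  the 95% CI is the χ²₁ profile-likelihood interval, and the MLE is
  tested against a brute-force grid search of the same likelihood.
* **Gaussian sizing**: a body's radius is half the FWHM of a Gaussian
  fitted to its brightest-plane intensity profile, radius = σ√(2 ln 2).
* **Correlations** are Pearson r with the Fisher-z interval
  tanh(atanh r ± 1.96/√(n−3)); |r| = 1 inputs are flagged degenerate with
  a collapsed interval.

## Brownian-dynamics simulator

Bodies live in a 2-D (x, z) box with reflecting walls but carry 3-D
volumes; collision radius, drag radius and buoyant weight all use
R = (3V/4π)^(1/3), the only reading that keeps 2-D dynamics, volumetric
fusion and Stokes drag mutually consistent. The per-step overdamped update
is Δx = ξ_x, Δz = −(VΔρ·g·g₀/ζ)Δt + ξ_z with ζ = 6πη₁R and ξ i.i.d.
Gaussian with variance 2(kBT/ζ)Δt per axis. Only the long-time viscosity
η₁ enters: on simulated timescales the Kelvin-Voigt retardation (τ ~ 1 s)
has fully relaxed, so short-time elastic caging is deliberately absent.
No hydrodynamic interactions, droplet deformation or Ostwald ripening.

Defaults: 400-µm box (nucleus diameter; configurable and logged),
1000 bodies, volumes power-law distributed with exponent −1.5 on
1–4000 µm³ (radii ~0.6–10 µm, median ~1 µm — the observed nucleolar size
scale), η₁ = 2 Pa·s (the long-time network viscosity used for the
simulated predictions), Δρ = 50 kg/m³, 298 K. At these defaults 1 g creep
reaches the disruption scale in ~10⁶–10⁷ s, i.e. the weeks-to-months
regime that matches oocyte lifetime.

The timestep keeps one step's drift plus 3σ of Brownian motion below half
a particle diameter, evaluated at both volume bounds (small particles are
diffusion-limited, large ones drift-limited), capped at t_end.

Fusion merges every overlapping pair (centre distance < R_i + R_j) in
ascending-distance order, iterating to a fixpoint; the merged body takes
the combined volume and the volume-weighted centroid (momentum-free,
symmetric), clamped to wall clearance. Neighbour search uses a k-d tree
queried at the maximum diameter.

**Recorded displacement.** The summary's Δz is the downward shift of the
*volume-weighted* mean body position. The number mean is not fusion-safe:
coalescence concentrates where bodies crowd (the floor), and merging two
low-z bodies into one raises the number mean, producing non-monotone and
even negative Δz. The volume-weighted mean is exactly invariant at each
fusion event and measures net mass transport; with it the early-time Δz(t)
at 1 g is linear to R² > 0.999. For the same reason the *median* radius is
not guaranteed monotone (floor coalescence can remove above-median bodies);
the exact coarsening invariant is the mean body volume (conserved total
volume over a non-increasing count), which the tests assert, and the
median still grows over a long 1 g run.

**Disruption time τ\*.** `time_to_displacement` interpolates the first
crossing of a threshold, default 200 µm (the nucleus radius). In the
default 400-µm box the mean displacement saturates just below 200 µm (the
mean starts at the box centre), so scaling studies (τ* ∝ 1/g, τ* ∝ η₁)
measure the crossing at 100 µm; in the drift-dominated regime the scaling
is threshold-independent. Crossing times at high g can sit inside one
sampling interval, so scaling tests sample densely (interval ≪ τ*).

## Synthetic-data generators

Every generator is deterministic under its seed and embeds its generating
truth in the returned object, making estimator round-trips testable.

* Bead trajectories are exact single-mode linear responses of the model
  (amplitude F₀/(6πR|G*|), phase atan2(G″, G′); creep x = F₀J(t)/6πR)
  plus additive Gaussian noise. Defaults stay in the experimental
  envelope: 0.02–1 Hz, 0.2–1.75 pN.
* Nucleolus clouds sample positions in the volume-equivalent sphere from
  a uniform density tilted by exp(−(z+R)/λ), with λ solved numerically so
  the expected mean-z offset equals the requested z₀ (a one-parameter,
  monotone family chosen because no generative form for the observed
  asymmetry is established); positions are then mapped to the requested
  ellipsoid — the exact inverse of the analysis pipeline's normalisation.
  Default nucleus semi-axes (220, 200, 180) µm. Radii are drawn
  independently of depth; real sedimenting nuclei correlate size with
  depth, so passing round-trips validate the estimators, not that
  biology.
* Centrifugation cohorts displace each nucleus by the Stokes-creep mean
  Δz = u/η (analytic median radius of the size law) plus optional
  per-nucleus scatter, using the experimental schedule (10 g up to 14 h,
  100 g up to 100 min, 1000 g up to 20 min); bodies pushed below the
  floor are clamped to it, mimicking the sedimented phenotype.

What passing tests therefore show: the estimators invert the stated
generative models to their stated tolerances, and the simulator obeys its
physics limits (Stokes drift at T = 0, MSD = 4Dt at g = 0, τ* ∝ 1/g and
∝ η₁). What they do not show: performance under segmentation errors,
tracking noise correlated in time, size-depth coupling, or nucleus shapes
far from an axis-aligned ellipsoid.

## Problem sizes

Test and acceptance computations run at desk scale by choice: refits use
301 creep samples / 10 frequencies (noise-free round-trips are exact
regardless of n); recovery studies use 500-body clouds (z₀ to ±5 µm),
10⁵ volume samples (exponent to ±0.05) and 100-replicate noise studies;
simulator checks use 500–1000 bodies over 10³–10⁵ simulated seconds with
5 seeds for scaling ratios. These sizes hold every stochastic tolerance
with margin while keeping the full suite under a minute of CPU apart from
the simulation scaling tests.
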