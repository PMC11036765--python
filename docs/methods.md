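# Methods

## Scope and modelling philosophy

`kneestrain` is a reduced-order (desk-scale) model of tibiofemoral
mechanics focused on one output: strain in the anterior cruciate ligament
(ACL) bundles under quasi-static bench loads and dynamic single-leg
landing. Everything that does not materially change that output at this
scale is simplified away: bones are rigid, cartilage and menisci appear
only through compliant contact and horn-attachment springs, ligaments are
straight line elements, and the patellofemoral joint is condensed into a
force-transmission rule. The model is generic, not subject-specific; its
geometry is parametric and placed from published anatomical ranges.

## Coordinates and kinematics

Right knee, right-handed frames: X anterior, Y proximal, Z lateral. The
femur frame is the joint frame; the tibia carries six joint coordinates
(tx, ty, tz in mm; flexion, valgus, internal rotation). The rotation is
the floating-axis (Grood–Suntay-style) composition
`R = Rz(−flexion) · Rx(−valgus) · Ry(internal)`, i.e. flexion about the
femoral lateral axis, internal rotation about the tibial long axis, valgus
about the floating anterior axis. Angles are degrees at every API surface
and radians internally. Units are mm, N, N·mm throughout.

## Ligaments

Bundles are straight, tension-only, and carry the piecewise law

    f(ε) = 0                      ε ≤ 0
    f(ε) = k ε² / (4 ε_l)         0 < ε ≤ 2 ε_l
    f(ε) = k (ε − ε_l)            ε > 2 ε_l

with `k` the linear-region stiffness (N per unit strain) and `ε_l` the
toe-to-linear transition strain (default 0.03, the standard value for this
element type; the source model never tabulates it per bundle). The law is
C¹ at `2 ε_l`; its strain energy has the closed form used by the energy
ledger. Per-bundle `k` and reference strain ship in
`src/kneestrain/data/bundle_parameters.csv` (classic 1-D element
literature values; ACL pre-strains 6 % AM / 10 % PL at extension — the
AM/PL assignment follows the bundles' flexion behaviour and is flagged in
the file). Pre-strain initialization sets `L0 = Lr / (1 + ε_r)` at the
full-extension reference pose, so the configured pre-strain is reproduced
exactly there. No bone wrapping: a bundle is a chord between insertions.

The default insertion geometry encodes the two classic cruciate facts:
the AM femoral site lies ~0.8 mm from the condylar (flexion) axis, making
the bundle near-isometric through flexion, while the PL femoral site lies
~7 mm from it, so PL slackens strongly as the knee flexes.

## Contact

Each femoral condyle is a sphere (r = 24 mm, centers ±22 mm from the
midline); each tibial facet is a concave spherical socket with 45 mm
clearance (socket radius 69 mm) — an effective congruency standing in for
cartilage + meniscus conformity. Contact is a frictionless normal penalty:
force = stiffness × penetration (8000 N/mm default, a numerical
regularization of much stiffer cartilage-on-bone contact). The socket
axis is tilted 10° posteriorly (the posterior tibial slope): the plateau
surface falls toward its posterior edge, so axial compression produces
the physiologic anterior tibial shear. The clearance sets the
anterior–posterior compliance under load (restoring force ≈ N·x/clearance
for contact load N and shear offset x) and was chosen together with the
slope during the one-time landing calibration described below.

## Muscle and load transmission

Muscle forces are inputs (no redundancy solving). Their reduced-order
lines of action:

* **Quadriceps** — transmitted through a rigid patellar tendon to the
  tibial tubercle; the tendon–shaft angle is `28° − 0.4·flexion(°)`, so the
  quadriceps is an anterior-shear (ACL-antagonist) load at low flexion and
  crosses to posterior past ~70°. The patellar ligament/MPFL/LPFL springs
  are carried in the model but the massless patella's equilibrium is
  condensed into this rule (rigid-tendon assumption).
* **Hamstrings** — tension from a posterior proximal tibial site toward a
  proximal-posterior femoral-shaft point (posterior shear + compression).
* **Gastrocnemius** — tension from a distal shank site toward its
  posterior femoral origin: knee compression, a flexion moment, and a net
  anterior drive at low flexion (ACL antagonist).
* **GRF** — the vertical ground reaction is applied as axial compression
  along the tibial shaft (the shank transmits it to the joint), which
  loads the ACL through the posterior slope.
* **Ankle plantar-flexion moment** — mapped to a posterior force
  `M / lever` (lever 300 mm) at the proximal tibia: the soleus mechanism
  that rotates the proximal tibia posteriorly. This mapping is the
  package's documented answer to an under-specified load path; the lever
  is a config parameter.
* **Hip moment/angles** — the femur is grounded, so hip-side kinematics
  enter only through the prescribed knee-flexion trajectory and the
  regression descriptors; the hip moment is a descriptor, not an applied
  load.

## Solvers

**Statics.** Equilibrium is solved on the free joint coordinates
(prescribed coordinates are displacement boundary conditions) by driving
the generalized force residual below 1e-6 N (translations) / 1e-6 N·mm
(rotations): a quasi-Newton root find (hybr), a damped-Newton polish with
backtracking, a trust-region least-squares restart for the slack/taut
kinks, and — for strongly displaced equilibria — overdamped pseudo-dynamic
relaxation plus load continuation. Initial guess defaults to the reference
pose; sweeps warm-start from the previous solution.

**Dynamics.** Semi-implicit Euler on the joint coordinates with a diagonal
generalized inertia (shank mass 3.6 kg; flexion/valgus inertia
0.35 kg·m², axial 0.03 kg·m²) — a point-inertia simplification of full
rigid-body dynamics, adequate because the model operates near-critically
damped, tracking the quasi-static response rather than resolving impact
ringing. Viscous damping is sized per coordinate as `2ζ√(k̂ m)` from a
local stiffness estimate (ζ = 0.9 default). The step (2e-4 s default) is
checked against the stability bound. An energy ledger (work of applied
loads + work of the flexion constraint = ΔKE + Δelastic + dissipated) is
accumulated every step; landings close it to well under 2 %.

## Validation protocols

Four bench protocols run on the default knee: flexion 0–90° under a 600 N
hamstring force; Lachman (30°) and anterior drawer (90°) with anterior
tibial force up to ±200 N; abduction moment to 50 N·m at 25° flexion with
axial rotation constrained (pure abduction). Because the published
experimental curves these tests are classically compared against are not
redistributable data, the package asserts the qualitative surface — PL
slackens monotonically with flexion, AM drops slightly then plateaus
(never re-tightening by more than 1 % strain), anterior-load strains are
monotone in the load, valgus grows monotonically with moment, ACL strain
rises with abduction moment — and provides `compare_curves` (Pearson r,
RMSE after linear resampling) for user-supplied reference CSVs.

## Synthetic landing cohort

The generator emulates the boundary conditions of a 10-participant
single-leg jump-landing panel: single-burst quadriceps / hamstrings /
gastrocnemius force curves (monotone-segment cubic splines through onset /
peak / decay knots, clipped at zero), hip and ankle moment bursts, smooth
trunk / hip / knee / ankle angle excursions, and a GRF spike (half-cosine
rise, exponential decay to body weight). Touch-down is the first GRF
sample above 10 N. A latent "landing softness" factor couples the postural
angles (soft landers flex trunk, hip, knee and ankle together and see
slightly lower GRF), which gives the downstream regression realistic
collinearity. Summary descriptors (angles at peak GRF, max knee flexion,
peak forces/moments, knee velocity) are always recomputed from the curves.

Cohorts are sampled with a Latin-hypercube design: each envelope variable
is drawn from independently permuted quantile strata across the n
participants. A 10-profile surrogate panel should span the envelope the
way a designed participant set does; iid sampling would let the cohort
mean wander between seeds for reasons unrelated to the mechanics. Plain
iid sampling is available via `stratified=False`.

Default envelopes (e.g. quadriceps 2600 ± 500 N peaking 70 ms after
touch-down, GRF 3.25 ± 0.4 body weights at ~45 ms, ankle plantar-flexion
moment 200 ± 35 N·m, knee flexion 18° at touch-down rising to 55 ± 8°,
10 % muscle pre-activation at touch-down) are plausible ranges for
recreational single-leg landings. They are surrogates, not measured data.
The contact clearance/slope and these envelopes were calibrated once, as
a set, so that the default cohort's landing outputs sit at the headline
scale of the in-vivo/in-silico literature (cohort-mean peak relative ACL
strain ≈ 3.5 % with the ankle moment, ≈ 5.4 % without); the *direction*
of every effect (ankle moment relief, quadriceps antagonism, slope-driven
shear) emerges from the mechanics and survives any reasonable
re-parameterization. What passing tests on this cohort do **not** show:
subject-specific accuracy, frontal-plane injury mechanics, or the
between-participant strain dispersion of real panels (the synthetic
cohort's sd of peak strain, ±0.5–1.3 %, is narrower than the ±2.2–2.6 %
typical of real profile panels — real boundary-condition sets are rougher
than any smooth spline family).

## Landing simulation and strain metric

Knee flexion follows the profile trajectory as a displacement boundary
condition (hip-side motion is absorbed there); the remaining five tibial
coordinates respond dynamically to the muscle forces, GRF compression and
(optionally) the ankle moment. Relative ACL strain uses the touch-down
gauge: `(L(t) − L_td)/L_td`, maximized over the 250 ms landing window
(window length is a config parameter; the event itself is over in
~100 ms). Both bundles are reported; the headline value is the larger
bundle peak, and the identity
`rel = (1 + ε_abs(t))/(1 + ε_abs(td)) − 1` links it to the slack-length
gauge. The ankle-moment on/off comparison re-runs the identical profile
with the ankle channel zeroed.

## Statistical pipeline

Peak strains are z-normalized (sample sd, n−1) for screening; bivariate
Pearson r with two-sided p from the t distribution (n−2 df) screens the
sagittal-plane candidates; the strain response is Box–Cox transformed
(λ maximizing the profile log-likelihood on a 401-point grid over [−2, 2]
plus a bounded polish; λ = 0 is the natural log) and fitted by OLS. The
"contribution" column is a sequential (type-I) decomposition in the
canonical predictor order (trunk, max knee flexion, ankle, hip) and sums
with the error share to 100 ± 0.1 %.

`predict_peak_strain` evaluates the published four-angle equation
(constant 9.09; coefficients +0.0701 knee, −0.2661 ankle, −0.1362 hip,
−0.1649 trunk; ln of percent strain). Two documented judgment calls:
(1) strain units are percent — the constant is dimensionally inconsistent
with fractional strain; (2) prediction always uses the ln branch because
the equation is published on that scale, while fitting reports its
estimated λ so users can check consistency. The positive knee-flexion
coefficient makes predicted strain *rise* with deeper maximum knee
flexion, in tension with the soft-landing interpretation of the other
three signs; the equation is evaluated exactly as published and the
tension is noted rather than resolved. Fitting the pipeline to the
synthetic cohort does not reproduce the published coefficients or
R² ≈ 0.90 — that would require the original participants' data — and no
such claim is made; parameter-recovery tests instead verify the pipeline
on cohorts simulated from known coefficients (noiseless recovery exact to
1e-8; 95 % CI coverage of every coefficient in ≥ 90 % of replicates).

## Numerical choices and degenerate inputs

* Static residual tolerance 1e-6 (N, N·mm); solver failures carry the
  last residual.
* Dynamics dt = 2e-4 s default, validated against the stability bound and
  by a halve-dt convergence check (< 1 % change in peak strain).
* Ties/initialization: statics start from the reference pose; sweeps
  warm-start; the landing settles statically at the first profile sample.
* Zero inter-insertion distance at initialization, non-positive
  constitutive parameters, constant inputs to z-normalization,
  non-positive values into Box–Cox, rank-deficient designs, mismatched
  cohort arms, and single-profile arms all raise typed errors.
* Gimbal: the floating-axis extraction warns at |valgus| → 90° (far
  outside physiology).

## Known limitations

Sagittal-plane focus (no plant-and-cut / frontal-plane injury mechanics);
no deformable tissues, so contact pressures and meniscal stresses are out
of scope; ligaments are chords (no wrapping, no MCL–meniscus
interaction); the patellofemoral joint is a transmission rule, not a
joint; the ankle-moment-to-knee load path is a one-parameter mapping; the
synthetic cohort under-disperses between-participant strain variability;
and the generic geometry means absolute strain values carry the usual
reduced-order caveat — trends and comparisons are the model's currency.
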