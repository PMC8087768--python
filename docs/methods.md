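# Methods

This note documents the model, the synthetic-data design, the numerical
choices, and the known limitations of the package.  Everything stated here
is computed by the test suite or `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## Link-segment model

The lower limb is a planar (sagittal) three-segment chain — foot, shank,
thigh — with x fore-aft (+ = travel direction), y vertical (+ = up).  Net
joint moments come from the standard distal-to-proximal free-body recursion:
the foot free body carries the GRF applied at the centre of pressure, the
foot weight, and the foot inertial terms (`m a_com`, `I α`), and yields the
ankle joint force and moment; the shank and thigh follow with the reaction
of the joint below.  Mediolateral forces are ignored.  Reported moments are
*extensor positive* (plantarflexor at the ankle); `g = 9.81 m/s²`.

Segment inertial parameters default to Winter-style anthropometric
proportions (mass fractions 0.0145 / 0.0465 / 0.100 of body mass for foot /
shank / thigh; COM at 50 / 43.3 / 43.3 % of segment length from the
proximal end; gyration radii 47.5 / 30.2 / 32.3 % of length).  They are
config-overridable because the literature source prints several variants.

Joint angles are included angles between adjacent segment vectors: straight
knee = 180°, neutral ankle (shank ⊥ foot) = 90°.  The hip angle is measured
against the downward vertical because no trunk marker exists in the marker
set; this stands in for a trunk segment and only matters for the hip
moment-arm polynomial, not for the moment recursion.

### Muscle forces

Extensor muscle-group forces solve the bi-articular moment system

    M_ankle = F_ankle · r_ankle
    M_knee  = F_knee · r_knee − F_G·r_G,knee − F_H·r_H,knee
    M_hip   = F_hip  · r_hip  − F_RF·r_RF,hip

with the bi-articular forces tied to their parent groups by PCSA fractions
(`F_G = 0.35 F_ankle`, `F_H = 0.40 F_hip`, `F_RF = 0.25 F_knee`, defaults
config-overridable).  Substituting the fractions leaves a linear 2×2 system
in (F_knee, F_hip) per frame, solved in closed form; a symbolic (sympy)
solution of the full system is the test oracle.

Moment arms r(angle) are polynomials about a per-joint reference angle,
scaled per subject: the ankle polynomial is anchored to the subject's
measured static AT moment arm at the neutral angle; hip/knee arms scale
with hip height.  The coefficients are deliberately configuration, not
constants: the published regressions they stand for exist in several forms,
so the dependence is explicit and swappable.  Positivity over the
physiological range is enforced at evaluation time.

### External moment arm of the GRF

`R_Ankle = ∫ GRF · r_Ankle dt / ∫ F_Ankle dt` over stance, with GRF the
resultant ground-reaction magnitude and r_Ankle the instantaneous AT moment
arm — the ratio exactly as defined, which yields values of order
`r²/lever` (~1 cm), not the geometric COP-to-ankle lever (~10 cm).  A
config switch (`external_arm_integrand = "cop"`) substitutes the
instantaneous COP-to-ankle lever in the numerator for users who want the
geometric external arm; the default follows the ratio definition.

### Tendon chain

Per support phase: plantarflexor force impulse `J_F = ∫ F_ankle dt`; mean
stress `σ = (J_F / T_stance) / CSA`; peak stress `max F / CSA`; strain
`ε = σ / E` with `E = 819 MPa` (mean human AT); `ΔL = ε L₀`; recovered
energy `W = ½ F̄ ΔL × 0.93` with `F̄ = J_F / T_stance` and 0.93 the tendon
resilience.  Dimensional note: an impulse divided by area is Pa·s, not Pa;
the package therefore time-averages the impulse by default so stresses are
in MPa, and offers the literal impulse/CSA form behind
`stress.raw_impulse`.  The same time-averaged force drives the Hookean
energy so W is in joules.  Negative mean stresses (net dorsiflexor impulse;
not produced by realistic steps) are clipped to zero before the
strain/energy chain, which keeps the Hookean model in its tensile regime.

SNW = |W⁺ + W⁻| / (|W⁺| + |W⁻|) per joint, with W⁺/W⁻ the trapezoid
integrals of the positive/negative parts of `M·ω`; because the two parts
sum to the power pointwise, W⁺ + W⁻ equals the integral of power to
round-off.  A step with zero work at a joint raises an undefined-SNW error
and is excluded from statistics.

## Signal processing

"4th-order zero-lag Butterworth" is interpreted as a 2nd-order pass run
forward and backward (`filtfilt`), the common gait-lab reporting
convention; `order_is_per_pass=True` selects 4th order per pass instead.
At the cutoff frequency the forward-backward pair is −6 dB by construction.
Decimation from 1 kHz to 500 Hz keeps every 2nd sample starting at sample 0
(phase-aligned with kinematic frames) after the 100 Hz force filter has
acted as the anti-alias stage.  Stance = maximal runs of vertical GRF ≥
20 N lasting ≥ 50 ms (both configurable; the event-detection rule is a
design choice, not a measured constant).  Accelerations use the central
second-order stencil with one-sided second-order stencils at the record
ends; differentiation happens over the whole trial *before* windowing, so
stance edges never see one-sided stencils.  Integrals use the composite
trapezoid rule.

## Synthetic cohorts

The generator emulates a 24-subject unshod over-ground cohort at five
self-selected speeds with 1 kHz force plates and 500 Hz motion capture.

**Morphometrics.** Body mass ~ N(64.15, 9.84²) kg; AT moment arm drawn
conditionally on mass (latent ρ = 0.70, attenuated by range truncation to a
realized cohort correlation ≈ 0.6) and truncated to 3.12–5.01 cm; tendon
CSA ~ N(0.61, 0.15²) cm², *independent of body mass* — a CSA–mass link
combined with the mass–moment-arm correlation would build a structural
moment-arm → stress/CSA channel into cohorts that are supposed to be null.
Resting tendon length ~ N(20, 1.5²) cm, independent of stature for the same
reason.  Hip height and foot length follow mild allometric relations with
scatter; sex is drawn at the cohort's 17 F : 7 M proportion and is
decorative (no field depends on it).

**Stance kinematics.** The ankle is anchored while the shank and thigh
rotate over it with a smooth monotone progression warp; the rotation
amplitude is solved (1-D root find on the monotone branch) so the hip
marker advances exactly `speed × stance duration`, with speed drawn from
the per-gait Froude distribution (means 0.130 / 0.245 / 0.362 / 0.662 /
1.086, SDs as configured, truncated at ±2 SD).  Knee flexion follows a
mid-stance bump.  The included ankle angle dorsiflexes then plantarflexes
as `θ̇ ∝ d − sin(2πu)`; the asymmetry d is calibrated per step by inverting
an idealized SNW map whose moment proxy is the gait's GRF shape times the
COP-lever profile, plus a per-gait logit-scale offset measured once from
forward calibration runs so realized cohort-mean ankle SNW lands on the
per-gait study values (0.450 / 0.367 / 0.231 / 0.447 / 0.755).  Late-stance
heel rise lifts the ankle smoothly so the metatarsal head stays near the
floor.

**Forces.** Vertical GRF is one raised-cosine lobe (jog/run/sprint, peaks
2.25 / 2.45 / 2.70 × body weight with ±5% step jitter clipped to keep run
peaks in 2.2–2.8 BW) or two overlapping lobes (walking gaits, ~1.1 BW per
peak); fore-aft force is braking-then-propulsive with near-zero net
impulse; the COP travels monotonically heel → toe over the foot.  Marker
noise 1 mm SD and force noise 2 N SD are additive Gaussian, zero-able for
oracle runs.  Stance durations default to 0.65 / 0.55 / 0.30 / 0.25 /
0.18 s with ±8% jitter; these are plausible defaults, not measured claims.

**Ground truth.** Each trial carries joint moments computed *forward* from
the constructed markers and forces by an independent frame-by-frame
Newton–Euler code path using the same equations the pipeline inverts
("shared-equation oracle").  With noise and filtering off, pipeline moments
reproduce the truth to better than 1e-6 relative (empirically to round-off).
The static standing fixture uses near-massless segments: the identity
`M_ankle = f_z (COP_x − ankle_x)` is exact only in the weightless-linkage
limit and isolates the GRF pathway of the recursion.

**Effect injection.** The moment-arm mechanism enters through two channels
at running/sprinting gaits: (i) the per-step ankle-SNW target shifts by
+0.15 per SD of moment arm (composed on the logit scale so targets never
pile up at a boundary), and (ii) foot strike shifts forefoot-ward for
shorter arms (COP start −0.10 foot lengths per SD of arm), which raises the
external lever and hence the tendon load on top of the intrinsic `F = M/r`
dependence.  Channel strengths were chosen so the realized step-level
correlations land in the band such cohort studies report (≈ 0.3–0.6 in
magnitude) with enough margin to be reliably detected in a 24-subject
cohort.  With injection *off* (null cohorts) both channels are removed and
the per-subject GRF is scaled by `arm / mean arm`, which cancels the 1/r
dependence of the tendon force; mass-specific stress and energy are then
independent of the moment arm by construction.  Note the intrinsic `F=M/r`
channel operates at *all* gaits in injected cohorts, so slow-gait stress
correlations are weakly negative in the generator even though the injected
channels are restricted to run/sprint.

**What the generator does not emulate:** marker dropouts and soft-tissue
artefact, double support on adjacent plates, 3-D kinematics, footwear,
step-to-step speed drift within a trial, muscle co-contraction, and any
force–velocity or activation dynamics.  Passing tests therefore validate
the computational chain and its statistical behaviour under the stated
conditions, not the physiology of real tendons.

## Statistics

Directional hypotheses are fixed a priori: the ankle-SNW / moment-arm
correlation is tested one-tailed positive; mass-specific stress and energy
one-tailed negative.  `t = r √(df / (1 − r²))`, df = n − 2, with the
p-value from the t tail in the stated direction.  Correlations are computed
both with steps pooled within gait (step-level df, matching how such tables
are conventionally printed) and on subject means.

The mixed model is `y = Xβ + u_subject + ε` with one random-intercept
variance component, fitted by maximum likelihood (statsmodels MixedLM; the
optimizer falls back bfgs → lbfgs → cg → powell on Hessian failures) with
Wald z tests.  Fixed effects are z-scored so β are standardized weights.
REML, Satterthwaite/Kenward–Roger df and the package-specific F
conventions of any particular mixed-model implementation are non-goals.

**Multiple comparisons in the null recovery battery.**  The recovery
experiment runs 5 seeds × 2 gaits × 3 outcomes = 30 directional tests on
null cohorts.  At an uncorrected α = 0.05 — worse under within-subject
clustering of repeated steps — at least one false positive would be the
expected outcome of a correctly null generator.  The null battery is
therefore evaluated on subject means (honest test size under repeated
steps) with Holm family-wise correction across the whole battery; the
injected-effect checks use the conventional pooled step-level tests, where
the true effects are large.  This design was fixed before the experiment
was first run.

## Problem sizes and runtime

Recovery experiments use 24 subjects × 2 gaits (run, sprint) × 4 steps per
cohort, 5 seeds, injected and null (≈ 1 900 trials end to end, ~15 s);
the full-cohort summary uses 24 × 5 × 3 = 360 trials; the mixed-model
recovery uses 50 subjects × 10 steps.  These sizes give stable estimates
while keeping the whole suite fast.

## Known limitations

- The hip "included angle" uses the vertical in place of a trunk segment.
- The literal external-arm ratio yields centimetre-scale values (see
  above); users wanting the geometric lever must switch the integrand.
- The SNW calibration map is idealized (no inertial terms), so realized
  per-gait SNW means track the targets to a few hundredths, not exactly.
- Bi-articular moment arms default to constants; only the mono-articular
  polynomials vary with angle.
- The generator's anchored-ankle construction makes the stance foot
  quasi-stationary; true push-off translation of the ankle is approximated
  by the heel-rise lift only.
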