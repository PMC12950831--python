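# Methods

## The screening problem

An esophageal balloon catheter measures Pes as a surrogate for pleural
pressure. Its validity is checked by occluding the airway during an
inspiratory effort: with no flow there is no resistive or elastic pressure
drop across the lung, so the airway pressure deflection ΔPaw equals the
pleural deflection, and ΔPes/ΔPaw ≈ 1 indicates correct placement and
filling. The package analyses two variants on a common footing:

* the prolonged expiratory occlusion (reference): ΔPaw/ΔPes taken at the
  Paw nadir of the occluded effort;
* the P0.1 maneuver (screen): the occlusion is released 100 ms after effort
  onset, and both deflections are read at that single 100 ms point.

A ratio strictly inside (0.75, 1.25) is classified `correct`, anything
else `incorrect`; both bounds are strict, so 0.75 and 1.25 themselves are
`incorrect`.

## Waveform model

Breaths are simulated with a single-compartment equation of motion,

    R·V̇(t) + V(t)/C = Paw_applied(t) − PEEP + Pmus(t),

integrated by forward Euler at dt = 5 ms (200 Hz, the ventilator export
rate). dt is small against adult respiratory time constants
(R·C ≈ 0.15–0.9 s for the default ranges), so the explicit scheme is
adequate; a diverging state (time constant unresolvable at 200 Hz) raises a
simulation error rather than returning garbage.

Muscle pressure is a half-sine deflection, Pmus(t) = p_max·sin(π·t/t_insp)
on 0 ≤ t ≤ t_insp — the standard lung-simulator convention, chosen because
it gives the P0.1 of a clean breath in closed form:

    P0.1_true = −p_max·sin(0.1·π / t_insp).

Pressure support is flow-triggered (threshold 0.05 L/s), pressurizes over a
0.15 s linear ramp, and cycles off at 25 % of peak inspiratory flow.

During an occlusion, flow is identically zero, volume is constant (to
machine precision — an invariant under test), and the measured airway
pressure is PEEP − Pmus(t): a complete occlusion transmits the full pleural
swing to the airway. The pleural swing itself is
ΔPpl(t) = −Pmus(t) + V(t)·E_cw/1000 (chest-wall recoil term in mbar/L).

The measured esophageal signal condenses every balloon-state question into
a transmission factor λ:

    Pes(t) = offset + λ·ΔPpl(t) + A_c·sin(2π·f_c·t + φ) + ε(t),

with a cardiac-oscillation artifact of amplitude A_c (phase φ drawn once
per breath) and white sensor noise ε. λ = 1 is an ideally placed, ideally
filled balloon; the classification rule is a pure ratio threshold, so λ is
a sufficient ground-truth parameter for correct vs. incorrect placement.
The mapping from physical blocking volume to transmission is deliberately
not modelled — λ is the abstraction, not a calibrated filling curve.

## Measurement conventions

* **Baselines.** Paw and Pes baselines are means over the 0.25 s
  immediately preceding the maneuver window — above quantization noise,
  short enough to sit inside the quiet end-expiratory phase.
* **Effort onset.** First sample in the window at which Paw falls 0.2 mbar
  below baseline and stays below for 50 ms. 0.2 mbar is well below
  physiological effort sizes; the sustain requirement rejects single-sample
  noise. No qualifying sample marks the maneuver unusable.
* **Occlusion deltas.** ΔPaw = Paw nadir over [onset, window end] −
  baseline; ΔPes is sampled *at the Paw-nadir time* (synchronous-swing
  criterion) rather than at an independent Pes nadir, which would bias
  ratios upward under cardiac artifact.
* **P0.1.** The deflection is read at onset + 100 ms, clamped to the window
  end. The clamp is deliberate: the valve reopens 100 ms after the *true*
  effort onset, while threshold-based onset detection fires a few
  milliseconds late, so the nominal onset + 100 ms point can fall just past
  the release; the release boundary is physically where the ventilator
  reads P0.1. Fewer than 75 ms of occluded signal after the detected onset
  is a measurement error. For the P0.1 ratio, ΔPaw is the 100 ms deflection
  (the P0.1 itself) and ΔPes the Pes deflection at the same sample — the
  principal interpretive assumption of the analysis.
* **End-expiratory Pes.** A 50 ms mean centred 0.5 s before effort onset
  (a single sample would be needlessly noise-sensitive).
* **Detection.** Maneuver windows are maximal zero-flow intervals
  (|flow| < 0.02 L/s) containing a Paw deflection > 0.5 mbar below the
  local pre-interval baseline, trimmed outward to where the deflection
  vanishes (0.05 mbar): the window start then coincides with the effort
  onset. Deflected windows of 0.08–0.15 s are labelled P0.1, ≥ 0.3 s
  occlusion, others discarded. No cardiac filtering is applied in the
  default path (a low-pass hook would be the natural extension point; the
  analysis here is deliberately of unfiltered signals).

## Screening cascade and diagnostics

Each P0.1 measurement is paired with the nearest *subsequent* occlusion of
the same patient (acquisition order: P0.1 maneuvers precede their reference
occlusion). Three pure-predicate filters follow; being predicates, the
retained set is order-invariant, and the recorded exclusion reason follows
the canonical order:

1. comparability: |ΔPes_end-exp| between the paired maneuvers must not
   exceed 20 % of the occlusion's end-expiratory Pes (the reference arm is
   the natural denominator); a reference value below 0.5 mbar makes the
   relative rule indeterminate and excludes the pair under a distinct
   reason;
2. drive: P0.1 > −1 mbar (weaker drive) is removed — the boundary value
   −1.0 itself is retained (strict inequality);
3. plausibility: negative ratios are removed; exactly 0 is retained.

The 2×2 table defines "positive" as occlusion-incorrect and
"test-positive" as P0.1-incorrect, so sensitivity is the screen's ability
to catch a bad balloon and NPV the safety of omitting a confirmatory
occlusion after a normal screen. Undefined metrics (zero denominator) are
reported as undefined, never as 0. Fisher's exact p is two-sided by the
"total probability of tables no more likely than observed" rule (with the
customary 1 + 1e-7 tie tolerance), computed from the hypergeometric pmf at
fixed margins; the test suite checks it against an exact
rational-arithmetic enumeration and against an independent library
implementation.

## Agreement statistics

* Simple OLS of Ratio_P0.1 on Ratio_occ (experimental on reference —
  configurable by swapping arguments); R² = 1 − SSE/SST; p from the F-test
  of zero slope.
* Bland–Altman on differences Ratio_P0.1 − Ratio_occ: bias, limits of
  agreement bias ± 1.96·SD (sample SD, n−1), and a t-based 95 % CI for the
  bias (at n ≈ 65 the difference from the normal interval is negligible,
  but small strata benefit). Clustered repeated measures are *not*
  variance-decomposed — the naive Bland–Altman is applied exactly as in the
  analysis being emulated; this is a documented limitation, not an
  oversight.
* Gaussian GEE, identity link, exchangeable working correlation,
  clustering by patient: iterated cluster-weighted GLS using the
  closed-form inverse of the exchangeable correlation matrix, with the
  moment estimator of α from standardized within-cluster residual
  cross-products (denominator N_pairs − p), iterated to max |Δβ| < 1e-8
  (cap 100 iterations; non-convergence is flagged, not raised). Standard
  errors come from the sandwich estimator (bread = model-based information,
  meat = sum of per-cluster score outer products); no small-sample
  correction is applied. With every cluster of size 1 the estimator reduces
  exactly to OLS. The implementation agrees with statsmodels' GEE to
  ~1e-8 on clustered test data (the library is used only as a
  cross-check oracle).
* Subgroup analysis: independent OLS per patient stratum (age/BMI split at
  the median, sex, primary respiratory failure, pulmonary comorbidity),
  reporting R² per group; groups under 3 pairs are flagged and skipped. No
  formal slope-heterogeneity test is fitted — per-group R² reporting only.

## Synthetic cohort: what it emulates, and what it does not

Defaults (drawn per patient unless noted):

| parameter | default | rationale |
|---|---|---|
| resistance | U(5, 15) mbar·s/L | adult ICU plausibility |
| compliance | U(30, 60) mL/mbar | idem |
| chest-wall elastance | U(4, 10) mbar/L | typical adult E_cw |
| PEEP | U(5, 10) mbar | idem |
| pressure support | U(8, 14) mbar | idem |
| p_max | U(5, 15) mbar, ×N(1, 0.05²) per maneuver | moderate spontaneous efforts; jitter creates within-patient clustering |
| t_insp | U(0.8, 1.2) s | normal inspiratory timing |
| respiratory rate | U(12, 25) /min | assisted-ventilation range |
| Pes offset | U(5, 12) mbar | end-expiratory esophageal pressure at PEEP |
| cardiac artifact | amplitude U(0, 2) mbar, rate U(60, 100)/min | visible but not dominant oscillations |
| sensor noise | SD U(0, 0.3) mbar | quantization + transducer noise |
| λ, correct balloon | U(0.90, 1.10), 60 % of patients | clearly valid placements; 60 % mirrors the evaluable-measurement mix of the emulated study |
| λ, incorrect | U(0.10, 0.50) w.p. 0.8, U(1.40, 1.60) w.p. 0.2 | frank failures: deflated/malpositioned balloons (common) vs. over-transmission (rare) |

λ is fixed per patient; each patient contributes 1–6 P0.1/occlusion pairs
organized in episodes of up to three P0.1 maneuvers followed by one
reference occlusion, concatenated on a single per-patient record.
Boundary-straddling λ (0.5–0.75, 1.25–1.4) is deliberately not generated:
the screening question emulated here is detection of frank balloon failure,
and a λ sitting on the decision threshold has no well-defined ground-truth
class under noise.

The generator does **not** emulate: leaks and auto-PEEP, multi-compartment
mechanics, ventilator trigger latencies (which vary between devices),
esophageal peristalsis/spasm artifacts, or a physical blocking-volume →
transmission curve. Passing tests therefore demonstrate correctness of the
measurement and statistics pipeline and its noise behaviour under this
generative model — not device-level performance on real recordings.

Noise propagation differs sharply between the two maneuvers, and this is
the mechanism the simulator is designed to expose: the occlusion ratio
divides by the full effort (≈ 5–15 mbar) and is robust, while the P0.1
ratio divides by the 100 ms deflection (≈ 1.3–5.7 mbar) and reads a single
Pes sample, so a 1 mbar cardiac oscillation — which also leaks through any
baseline window shorter than a cardiac period — produces ratio errors an
order of magnitude larger. On such cohorts the P0.1 screen's specificity
degrades well below its sensitivity, reproducing the false-positive-heavy,
rule-out-oriented profile of the method; the exact numbers for a given
seed are computed by `scripts/acceptance.py`, never asserted a priori.

## Numerical choices and problem sizes

Floating-point I/O uses `%.17g` with round-trip parsing, so records survive
write/read bit-exactly. Ratios with ΔPaw = 0 are NaN (and excluded by the
plausibility rule). The α estimate of the GEE is clipped to its validity
interval (−1/(m_max−1), 1). Reported analyses use a 25-patient cohort with
1–6 pairs per patient (≈ 80–120 maneuvers); validation simulations in the
test suite use 100–200 replicates of their respective designs (onset
robustness, GEE coverage at 50 clusters × 4, subgroup homogeneity at
n = 60), sizes at which the checked proportions are stable to within their
asserted margins.
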