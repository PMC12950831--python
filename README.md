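# pescreen

Screening the validity of esophageal-pressure (Pes) measurements during
assisted mechanical ventilation, from 200 Hz ventilator waveforms.

Transpulmonary pressure, Paw − Pes, is a key monitoring quantity in
ventilated patients with spontaneous breathing — but only if the esophageal
balloon catheter is correctly placed and filled. The reference check is the
**expiratory occlusion maneuver**: the airway is occluded for a full
inspiratory effort, and with zero flow the airway pressure swing must equal
the pleural swing, so

&nbsp;&nbsp;&nbsp;&nbsp;Ratio_occ = ΔPes/ΔPaw ≈ 1 (accepted when 0.75 < ratio < 1.25)

confirms a valid Pes signal. The occlusion test is uncomfortable and manual.
The **P0.1 maneuver** — an airway occlusion lasting only the first 100 ms of
an effort, routinely automated on ICU ventilators to index respiratory
drive — offers the same ΔPes/ΔPaw comparison in a brief, repeatable form
(Ratio_P0.1). `pescreen` implements the complete analysis of P0.1-based
screening against occlusion-as-reference:

* **waveform_io** — CSV dialect for multi-channel 200 Hz traces
  (time, Paw, flow, volume, Pes; pressures in mbar) and maneuver annotations;
* **simulate** — a single-compartment lung simulator (half-sine muscle
  pressure, forward Euler at 200 Hz) with pressure support, embedded
  occlusion/P0.1 maneuvers, a balloon transmission factor λ (ground truth
  for placement quality), cardiac-oscillation artifact, sensor noise, and
  cohort generation with within-patient clustering (1–6 measurement pairs
  per patient, three P0.1 per reference occlusion);
* **maneuvers** — maneuver-window detection (zero flow + sustained Paw
  deflection), effort-onset detection, and extraction of ΔPaw, ΔPes,
  ΔPes/ΔPaw, P0.1 and end-expiratory Pes;
* **screening** — P0.1↔occlusion pairing, the filter cascade
  (≤ 20 % end-expiratory Pes deviation; P0.1 ≤ −1 mbar for adequate drive;
  non-negative ratios), strict 0.75–1.25 classification, the 2×2
  contingency table (positive = occlusion-incorrect) with sensitivity,
  specificity, PPV, NPV and a two-sided Fisher exact test;
* **agreement_stats** — linear regression, Bland–Altman (bias, 95 % limits
  of agreement bias ± 1.96·SD), a hand-implemented Gaussian GEE with
  identity link, exchangeable working correlation and robust sandwich
  standard errors (cluster = patient), and per-subgroup regressions;
* **cli** — `pescreen simulate | analyze | screen | agree | report`.

## Worked example

Simulate one breath with a half-filled balloon (λ = 0.5) and measure it:

```python
from pescreen import (RespiratorySystem, EffortProfile, VentilatorConfig,
                      BalloonModel, simulate_breath,
                      detect_occlusion_windows, measure_maneuver,
                      classify_placement)

system  = RespiratorySystem(resistance=10, compliance_rs=45, elastance_cw=0, peep=5)
effort  = EffortProfile(p_max=10, t_insp=1.0, respiratory_rate=18)
balloon = BalloonModel(lambda_transmission=0.5, pes_offset=8)

for kind in ("occlusion", "p01"):
    rec, _ = simulate_breath(system, effort, VentilatorConfig(), balloon,
                             maneuver=kind, seed=0)
    m = detect_occlusion_windows(rec)[0]
    meas = measure_maneuver(rec, m)
    print(kind, f"dPaw={meas.delta_paw:.2f} dPes={meas.delta_pes:.2f} "
                f"ratio={meas.ratio:.3f}", classify_placement(meas.ratio))
```

prints

```
occlusion dPaw=-10.00 dPes=-5.00 ratio=0.500 incorrect
p01 dPaw=-3.09 dPes=-1.55 ratio=0.500 incorrect
```

The occluded airway sees the full 10 mbar effort; at 100 ms the half-sine
effort has reached 10·sin(0.1π) = 3.09 mbar. In both maneuvers the balloon
transmits half of the pleural swing, the measured ratio recovers λ = 0.5,
and the placement is flagged invalid (outside 0.75–1.25).

The published 2×2 surface — 38 occlusion-correct measurements of which 27
were P0.1-concordant, and 27 occlusion-incorrect of which 25 were caught —
is reproduced by

```python
from pescreen import ContingencyTable, diagnostic_metrics
diagnostic_metrics(ContingencyTable(tp=25, fn=2, fp=11, tn=27))
# sensitivity 0.926, specificity 0.711, ppv 0.694, npv 0.931
```

i.e. 93 % sensitivity and 93 % NPV for ruling out a bad balloon, with 71 %
specificity and 69 % PPV — the profile of a screening (rule-out) test whose
positives need confirmatory occlusion testing.

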