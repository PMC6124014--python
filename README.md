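# raspro

Severity quantization, consensus-motif summarization, and
interventional-time alert scoring for multi-sensor remote patient
monitoring — plus an evaluation harness that measures whether the
compact representations can replace raw vital-sign data for detecting
and predicting acute hypotensive episodes.

## Who this is for

Remote monitoring floods physicians with raw multi-sensor time series.
This package implements a three-stage filter pipeline that turns those
streams into a few clinically meaningful tokens:

1. **Personalization — severity quantization.** Each sensor's raw values
   are discretized into ordered severity symbols `… A-- A- A A+ A++ …`
   using per-patient, per-sensor boundaries. Symbols from N sensors over
   a W-sample window form a patient specific matrix (PSM).
2. **Precision — consensus motifs.** Each PSM row (a window
   `C = {α[1..W]}`) is summarized by the candidate minimizing
   `σ[p] = Σ_i D(α[p], α[i])`, where `D` is the hamming distance between
   levels (adjacent levels are at distance 1). Splitting candidates by
   their distance to normal against a near-normal threshold `S_THRESH`
   yields a consensus *normal* motif (CNM) and a consensus *abnormality*
   motif (CAM) per patient — compact enough to send as an SMS, with
   frequency maps, full symbol series and raw data available as
   progressively detailed data-on-demand tiers.
3. **Prevention — alert scoring.** Each (sensor, level) pair with a
   medically accepted intervention time `δ` gets weight `θ = K_P / δ`;
   the Alert Measure Index `AMI = Σ_n θ[S_n][CAM_n] · num(CAM_n)`
   (with `num` counting a level's +/− marks) ranks patients by urgency.

The evaluation harness compares three feature representations of mean
arterial pressure (MAP) windows — raw (OTS), quantized ordinals (QTS,
breadth B ∈ {5,10,15,20} mmHg) and blockwise consensus ordinals (MTS,
window W ∈ {5,10,15}) — as inputs to an RBF-kernel SVM for classifying
and predicting acute hypotensive episodes (MAP < 60 mmHg sustained
longer than 30 min), using post-marker windows (classification) or
expanding/moving pre-marker windows (prediction, T ∈ {30..180} min),
a stratified 70/30 split and 5-fold cross-validated model selection.
A seeded generator produces the 35-event + 35-control MAP cohort the
protocol runs on. See `docs/methods.md` for the full model description.

## Worked example

A patient whose blood pressure sits two severity levels low while heart
rate stays normal:

```python
from raspro import (SensorSpec, build_uniform_scheme, build_psm,
                    quantize_series, extract_motifs, weight_matrix,
                    compute_ami, encode_motif_sms)

specs = {
    "BP": SensorSpec("BP", units="mmHg", n_sub_levels=2, n_supra_levels=2,
                     near_normal_threshold=1,
                     intervention_times={"A--": 30.0, "A-": 60.0}),
    "HR": SensorSpec("HR", units="bpm", n_sub_levels=2, n_supra_levels=2,
                     near_normal_threshold=1,
                     intervention_times={"A++": 20.0, "A--": 20.0}),
}
schemes = {"BP": build_uniform_scheme(specs["BP"], (60.0, 100.0), 10.0),
           "HR": build_uniform_scheme(specs["HR"], (60.0, 100.0), 15.0)}

qts = {"BP": quantize_series([44.0, 47.5, 43.2, 46.1, 49.0], schemes["BP"]),
       "HR": quantize_series([72.0, 75.0, 71.0, 78.0, 74.0], schemes["HR"])}
psm = build_psm(qts, window_start=0.0, window_len=5, patient_id="P001")
cnm, cam = extract_motifs(psm, specs)
ami = compute_ami(cam, weight_matrix(specs, k_p=60.0))
print([s.label for s in qts["BP"].symbols])
print(encode_motif_sms(cam, ami))
```

prints

```
['A--', 'A--', 'A--', 'A--', 'A--']
P001|CAM:BP=A--,HR=A|AMI:4.0
```

BP values in the 40s fall two 10-mmHg intervals below the 60–100 band,
so every sample quantizes to `A--`; the abnormality motif is
`⟨A--, A⟩`. With `K_P = 60` min and a 30-min intervention time on the
deep BP level, `θ = 60/30 = 2.0`, and `AMI = 2.0 × 2 (BP) + 0 (HR) =
4.0` — a patient who outranks anyone scoring lower in the priority
table. The single line after the patient id is the SMS-compact motif
encoding (decode with `decode_motif_sms`).

The same pipeline is available from a shell:

```bash
raspro simulate --config cfg.yaml --out cohort/
raspro alert    --config cfg.yaml --in cohort/H001.csv --out priorities.csv
raspro evaluate --mode expanding --config cfg.yaml --out results.csv
```

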