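# Methods

## The pipeline

The package processes multi-sensor vital-sign streams in three stages.

**Severity quantization (personalization).** Each sensor `S_i` has a
configured number of severity levels `L_i = n_sub + n_supra + 1` arranged
around a clinically normal band. Raw values are discretized into ordered
symbols `…, A--, A-, A, A+, A++, …` whose signed ordinal counts the marks
(`A` = 0). With a uniform scheme the intervals have a fixed breadth `B`
(raw units) stacked outward from the normal band; the outermost intervals
are unbounded, so every finite value maps to exactly one symbol.
Personalization is purely configuration: bands, breadths, level counts,
thresholds and intervention-time tables are per sensor and per patient;
no boundary learning is performed. A value exactly on an interval
boundary takes the *milder* adjacent symbol, so MAP = 60 mmHg is normal —
consistent with hypotensive events being defined by values strictly below
60. Symbols from `N` sensors over a `W`-sample window form the patient
specific matrix (PSM). Multi-rate sensors are first aligned to a common
grid (default 1 sample/min) by previous-value hold with a bounded hold
age; samples older than the hold age become explicit missing markers and
are never imputed.

**Consensus motifs (precision).** For a window `C = {α[1..W]}` of one
row, `σ[p] = Σ_i D(α[p], α[i])` sums the hamming distances of candidate
`p` to every candidate (self-term 0), where `D` between two levels is
their absolute ordinal difference. The consensus *normal* symbol is the
minimal-σ candidate with `D(α, A) < S_THRESH` (the sensor's near-normal
threshold); the consensus *abnormality* symbol is the minimal-σ candidate
with `D(α, A) ≥ S_THRESH`. Stacked over rows these give the CNM and CAM
motifs. Ties in σ resolve toward the greater `|ordinal|` (a summarizer
used for alerting should not under-report severity), then to the earliest
occurrence, making the consensus deterministic and always an element of
the window. When a row has no abnormal candidate, its CAM entry falls
back to the row's consensus normal symbol; the entry then contributes
zero to alert scores. Rows more than half missing yield none-markers.
The motif time series (MTS) summarizes a whole quantized series by
applying the *unconstrained* minimal-σ consensus to consecutive
non-overlapping `W`-blocks (trailing partial block summarized as-is), so
every block yields a symbol regardless of `S_THRESH`.

**Alert scoring (prevention).** A level `α` of sensor `S_n` with a
medically accepted intervention time `δ[S_n][α]` (minutes) gets weight
`θ[S_n][α] = K_P / δ[S_n][α]`, where `K_P` (minutes) is a physician-set
patient constant; levels with no configured `δ` have weight 0. The Alert
Measure Index of a patient window is `AMI = Σ_n θ[S_n][CAM_n] ·
num(CAM_n)` with `num` the mark count (`num(A) = 0`, generalized to
`|ordinal|`). AMI is linear in `K_P` and monotone in severity at fixed
weights; an all-normal motif scores exactly 0. Patients are ranked by
descending AMI; ties go to the earlier window, then the patient id. The
weight rule is a pluggable strategy (`weight_fn`), with the reciprocal as
the default and only built-in. AMI is reported raw, not normalized by
sensor count.

## Evaluation protocol

An acute hypotensive episode (AHE) is a maximal run of MAP samples
strictly below 60 mmHg lasting strictly more than 30 minutes; a 30-minute
run is not an event. Episodes are labelled H (event, with marker `t0`
such that onset lies within the following hour) or G (control, no event).

Feature vectors per representation: OTS = raw mmHg values; QTS = signed
ordinals under a breadth-`B` MAP scheme; MTS = ordinals of the blockwise
consensus (length `window / W`). The MAP scheme grades downward only:
`ceil(60/B)` sub-normal levels cover the range to 0 mmHg, and everything
at or above 60 is `A`, since the event of interest is defined solely by
low pressure. Windows: precision mode uses the 60 minutes after `t0`;
expanding mode the `T ∈ {30, 60, 90, 120, 150, 180}` minutes ending at
`t0`; moving mode a 30-minute slice starting `T` minutes before `t0`
(non-overlapping backward strides). Prevention-mode windows end at or
before `t0` by construction — post-marker samples never leak into
predictors. Controls have no `t0`, so each G patient receives one anchor
drawn from the seeded stream and reused across the entire grid.

Each grid cell is scored by a support-vector classifier with RBF kernel
inside a pipeline with feature standardization. The regularization
constant is selected from {0.1, 1, 10} (kernel width at the `scale`
default) by stratified 5-fold cross-validation on a stratified 70% train
split; F1 (positive class H) is computed on the held-out 30% from the
confusion counts via the package's own harmonic-mean implementation
(`f1_score`), with the 0-convention when there are no true positives.
The kernel and grid are package choices — overridable through
`ExperimentConfig` — since nothing in the protocol pins them; results
are fully determined by the config seed. `best_per_representation`
reduces a result table to the best (B, W) per representation (and per T
in prevention modes), the analogue of best-curve comparisons, and `rmse`
compares such F1 curves.

## The synthetic cohort

The generator emulates the evaluation cohort: 35 H + 35 G, MAP at
1 sample/min. The baseline is a stationary AR(1) Gaussian process
(marginal sd 4 mmHg, lag-1 correlation 0.9) — the simplest model with
the short-range autocorrelation of slowly varying vitals. Defaults,
chosen once as clinically plausible study conditions:

| parameter | default | meaning |
|---|---|---|
| `duration` | 300 min | long enough for a 180-min pre-marker window, a ≤60-min marker-to-onset gap, the dip, and the post-marker hour |
| `baseline_mean` / `h_baseline_mean` | 85 / 75 mmHg | controls sit mid-normal; event patients run low-normal |
| `baseline_sd`, `ar1_rho` | 4 mmHg, 0.9 | ambient variability and its persistence |
| `dip_depth`, `dip_duration` | 8 mmHg, 45 min | terminal episode plateau at 52 mmHg, comfortably past the >30-min rule |
| `onset_ramp` | 10 min | linear descent/recovery around the plateau |
| `prodrome_dips/depth/duration` | 3 × 5 mmHg × 10 min | transient pre-marker hypotensive dips, one guaranteed within the last half hour before `t0` |
| `borderline_duration/offset` | 30 min, 2 mmHg | peri-onset phase hovering just under threshold, never before `t0` |

H series are assembled as baseline + prodrome dips + borderline phase +
terminal dip; `t0` is placed uniformly so that at least 180 minutes
precede it and the post-marker hour and the dip fit inside the series,
with the onset `U(ramp, 60)` minutes after `t0`. The prodrome and the
lower H baseline are what give *pre-marker* windows their predictive
signal: without them, every pre-onset sample quantizes to `A` and the
quantized representations of H and G patients are identical. The
borderline phase reflects that sustained episodes rarely begin from a
healthy baseline in a single step; it makes the post-marker hour
recognisably abnormal even when the sustained run begins late in it.
Labels are guaranteed rather than merely likely: each draw is validated
with the episode detector (H: first event onset in `[t0, t0+60]`, run
>30 min; G: no event) and rejected draws are regenerated from a derived
substream. Every patient uses an independent substream of the master
seed, so cohorts are reproducible and order-insensitive.

What the generator does *not* emulate: measurement artifacts and dropouts,
circadian and treatment-response trends, heavy-tailed noise, inter-patient
variance heterogeneity, and any coupling between MAP and other vitals.
Passing tests therefore demonstrate the pipeline's correctness and the
internal consistency of the protocol on a favourable, well-separated
cohort — not clinical performance on ICU recordings, where separability
is far lower and classifier scores land well below the values seen here.

The separate fixture generator (`generate_multisensor_patient`) inverts
the quantizer: given a per-sensor severity script it draws raw values
from the interior of each symbol's interval (5% margin from boundaries;
one typical width beyond the edge for unbounded intervals), so
re-quantization recovers the script exactly.

## Numerical and formatting choices

- Timestamps are minutes from series start (float); ISO-8601 input is
  converted on read. Severity labels use ASCII `+`/`-` only.
- Quantization uses binary search over breakpoints; exact boundary hits
  resolve to the milder neighbour. NaN is the missing marker in raw
  series; `None` in symbol sequences.
- σ and consensus use the O(W²) definition directly (W ≤ tens; no need
  for anything cleverer, and the brute force *is* the reference
  semantics).
- The SMS codec (`P001|CAM:BP=A--,HR=A|AMI:4.0`, `~` for none-entries)
  refuses to emit more than 160 characters rather than truncate; floats
  round-trip through `repr`.
- Degenerate inputs raise typed errors (`InvalidParameterError`,
  `NoConsensusError`, `ParseError` with line numbers, …) rather than
  returning sentinels; the zero-convention of F1 is the one deliberate
  exception.

## Problem sizes

The default test suite and the acceptance script run the full precision
grid (17 models), expanding grid (102) and moving grid (102) on the
70-patient cohort; with ≤180-sample feature vectors and the small CV grid
this is a few hundred SVM fits and completes in well under a minute on
one CPU. Module tests use reduced cohorts (8+8 or 10+10) where
statistical power is irrelevant.

## Known limitations

- Severity boundaries, `W`, `K_P` and δ-tables are configuration inputs;
  no learning or risk-adaptive derivation is implemented.
- `S_THRESH` is a single per-sensor value, applied to both sub- and
  supra-normal sides.
- AMI is not normalized across patients monitored with different sensor
  counts; comparisons are most meaningful within a fixed sensor set.
- The evaluation consumes the synthetic cohort only; no reader for
  PhysioNet/waveform-database records is included.
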