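# Methods

This note documents the model, its parameters and the numerical choices
behind the package, and what the synthetic-data tests do and do not show.

## Signal model and assumptions

Dual-belt RIP records two uncalibrated voltages proportional to ribcage
(RCG) and abdominal (ABD) cross-sections, here assumed sampled at a
common fixed rate (50 Hz in the intended application). The classifier
assumes:

- breathing is quasi-periodic near a modal frequency of ~0.7 Hz
  (42 breaths/min), with amplitude and frequency drifting slowly;
- pauses suppress excursions to ≤ ~10 % of the preceding baseline
  (the pediatric apnea scoring convention);
- movement produces aperiodic power concentrated below ~0.5 Hz with
  amplitude exceeding breathing;
- thoracoabdominal synchrony is captured by the phase between the two
  belts (0° synchronous, ~45–135° asynchronous, 180° paradoxical);
- belt gain is arbitrary, so every metric must be invariant to rescaling
  either channel by a positive constant.

## Windows and parameters

All metrics use rectangular sliding windows, advanced one sample at a
time. Centered windows have odd sample counts (seconds are converted via
`round(width·fs)` forced to the nearest odd integer, ties rounding up);
trailing windows cover the most recent `N` samples including the current
one. Defaults (seconds unless noted):

| parameter | default | role |
|-----------|---------|------|
| `n_dt_pau_mvt` | 5 | detrend window for the variance/nonperiodic-power chains |
| `n_dt_syb_asb` | 2 | detrend window for the synchrony chain |
| `n_v` | 1 | variance estimation window (fast, to catch short pauses) |
| `n_qv` | 120 | trailing window for the variance quantile |
| `n_ma` | 1.42 | moving-average notch width; first null at `fs/N_MA` ≈ 0.7 Hz at 50 Hz |
| `n_rms` | 5 | RMS window on the notch output |
| `n_qrms` | 600 | trailing window for the RMS quantile |
| `n_smo` | 0.42 | pre-binarization smoothing |
| `n_b` | 2 | power window for `b⁺`/`b⁻` |
| `n_b_phase` | 101 samples | phase-averaging window |
| `q_var`, `q_rms` | 0.5 | normalization quantiles (median: breathing is the majority pattern, so the median tracks normal breathing power) |
| `hp_cutoff` | 0.5 Hz | high-pass for the sum/difference signals |

The detrending is applied once per metric chain, with that chain's
window (5 s for the pause/movement chain, 2 s for the synchrony chain);
the two-channel record is therefore detrended twice in total, not per
equation.

## Numerical choices

- **Edge policy.** Centered windows shrink symmetrically at the record
  edges (effective half-width `min(h, n, len−1−n)`), keeping every output
  series index-aligned with the input. Trailing quantiles use all samples
  available so far. `valid_mask` marks samples whose largest window
  (the 600 s trailing quantile) is fully supported; training excludes
  invalid samples by default, classification never does (every sample
  must get a label).
- **Quantile floor.** The ratios inside both logs are floored at
  `1e-12 ×` the record's peak windowed power (falling back to `1e-12`
  absolute for an all-zero record). A relative floor keeps the metrics
  finite through silent calibration stretches *and* exactly
  scale-invariant; an absolute floor would break invariance at samples
  whose detrended value is pure rounding residue.
- **Binarization.** `RIP_B = 1` iff the smoothed detrended signal
  exceeds `1e-9 ×` its peak magnitude; ties and near-ties go to 0. The
  tolerance makes the binary signal invariant to channel rescaling under
  floating-point rounding.
- **High-pass filter.** 5th-order Butterworth at 0.5 Hz applied
  forward-backward (`sosfiltfilt`): zero phase (so `b⁺`/`b⁻` stay aligned
  with the sample axis) and ≥ 40 dB combined attenuation below 0.3 Hz,
  where pause and movement power concentrates.
- **Frequency demodulation.** Transitions of the binary signal delimit
  half-periods; `f = fs/(2·Δn)` is piecewise constant between
  transitions, extended to the record edges with the nearest defined
  value, and NaN throughout if fewer than two transitions exist. NaNs are
  excluded from summaries, never imputed. The frequency is demodulated
  from the abdominal channel (the two channels behave near-identically;
  it is a descriptive output, not a classifier feature).
- **k-means.** scikit-learn `KMeans` with k-means++ initialization,
  `n_init=10`, `tol=1e-6`, `max_iter=300`, and a caller-supplied seed
  stored in the model. No feature scaling: the metrics are already
  log-/quantile-normalized. The boundary re-weighting
  `w = N_j/(N_j+N_m)` is applied once, after convergence; points exactly
  on the hyperplane go to the anti-class (strict `< 0`).
- **Stage features.** PAU uses {nv_rcg, nv_abd}; MVT {npp_rcg, npp_abd};
  SYB {b⁺}; ASB {b⁻}. Frequency and phase are descriptive only.

## Evaluation conventions

Comparisons use the merged vocabulary {PAU, SYB, ASB, UNKNOWN}
(UNKNOWN = MVT ∪ UNK ∪ SIH). Precision and recall follow the convention
of the original study: the confusion matrix has reference rows and
predicted columns, *precision* is row-normalized and *recall*
column-normalized. This is transposed relative to textbook usage; the
`orientation="conventional"` switch (and `--orientation conventional` on
the CLI) provides the standard definitions. The F-score is the harmonic
mean, defined as 0 when precision = recall = 0. Event-level pattern
matching considers reference events of duration ≥ 2 s (inclusive) and
counts an event as matched when strictly more than the threshold
fraction (default 50 %) of its samples are identically labeled.

## Synthetic data

The generator produces labeled segments and concatenates them with
raised-cosine cross-fades ≤ 0.2 s (cross-faded samples take the incoming
label). Segment models: SYB/ASB are sinusoids with slow amplitude (±10 %)
and frequency (±4 %) jitter and an abdominal lag of 4°/100° by default;
PAU caps excursions at 10 % of the preceding breathing amplitude; MVT is
band-limited (< 0.5 Hz) Gaussian noise, partially correlated between
belts, at twice the breathing amplitude; SIH superposes one ~2.5×
breath on synchronous breathing; UNK is irregular low-amplitude
breathing with drifting phase. The default *study-like* scenario mixes
SYB 60 %, MVT 15 %, UNK 11 %, ASB 7 %, PAU 5 %, SIH 2 % — the pattern
distribution of the intended clinical population — with breathing
frequencies drawn from 0.66–0.80 Hz around the published SYB/ASB medians
(0.76/0.71 Hz). Tests and the acceptance script use 1200 s records at
50 Hz: long enough to support the 600 s trailing-quantile window with
margin, small enough to run in seconds.

What the simulator does **not** model: cardiogenic artifact, belt drift
and repositioning, behavioral-state transitions, co-located sigh/pause
sequences, obstructive-apnea paradoxing, or scorer disagreement in the
reference labels. Round-trip accuracy on synthetic records (~0.85–0.87)
therefore demonstrates internal consistency of the metric → cascade →
evaluation pipeline under the stated signal model, not clinical
performance; on real infant records the original study observed 0.80
against a consensus manual reference.

## Known limitations

- Training assumes a homogeneous population: metrics are pooled across
  records before clustering, so records with atypical pattern mixes pull
  the shared boundaries.
- No sigh detector: sighs fall into MVT/UNK, which is why evaluation
  merges them into UNKNOWN.
- Sample-wise classification fragments events below ~2 s; event-level
  analyses should filter on duration (the fragmentation histogram makes
  this visible).
- The zero-crossing frequency estimate is undefined during long
  transition-free stretches (pauses) and biased during movement; it is
  reported as NaN or a slow estimate, respectively, and deliberately not
  used as a classifier feature.
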