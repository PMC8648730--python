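# Methods

## Time axis and annotation model

All sampling runs on a per-subject global time axis: float seconds,
origin at the start of the first recording file, every interval
half-open `[start, end)`. Recording files are placed on this axis from
their clock stamps; a file whose start clock precedes the previous
file's start clock is assumed to have crossed midnight (+24 h), and a
start clock falling strictly inside the previous file's span is
rejected as an overlap. Clock stamps carry no dates, so a gap longer
than a day is ambiguous in the wrapped notation; the summary writer
therefore emits unwrapped hours (e.g. `36:00:00`), a convention the
source archive itself uses, which makes the round trip exact. Dummy
(`-`) and duplicate channel labels are dropped at parse time, and the
per-subject working montage is the intersection of channel names across
files in first-file order — the archive changes montage mid-subject and
no published rule exists, so intersection is this package's policy.

Coverage is the union of file spans; all labeling is interval algebra
(intersection, subtraction) against coverage, so recording gaps clip
segments instead of corrupting them.

## Sampling rules

With SPH (seizure prediction horizon), SOP (seizure occurrence period),
seizure-free time T and an interictal guard — defaults 5 min, 30 min,
4 h, 2 h, all configurable in seconds:

* a seizure is **leading** iff it is the subject's first or the gap
  from the previous seizure's *offset* to its *onset* is ≥ T
  (offset-to-onset is the conservative reading; measuring from onsets
  would shorten the protected quiet span);
* the **preictal** segment of a leading seizure is
  `[onset − SPH − SOP, onset − SPH)` ∩ coverage, minus any earlier
  ictal span. An empty result (missing data) is a warning, not an
  error — real archives routinely lose preictal coverage;
* **interictal** time is coverage minus `[onset − guard, offset + guard)`
  of *every* seizure, leading or not. Note this definition is purely
  guard-based, so the guard must dominate SPH + SOP (2 h ≫ 35 min in
  the default geometry) for the preictal and interictal states to be
  disjoint; the randomized property tests respect the same constraint;
* segments are tiled into windows of `window_len` (default 5 s)
  advancing by `window_len − window_overlap` (default: no overlap),
  anchored at each segment's start; partial windows at segment ends are
  dropped. Anchoring is a free choice — nothing downstream depends on
  it — and segment-start anchoring maximizes yield deterministically.

Follow-up seizures contribute no positive samples but do exclude
interictal time; whether preictal intervals may overlap an earlier
seizure's *postictal* span is unknowable without postictal annotations
(no public database has them), so only ictal spans are subtracted.

## Classifier

Input is a single channel's window vector (length L = window seconds ×
rate; 1280 at 256 Hz, divisible by 2⁵). Architecture: five blocks of
[conv1d k=3 s=1 same padding → batch-norm → ReLU → max-pool k=2 s=2]
with 16 filters each, then a single-layer bidirectional LSTM (hidden
10) over the L/32 remaining time steps with the 16 conv channels as
features, then dropout 0.5 and a fully connected softmax pair. The
final representation is the concatenated last hidden state of both
LSTM directions (20 units). `use_lstm=False` removes the recurrent
stage and classifies the flattened conv features (the "CNN + FC"
ablation). Kernel/stride settings follow the architecture figure of
the source design (conv 1×3 stride 1, pool 1×2 stride 2); same padding
is assumed so pooling alone controls length.

The network and its backpropagation are implemented directly in numpy
(the architecture is the package's core contribution); gradients of
every layer, including batch-norm batch statistics and LSTM
backprop-through-time, are validated against central differences in
the test suite. Initialisation is fan-in uniform; training is Adam on
softmax cross-entropy with shuffled mini-batches. All randomness —
init, shuffling, dropout, class undersampling — derives from one
`random_state`, so identical data and seed reproduce identical weights.
Defaults: 20 epochs, batch 32, learning rate 1e-3, majority-class
undersampling to 1:1 (interictal time dwarfs preictal time; the
undersampling is seeded). The training recipe is this package's own:
no published recipe exists for the architecture.

### Budget accounting

Parameters, closed form per layer: conv `k·c_in·c_out + c_out` plus
`2·c_out` for batch-norm; LSTM `D·4·(h·(c₅+h) + 2h)` with D directions
and two bias vectors per gate block (the common recurrent convention —
stated explicitly so alternative conventions can be audited); FC
`in·classes + classes`. Default: conv 3,360 + Bi-LSTM 2,240 + FC 42 =
**5,642**, verified at runtime against tensor enumeration.

FLOPs, per single-channel window forward with 1 MAC = 2 FLOPs: conv
`2·k·c_in·c_out·L_out`; batch-norm 2 and ReLU/pool 1 FLOP per output
element; LSTM `2·params + 10·h` per step per direction (the 10·h term
covers gate non-linearities and state updates); FC `2·in·out`; softmax
3 per class. Default total ≈ **2.29 M**, of which the conv stack is
1,966,080. The published envelope (6.274 k parameters, 12.825 M FLOPs)
does not specify widths or counting conventions, so both budgets are
treated as upper bounds the default configuration must stay inside —
which it does with margin.

## Evaluation protocol

Each C-channel window is split into C single-channel vectors inheriting
the window label; one shared model classifies all channels, and the
window decision is positive when the positive-channel count **strictly
exceeds** a threshold (default N/2; for odd N this is exactly simple
majority, verified exhaustively).

Folds: one per leading seizure (≥3 required, else an eligibility
error). Interictal segments are sorted chronologically and partitioned
into as many contiguous blocks as folds, balanced by duration; block k
is held out with seizure k. The protocol's published form only
leaves out preictal seizures; holding out a contiguous interictal block
as well extends the same no-leakage principle to the negative class and
is this package's choice. When a subject has fewer interictal segments
than folds, later blocks may be empty (specificity then reported as
absent). Metrics are window-level (accuracy, sensitivity = TPR,
specificity = TNR) per fold, averaged unweighted across folds;
undefined ratios are reported as absent, never as zero. A leakage audit
(train/test segment-id and source-seizure sets disjoint) runs inside
every fold and raises on violation.

For contrast only, the same window pool can be evaluated under a
shuffled K-fold or 8:1:1 split that ignores provenance; on synthetic
data these are expected to score at least as high as LOOCV on average —
the optimistic bias the protocol eliminates.

## Synthetic data generator

Background: per-channel AR(2) noise, coefficients (0.5, −0.1),
innovation scale 20 µV — short-range correlation typical of broadband
EEG — plus a slow per-channel baseline drift (stationary AR(1), std
20 µV, correlation time 15 s, burn-in removed; a constant per-file
level is available via `drift_tau=None`). The drift is the
within-segment "identical feature" (electrode and session state) that
neighbouring windows share: shuffled splits place adjacent windows on
both sides of the partition and can exploit it, while honest
leave-one-out folds cannot — held-out recordings carry their own
drift. Its correlation time is deliberately much shorter than a file,
so held-out predictions are only locally correlated and chance-level
runs stay tightly at chance; it is also why the partition-contrast
experiments are meaningful on this data at all. Preictal signature: an additive tone per channel,
frequency drawn once per subject from `band_center ± bandwidth/2` with
random phase, amplitude `gain × noise scale`, active exactly on
`[onset − SPH − SOP, onset − SPH)` of every seizure, so the generative
truth coincides with the labeling rule by construction. Ictal spans get
a 6× amplitude 3-Hz burst. Signals, summaries and timelines are
bit-reproducible from the seed.

The generator's default regime is the benchmark one (23 channels,
256 Hz, SPH/SOP/T/guard as above). Test fixtures reduce rate and
channel count (64 or 32 Hz, 2–4 channels) — the pipeline nowhere
hard-codes either — and the training experiments use a proportionally
scaled geometry (SPH 20 s, SOP 100 s, T 600 s, guard 300 s) yielding 20
preictal windows per seizure and three 32-window interictal blocks, so
repeated seeded replicates (trend over gains, 20-run null calibration,
10-seed partition contrast) each complete in seconds.

What the generator does **not** emulate: seizure morphology, montage
physics, artifacts, non-stationary background, inter-channel
correlation structure, or any biophysics of the preictal state. Passing
tests therefore demonstrate that the *pipeline* labels, partitions,
trains and audits correctly and can recover a separable signal — they
say nothing about clinical performance on real EEG, which requires the
public archive and the full 27-fold run via `szbench run`.

## Numerical choices and degenerate inputs

* Half-open intervals everywhere; empty and inverted intervals vanish
  under normalization; an empty read returns a C×0 matrix.
* Sample indices are `round(rate × offset)`; concatenation across
  abutting files is asserted sample-exact.
* Vote threshold comparison is strict (`count > threshold`); ties at
  even N with threshold N/2 resolve negative.
* Batch-norm eval mode uses running statistics (momentum 0.1), so
  batched and single-vector inference agree to 1e-5.
* Undersampling keeps the first occurrence order (sorted indices) after
  seeded choice, so training sets are reproducible.
* Single-class training sets raise; zero-window folds yield zero-count
  metrics with absent rates.

## Known limitations

* The LOOCV contrast harness demonstrates bias *direction* on synthetic
  data, not its clinical magnitude.
* Postictal state is not modeled (unannotated in public data); T = 4 h
  is the only guard against preictal/postictal overlap.
* No alarm-level post-processing (refractory periods, false alarms per
  hour): metrics are per-window.
* The EDF reader trusts the summary file's clock stamps; it does not
  cross-check against EDF headers.
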