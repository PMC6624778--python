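# Methods

This note records the model, the numerical conventions, and the design
choices behind `p300hist`, in enough detail to reimplement it.

## Signal model and preprocessing

The input is a multichannel EEG recording in microvolts with a stimulation
log: flashes of the 12 speller-matrix locations, grouped into
12-permutation intensification sequences and trials of `k_a` sequences.
Sample indices are 0-based throughout; a flash event is the first sample of
a run of equal nonzero stimulus codes (codes held for the 0.125 s flash
collapse to one onset).

Enhancement runs notch → lowpass → decimate, all causal (forward-only), as
an online speller would:

- mains notch (IIR, Q = 30) at `notch_hz`; 50 Hz by default and
  configurable, since the notch frequency is a property of the recording
  site, not of the method;
- 4th-order 10 Hz lowpass Butterworth (second-order sections);
- decimation to `target_fs` = 16 Hz with a causal order-30 FIR anti-alias
  filter when the ratio is an integer (256 → 16). For non-integer ratios
  (e.g. 250 Hz hardware) a rational polyphase resampler (8/125) is used
  instead; its FIR is designed by the resampler rather than fixed at order
  30, which only affects the transition band, far above the 10 Hz edge.

Event indices are rescaled by the rate ratio with flooring. Causal
filtering leaves a settling transient of a few output samples at the
recording start; sessions begin before the first flash, so epochs are
unaffected.

Artifact rejection operates on the enhanced signal (the pipeline order
lists it after enhancement): a sequence is dropped when any sample of any
channel inside any of its 12 epochs `[onset, onset + n_max)` exceeds
±70 µV strictly. Epochs are half-open windows of
`n_max = target_fs · t_max` = 16 samples. The ensemble average divides by
the number of *surviving* sequences `k_a' ≤ k_a`, so rejection changes the
variance of the average but not its expectation; trials losing every
sequence are flagged and decode as failures rather than aborting a run.

## Plotting

Averaged epochs are standardized per location and channel,
`v[n] = floor(gamma (x[n] − mean)/sd)` with the `n_max − 1` (sample)
standard deviation. Standardization makes the plot invariant to the
response amplitude and to how many sequences were averaged; constant
epochs (sd = 0) cannot be standardized and are skipped with a warning —
with any measurement noise they do not occur.

The vertical offset `z = floor((max−min)/2) − floor((max+min)/2)` is kept
in this two-floor form; for integers the floors share parity and the
expression collapses exactly to `−min`, i.e. it shifts the smallest
ordinate to zero. Sample `n` (1-based) is drawn at column `gamma·n`, so
the canvas is `gamma·n_max + 1` pixels wide with `gamma − 1` empty columns
between samples, filled by classic 8-connected integer Bresenham segments.
Canvas height is tight to the ordinate range plus one all-black padding
row on each side, so finite differences at the extreme pixels have
support. Row indices grow with the standardized value; displayed with row
0 on top, a positive deflection therefore renders downward. Only
calibration/query consistency matters; the convention is fixed and stated
here. `zero_row = z + 1` is the row of standardized value 0 and anchors
the keypoint.

## Descriptor

Gradients are central differences on interior pixels and one-sided
differences on borders; angles are `atan2(Jy, Jx)` with +y down the rows,
mapped to [0, 360). The histogram accumulates, for every pixel with
normalized offset `v = (p − p_k)/(3s)`,

    h(theta, i, j) = 3s · |J(p)| · w(vx − c_j) · w(vy − c_i) · w_ang(angle − theta)

with `w(z) = max(0, 1 − |z|)`, spatial bin centres
`c ∈ {−3/2, −1/2, 1/2, 3/2}` (block row `i` follows the vertical offset,
block column `j` the horizontal one), and the circular angular kernel
`w_ang(a) = Σ_{r∈{−1,0,1}} w(8a/2π + 8r)` — a literal circular linear
interpolation over the 8 bins of 45°. The leading factor `3s` is kept even
though it cancels under normalization, to preserve equality with the
defining formula. Pixels whose spatial weights all vanish are skipped
(mathematically identical); pixels outside the image contribute zero. The
flattening is block-row-major: index `8·(4i + j) + theta/45`.

Properties the suite verifies: equality with a verbatim triple-loop oracle
to 1e-9 relative; partition of unity of the combined weights on interior
pixels (so `Σh = 3s · Σ|J|`); translation covariance; and the horizontal
mirror permutation `(i, j, b) → (i, 3−j, (4−b) mod 8)`.

Patch scale is chosen analytically, not tuned: `s_x = gamma·lambda·fs/12`
and `s_y = gamma·delta_uV/12` give the scales whose 12s-pixel patch covers
a span of `lambda` seconds and `delta_uV` microvolts. At `gamma = 4`,
16 Hz, a 0.56 s / 9 µV transient yields `s_x ≈ 2.99`, `s_y = 3`, resolved
to the common integer 3 (the two directions must agree within 0.1 before
rounding). The keypoint sits at column `floor(0.55·fs·gamma)` = 35 —
flooring matches the printed coordinate — and at `zero_row` vertically,
with the patch allowed to overhang the canvas (outside pixels are zero).

Normalization into [−1, 1] is by the maximum absolute entry; since raw
histograms are nonnegative this lands in [0, 1], which is the natural
reading of the stated range for a nonnegative vector. Unit-L2 is available
via `RunConfig.norm = "l2"`. The zero descriptor maps to itself.

## Calibration and k-NBNN decision

Per calibration trial and channel, the descriptors of the instructed
letter's row and column locations enter one pooled template set `T^c`
(row- and column-role templates are not partitioned — queries compare
against the whole pool). The best performing channel is selected by
leave-one-trial-out decoding within calibration, excluding self-templates;
without the exclusion every channel would match its own trial perfectly
and the selection would be vacuous. At least 2 calibration trials are
therefore required.

A query location's score is the sum of its cosine distances
(`1 − cos`) to the `k = 7` nearest templates of `T^bpc`; the decision
takes the argmin over locations 1–6 (row) and 7–12 (column). The
descriptors extracted from binary plots are sparse, and the cosine metric
separates them markedly better than the squared Euclidean norm, which
remains available (`metric = "sqeuclidean"`) for ablation. Ties break
toward the lowest location index (deterministic; measure-zero with float
scores). When the pool is smaller than `k`, `k` truncates with a warning.
Degenerate query locations score +inf and can never win.

## Synthetic sessions

The simulator generates the oddball protocol exactly as the decoder
expects it: per letter, `k_a` random 12-permutations at the 0.125 s flash
+ 0.125 s rest cadence, a 2 s inter-trial pause (≥ the 1 s epoch, so final
windows always fit). Background noise is 1/f-shaped ("pink") Gaussian,
scaled per channel to `noise_sd_uV` — resting EEG is low-frequency
dominated, so pink noise loads the 10 Hz passband realistically where
white noise would be mostly filtered away; white noise is available via
`noise_color`. After every target row/column flash a positive half-sine of
400 ms span and `p300_amp_uV` peak is added at 300 ms latency ± uniform
jitter (20 ms default) on the responsive channels (all by default;
restricting it to one channel gives the ground truth for channel-selection
tests). Overlapping deflections from consecutive target flashes (250 ms
asynchrony < 400 ms span) add linearly, as evoked potentials do to first
order.

Defaults are the documented operating regime: 5 µV deflection on 28.1 µV
background, i.e. 20·log10(amp/sd) ≈ −15 dB, the amplitude/SD ratio typical
of single-epoch P300 measurements. What the simulator does *not* emulate:
volume conduction and inter-channel correlation (channels are
independent), latency/shape variability across trials beyond uniform
jitter, non-stationarity, and structured artifacts (blinks, EMG). Passing
tests therefore show the decoder is correct and statistically well
behaved under the stated generative model, not that it attains any
particular recognition rate on recorded patients.

## Evaluation

CRR is the percentage of correctly decoded letters with *all* trials in
the denominator — a trial whose pipeline failed counts as an error, and
the failure count is reported separately. The Wolpaw information transfer
rate over 36 classes is reported informationally. The `--ka-sweep` option
re-decodes the same segmented trials using only the first `k_a_used`
surviving sequences, tracing the performance-versus-averaging curve.

## Problem sizes used by the test suite

The behavioral tests run on simulated material sized for a desk check:
word recovery uses 15 calibration + 5 test letters at 8 µV on 4 µV noise
with `k_a = 10`; the chance-level check decodes 500 zero-amplitude trials
(`k_a = 2`, 2 channels, 10 µV noise) against the binomial 99% interval
around 1/36; the averaging-gain check decodes 200 trials at 5 µV on 10 µV
noise with 1 versus 10 sequences. The descriptor is cross-checked against
the brute-force oracle on 100 random 36×36 gradient fields.

## Known limitations

- The `.mat` adapter for the public ALS speller recordings is best-effort
  (field names vary across exports) and is deliberately outside the test
  gate; unknown layouts raise a clean unsupported-format error.
- Causal filters introduce group delay (~60 ms for the FIR decimator at
  256 Hz); it is common to calibration and query epochs and therefore
  cancels in the decision, but absolute latencies read off plots include
  it.
- No spatial filtering, re-referencing, ocular-artifact regression,
  multi-keypoint or multichannel descriptor fusion; single fixed keypoint
  per image by design.
- Sequence indices are renumbered 1..k_a' when a session written after
  artifact rejection is re-read (the CSV stores onsets, not the original
  sequence numbering).
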