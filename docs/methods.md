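# Methods

## The entropy statistic

`mmdisten` computes a multivariate, multiscale variant of distribution
entropy for a multichannel time series `x_{c,i}` (`c = 1..C` channels,
`i = 1..N` samples).  For a scale factor `s` the computation runs in five
stages:

1. **Coarse-graining.**  Each channel is replaced by the means of
   non-overlapping windows of width `s`:

       g^s_{c,j} = (1/s) * sum_{i=(j-1)s+1}^{js} x_{c,i},   j = 1..floor(N/s)

   Trailing remainder samples are discarded; `s = 1` is the identity.

2. **Joint phase-space reconstruction.**  Delay vectors of dimension `m`
   with lag `tau` are formed simultaneously over all channels, giving one
   `C x m` template matrix `M^s(j)` per start index
   `j = 1..N_s - (m-1)tau`.  Because all channels enter one template, the
   statistic measures within- and cross-channel structure jointly, and is
   invariant under channel permutation (the Euclidean norm below is a
   symmetric function of the channel stack).

3. **Distance matrix.**  Pairwise Euclidean distances between flattened
   templates, scaled by a tolerance and exponent:

       D_ij = ( ||M^s(i) - M^s(j)||_2 / r )^n

   with `r = r_coef * SD` where SD is the **pooled** population standard
   deviation of the original, pre-coarse-graining series over all channels
   and samples.  Computing `r` once keeps the tolerance identical across
   scales, so the entropy-versus-scale curve compares like with like.

4. **Empirical PDF.**  A `B`-bin equal-width histogram of the upper-triangle
   distances (`i < j`), normalised to probabilities `P_t`.

5. **Normalised entropy.**

       E(m, tau, r, n, B, s) = -(1/log2 B) * sum_t P_t log2 P_t

   which lies in [0, 1]; empty bins contribute nothing (`0 log 0 = 0`).

### Defaults and what they do

| parameter | default | role |
|---|---|---|
| `m` | 3 | embedding dimension; 3 separates the benchmark series best |
| `tau` | 1 | embedding delay (samples of the coarse-grained series) |
| `r_coef` | 0.2 | tolerance as a fraction of the pooled SD |
| `n` | 2 | distance exponent (squares the r-scaled distance) |
| `B` | 64 | histogram bins of the distance ePDF |
| `scales` | 1..15 | scale factors of the entropy curve |

Units: the input amplitude is arbitrary (typically microvolts for EEG);
the entropy is unitless.  The statistic is invariant under affine amplitude
rescaling of the input (both the distances and `r` scale together, and the
histogram spans `[min, max]` of the scaled distances).  A corollary worth
knowing: `r_coef` and `n` do not change the value at all under this bin
convention — dividing every distance by `r^n` and raising to a fixed power
`n` are monotone transforms that leave equal-width bin occupancy over
`[min, max]` unchanged for `r`, and `n` only redistributes values within
the same rank order (`n` does affect the value; `r_coef` provably cannot).
The tolerance sweep over `r_coef` in the consistency experiments is
therefore flat per series, and only the between-series ordering is
informative.

### Numerical conventions

- **Histogram edges:** `B` equal-width bins spanning `[min, max]` of the
  upper-triangle scaled distances.  A value on an interior edge goes to the
  higher bin; the rightmost bin is closed (numpy's convention, kept for
  bit-reproducibility).
- **Degenerate histogram:** if all distances coincide (constant series),
  all mass goes to the first bin and the entropy is exactly 0.
- **Constant series:** detected up front (pooled SD = 0) and returns 0 at
  every scale rather than raising a division error.
- **Feasibility:** a scale is feasible when `floor(N/s) >= (m-1)tau + 2`
  (at least two templates).  Infeasible scales raise an error naming the
  scale — the curve is never silently truncated.
- **Embedding modes.**  `mode="single"` (default) computes distances
  between the `C x m` templates directly.  `mode="nested"` builds a
  second-level template stacking `m` consecutive first-level templates
  (dimension `C x m*m`) before the distance step, with the start-index
  bound tightened to `N_s - 2(m-1)tau` so all accesses stay in range.  The
  two modes give very similar curves; single-level is the default because
  it matches the stated index ranges of the construction and the
  distribution-entropy convention.
- **Cost.**  The distance stage is O(count^2) in time and memory
  (`count ~ N/s`).  A 10-s epoch at 256 Hz (2560 samples) needs ~3M
  distances at scale 1 and is fast; do not call the entropy on multi-minute
  windows directly — epoch first, as the pipeline does.

## Benchmark series

Three 400-sample series of graded complexity probe the statistic's
consistency: a 50 Hz unit sine, a logistic-map series
(`x_{k+1} = 4x_k(1-x_k)`, seed-derived start, 100 burn-in iterates), and
standard Gaussian noise.  The sine is sampled at 400 Hz (one second, 8
samples per cycle).  The sampling rate matters more than is obvious: the
entropy sees the *set of pairwise template distances*, and a coarsely,
commensurately sampled sine visits few distinct template values, keeping
that set small and the entropy low.  At 20+ samples per cycle the sine's
distance set is rich enough that its entropy overtakes Gaussian noise at
several scales, destroying the regular < stochastic ordering the statistic
is supposed to exhibit; at 8 samples per cycle the ordering
sine < Gaussian and sine < chaotic holds at every scale factor 1–15
(median over 20 noise seeds).

**Known limitation (bin-count trend).**  Because the entropy is normalised
by `log2 B`, a series whose distances take finitely many values cannot
show a non-decreasing trend in `B`: its histogram entropy saturates at the
log of the number of distinct values while the normaliser keeps growing,
so the normalised value decays like `1/log2 B`.  The sine is exactly such
a series (at scale 10 its coarse-grained values alternate between two
levels).  The chaotic and Gaussian series, whose distances are effectively
continuous, do show the non-decreasing trend.  The corresponding
acceptance test asserts the trend for all three series and fails — by
design, honestly — for the sine.

## The three-state synthetic recording

`gen_epileptic_like` concatenates three regimes per channel (defaults: 10
min interictal, 10 min preictal, 2 min ictal at 256 Hz), with ground-truth
state intervals attached:

- **interictal** — 1/f-shaped (pink) noise, amplitude 30: intermediate
  entropy (~0.77 pooled over scales 1–15);
- **preictal** — sparse large spike discharges (rate 0.01/sample,
  amplitude ±200) over a small Gaussian background (SD 5): the heavy tail
  concentrates the distance histogram in its lowest bins, giving the
  lowest entropy (~0.58);
- **ictal** — high-amplitude logistic-map chaos plus noise: the highest
  entropy (~0.82).

The regimes are *not* clinical EEG: no montage, no physiologic rhythms, no
artifacts.  They are designed solely so the three states are separable by
the entropy curve with the ordering observed on real epileptic EEG (ictal
highest, preictal lowest).  An earlier candidate preictal regime — a
narrowband oscillation plus noise, the textbook picture of preictal
synchronisation — was rejected after measurement: its distance histogram
is broad and its entropy the *highest* of the three regimes (~0.95),
which would invert the intended ordering.  A green end-to-end test on this
generator establishes that the chain is wired correctly and that the
classifier and alarm behave as designed on separable features; it says
nothing about clinical performance.

## Classification

Entropy curves (one row per epoch; channels pooled into a single
multivariate computation) feed a feed-forward network with two hidden
layers of 12 rectified-linear units and a 3-way softmax output, trained by
backpropagation with mini-batch RMSprop (decay 0.9, lr 1e-3, batch 32) on
the categorical cross-entropy.  The network is implemented directly on
numpy: it is small enough that a framework buys nothing, and a fixed seed
then makes initialisation, shuffling and hence the final weights exactly
reproducible.  The default 1000 training epochs brings the loss below 0.01
on the reference synthetic task; a few hundred epochs leaves the minority
ictal class unlearned.  Ties in the output probabilities resolve to the
lower class index (interictal < preictal < ictal).

The default evaluation split is stratified per state (test fraction 0.3).
A `paper-literal` split mode — train on interictal epochs, test on
preictal epochs — is provided for completeness; it cannot fit a 3-class
model (training refuses single-class input), which is the point: it
documents that this protocol is ill-posed as a 3-state evaluation.

## Epoch labelling

Epochs default to 10 s, non-overlapping: at 256 Hz that is 2560 samples,
which keeps scale 15 feasible (`N_s ≈ 170`).  Samples inside an annotated
seizure are ictal; samples within the preictal horizon (default 30 min,
aligned with reported average prediction lead times) before an onset are
preictal; all else interictal.  An epoch takes the majority state of its
samples; exact ties go to the more severe state.  For synthetic recordings
with known ground truth the generator's state intervals can be used
directly — with a 30-min horizon and a 20-min pre-onset span, horizon
labelling would otherwise mark *every* pre-onset epoch preictal and
collapse the 3-class problem.

## Alarm rule and prediction metrics

The seizure feature mean `S_F` is the mean entropy of ictal training
epochs (pooled over scales).  The monitored stream `P_F` is the pooled
per-epoch entropy in recording order.  At each step the mean of the last
`evaluation_window_epochs` values (default 6, i.e. one minute of 10-s
epochs) is compared to `S_F`:

- `as-printed`: fire when `S_F >= running mean(P_F)`.  Since interictal
  and preictal entropy both sit below the ictal mean, this fires
  essentially immediately and then stays silent for the refractory period
  (default 30 min) — usable only because of the refractory rule.
- `crossing-up`: fire when the running mean rises to at least
  `crossing_fraction * S_F` (default fraction 0.7) from below; a stream
  already above threshold at the first step counts as a crossing.

A seizure counts as predicted when at least one alarm falls within the
prediction horizon before its onset; the earliest such alarm sets the lead
time.  Alarms inside an annotated seizure are detections (neither
predictive nor false); every other alarm is false.  Reported rates:
`R_fa = N_fa / H_t` (false alarms per hour), `R_p = N_p / N_t` (fraction
of seizures predicted) and `T_avg = T_p / N_p` (mean lead time, minutes;
undefined when nothing was predicted — accessing it then raises).

The exact buffering of the stream behind the published flow chart is not
recoverable; both comparators, the window and the refractory period are
therefore explicit, configurable parts of the rule, and the replay
semantics (causal scan, running mean over a possibly part-filled window,
time-based refractory suppression) are pinned down by an oracle test.

## EDF I/O

The reader/writer handles plain EDF: 256-byte ASCII header, per-signal
subheaders, little-endian 16-bit records, per-channel physical scaling.
One-second records are used when the sampling rate is integral and divides
the length; otherwise a single record spans the recording.  Physical
bounds are widened until their 8-character header rendering brackets the
data, so a write/read round trip is exact to 16-bit quantisation.  EDF+
embedded annotations are out of scope; seizure times travel in a side-car
CSV (`onset_s,offset_s`), with a best-effort, non-normative parser for
CHB-MIT-style summary text.
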