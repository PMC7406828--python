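# Methods

This note documents the models, conventions and design choices behind
`expmse-decode`: a pipeline that turns region-level neural time series
into *time-resolved multiscale entropy* feature maps and decodes task
conditions from them with a shallow convolutional network.

## 1. The complexity measure

### Shared probability machinery

For a standardized series {x_n} with embedding dimension *m* and
tolerance *r*, the conditional probability that the current value
follows its *m*-length past is estimated by template matching: a
template at position *j* is the (m+1)-vector (x_{j−m}, …, x_j);

* A_n = #{j : max_k |x_{j−m+k} − x_{n−m+k}| ≤ r, k < m} — past matches,
* B_n = subset of A_n with |x_j − x_n| ≤ r — past+current matches,

so p(x_n | x_n^−) ≈ B_n / A_n.  Distances are Chebyshev (max-norm), the
standard sample-entropy choice.  The four statistics differ only in
where the time average sits:

| statistic | definition | averaging |
|---|---|---|
| expSampEn(n) | −log(B_n/A_n) | none — kept as a time series |
| ApEn | ⟨−log(B_n/A_n)⟩ | after the log |
| SampEn | −log(ΣB_n / ΣA_n) | probabilities before the log |
| LSampEn | −log⟨B_n/A_n⟩ | conditional probability before the log |

Natural logarithms throughout (nats).  **Self-matches are excluded in
all four measures.**  Classic ApEn includes the self-match; we exclude
it uniformly so that the identity

    mean over defined n of expSampEn(n)  ==  ApEn

holds *exactly* (it is asserted to 1e−13 in the tests).  Points where
A_n = 0 or B_n = 0 are undefined; expSampEn flags them in a mask rather
than silently emitting NaN or infinity.

### The template index

A per-time-point entropy needs far more templates than one short
segment can provide, otherwise most points are undefined.  The index is
therefore built from the **whole recording**: every region's series
(all tasks and rest periods) is coarse-grained at the time scale factor
τ (non-overlapping means of τ samples), the per-region coarse series
are concatenated, and the concatenation is standardized to mean 0 /
SD 1.  Tolerance r = 0.2 then means 0.2 SD of the index.  Conventions:

* **Coarse-grain each region first, then concatenate.**  Templates
  whose (m+1)-window would span a region boundary are inadmissible;
  coarse-graining across a boundary would average unrelated signals.
* **Capping.**  When the number of admissible template positions
  exceeds `cap`, positions are uniformly stride-subsampled
  (`pos[::ceil(K/cap)]`).  Query points are *never* subsampled — every
  time point of every region receives an entropy value.
* **Edges.**  The first and last 2 % of raw samples are flagged
  (EMD/Hilbert boundary artifacts); queries overlapping flagged samples
  are treated as undefined.
* **Interpolation.**  Undefined interior points are filled linearly
  between the nearest defined neighbours; leading/trailing gaps take
  the nearest defined value (a line needs two neighbours).
* Scale invariance: standardization absorbs any common rescaling of
  the input, so doubling the signal changes nothing (property-tested).

Match counting is exact brute force accelerated by sorting templates by
their first past coordinate and scanning only the |Δ| ≤ r band
(a numba kernel); it is bit-identical to the exhaustive double loop and
is verified against one in the tests.

### The multiscale map

Per region the pipeline computes expSampEn for each of 3 bands × 2
components × 5 TSFs and averages each gap-free coarse series onto a
common 0.64 s grid ("ML grid"), yielding a region × 30 × time tensor.
Column order is band (gamma, beta, alpha) × component (Amp, Phase) ×
TSF (A–E), with per-band TSFs

* gamma: 2, 4, 8, 16, 32
* beta: 4, 8, 16, 32, 64
* alpha: 8, 16, 32, 64, 128

chosen so that each band's scales span comparable fractions of its
oscillation period.  The phase component enters as cos(phase) and is
coarse-grained as ordinary values (no circular averaging).  Because the
index is standardized per (band, component, τ), the map measures
*relative* irregularity at each scale; multiscale profiles with a fixed
absolute tolerance (the classic white-vs-1/f ordering) are exposed by
the plain `sampen` + `coarse_grain` functions, where r stays in units
of the original series SD.

## 2. Signal decomposition

Bands are obtained by ensemble empirical mode decomposition (EEMD):
white noise at 0.2 SD of the signal is added in each of `n_ensembles`
runs, each run is sifted into intrinsic mode functions (cubic-spline
envelopes through local extrema, mirrored boundary extension, a fixed
10 sifting iterations per IMF, at most 10 IMFs), and the per-run IMFs
are averaged.  The ensemble residual noise floor makes the
reconstruction error ≈ 0.2/√n_ensembles relative RMS, which the tests
verify.  On 400 Hz input the IMF peak frequencies fall dyadically near
>100, 40, 20, 10 and 4 Hz, so IMFs 2–4 are designated gamma, beta and
alpha; the fixed mapping is refused for other sampling rates unless an
explicit mapping is supplied.  Whether a slower band (IMF 5) is worth
analyzing is left to configuration.  Each band IMF is converted by the
Hilbert transform into instantaneous amplitude (envelope), wrapped
phase and cos(phase).  Band power — the baseline input family — is the
squared envelope averaged in 0.64 s bins (for narrowband signals this
differs from bin-averaged squared IMF by ≈ 2×; the envelope is already
computed for the entropy map, so envelope² is used).

A zero-phase 150 Hz low-pass + 60/120 Hz notch + resample-to-400 Hz
stage is provided for externally recorded data; synthetic recordings
are generated at 400 Hz directly.

## 3. Study layout and feature assembly

The trial structure is 6 s rest + 6 s task per trial, tasks in a fixed
order within a session, 8 trials × 12 tasks × 3 sessions at full scale.
The first session is treated as practice and excluded; the first trial
of each task in each analyzed session has no pre-task break and is also
excluded, leaving 14 analyzable trials per task (7 × 2 sessions) at
full scale.

**ML-grid convention.**  The 0.64 s grid is global (bin k covers raw
samples [256k, 256(k+1)) at 400 Hz).  A 12 s trial is not a whole
number of bins, so a trial's nine ML samples start at the bin
containing its task onset (bin-start convention).  Those nine bins
always end before the task offset, and the first bin can reach at most
0.64 s back into the *same trial's* rest period — crops therefore never
span another trial's samples.

Crops: every 4-of-9 subset of a trial's ML samples is averaged into one
crop (C(9,4) = 126 per trial, lexicographic order) for the expMSE and
band-power families; the raw family uses the 200 Hz downsampled signal
(the gamma IMF lies below 80 Hz) and a 2 s (400-sample) window sliding
in 6-sample steps over the 1200-sample task segment, giving 134 crops.
The 6-sample step is the unique small integer step that yields 134
crops from a 1200-sample trial.  Decoding uses the four
visual/motor tasks (VP, VI, ME, MI) — the auditory tasks share their
cue modality with the task cue itself — while *all* tasks feed the
entropy index.  The two-class relabeling maps {VI, MI} → imagery and
{VP, ME} → non-imagery.

## 4. Decoder

A shallow CNN: two blocks of (stride-1 'same' convolution → batch
normalization → ELU → non-overlapping max-pool), then a dense softmax
layer.  Filter shapes per input family: 5×5 (expMSE, 68×30), 5×10
(raw, 68×400), 5×2 (band power, 68×3); pooling 2×2 (2×1 for the
3-column band-power input).  Filter counts default to 16 then 32;
learning rate 1e−3 (Adam), batch 64, early stopping on validation loss
with best-weight restoration.  These training hyper-parameters are
package defaults, not reconstructions of anything.

Training is *cropped*: every crop contributes one cross-entropy term;
at test time the per-crop probability vectors of a trial are averaged
and the argmax is the trial prediction.  Feature standardization
(per-cell mean/SD) is fit on the training crops of each fold only.

Cross-validation designs:

* **intra** — per task, trials are split into four groups by seeded
  round-robin dealing (14 trials → {4, 4, 3, 3}); the 12 ordered
  (validation, test) group assignments give 12 folds at 2:1:1.
* **inter** — one fold per held-out subject (all of its trials are
  test data); each remaining subject's trials are dealt evenly into
  training and validation halves per task.

Input families are compared by two-tailed paired t-tests on per-fold
accuracies (Wilcoxon signed-rank available); the degenerate all-zero
difference case returns p = 1.

## 5. Sensitivity maps

M_c(x) = ∂S_c/∂x is the exact reverse-mode gradient of the class score
at the classification layer with respect to the input map, computed in
inference mode.  The score is the pre-softmax logit by default
(standard saliency practice; post-softmax is available by flag, and the
argmax class is invariant to the choice).  Each per-crop map is
standardized by dividing by its own SD — no mean subtraction, signs are
preserved, since the sign (does increasing this cell push toward the
class?) is the object of interest.  Task maps average the standardized
maps over the task's test-partition crops across folds; signed values
are averaged, not magnitudes.  Gradients are taken with respect to the
standardized model input, so all cells share a scale.

## 6. The synthetic cohort

The generator emulates source-space, atlas-averaged neural recordings:

* **Background**: 1/f^α noise (α = 1 by default), unit SD per region,
  via FFT spectral shaping.
* **Oscillations**: alpha ≈ 10 Hz, beta ≈ 20 Hz, gamma ≈ 40 Hz, with
  baseline amplitudes 1.0 / 0.7 / 0.5 relative to the background
  (stronger at lower frequencies, as in cortical spectra).  Each band's
  phase is a random walk: increment 2πf/fs plus Gaussian jitter with
  SD = 0.3 × (2πf/fs), giving a realistic band width.
* **Effects**: inside the task windows of a given task and region
  group, `amplitude_gain` multiplies the band's envelope and
  `regularity_gain` divides the phase-jitter SD.  Higher regularity
  makes the band component more predictable; the entropy map recovers
  it as *lower* expSampEn of the **cos-phase** component (paired sign
  test across 50 trials).  An amplitude gain instead *raises* the
  task windows' amplitude-component expSampEn: the index is
  standardized globally, so a doubled envelope doubles the local
  fluctuation scale in index units and fewer templates match.  Both
  shifts are discriminative and both are asserted in the tests.
* **Default (strong-effect) condition set**: VP → occipital gamma,
  VI → occipital alpha, ME → central beta, MI → central alpha (each
  amplitude ×2, regularity ×4), plus a weaker supramodal prefrontal
  gamma regularity effect (×2) for the imagery tasks.  Directions
  follow the qualitative physiology the task set probes
  (modality-specific bands in modality-specific regions; supramodal
  prefrontal involvement in imagery); the magnitudes are package design
  choices — no quantitative effect sizes exist to copy.
* **Between-subject variability**: effect gains are multiplied by
  N(1, 0.15) per subject by default, making inter-subject decoding
  harder than intra-subject, as expected for real cohorts.
* Region labels default to the 68 Desikan–Killiany names; any label
  set is accepted.  Task cues are not simulated — trial boundaries come
  from the event table.

What the generator does **not** emulate: volume conduction / source
leakage between regions, non-stationary background (drowsiness,
adaptation), artifacts (blinks, heartbeats), cross-frequency coupling,
and evoked transients at task onset.  Passing tests therefore show the
pipeline recovers the kinds of effects it models, at the injected
strengths — not that equally high accuracy would be obtained on real
recordings.

Limitations worth noting: EMD mode mixing makes a strong alpha effect
partially visible in the beta IMF of the same regions, so the decoder
may legitimately spread its sensitivity across neighbouring bands of
the correct regions (visible in the alpha-effect task maps); and at
desk scale the entropy index is capped far below the full-scale index
size, which raises the undefined-point rate slightly (interpolation
covers it).

## 7. Desk-scale problem sizes

The default configuration runs the *entire* pipeline at desk scale
while preserving every structural rule: 3 subjects, 6 regions (2
occipital, 2 central, 2 prefrontal), the 4 decoded tasks, 4 trials per
task, 3 sessions (first is practice), EEMD with 8 ensembles, index cap
30,000, CNN filters 8/16, early-stopping patience 5 with at most 40
epochs.  This yields 6 analyzable trials per task per subject, the full
12-fold intra-subject plan, and 3 × 12 × 6 = 216 test-trial decisions.
The full-scale configuration (8 subjects, 68 regions, 12 tasks, 200
ensembles, cap 500,000) is exposed via `full_scale_config()` but is
slow on one CPU.

## 8. Numerical conventions

* Tolerance comparisons use ≤ r (inclusive), matches counted over
  admissible positions only.
* Max-pool drops trailing rows/columns that do not fill a window;
  pooling larger than the feature map is an error, not a clamp.
* Batch-norm uses running statistics (momentum 0.9) in inference mode;
  saliency backprops through the inference-mode (linear) normalization.
* The engine is float64 end to end; training is deterministic given
  the config seed (fold assignment, initialization, shuffling).
* EEMD ensemble seeds derive from (stage seed, region index); subject
  seeds derive from the master seed — every stage is independently
  reproducible.
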