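# Methods

`surgflow` analyses the workflow of a laparoscopic cholecystectomy (LC)
from the outputs of two phase classifiers — one scoring endoscopic video
frames, one scoring the surgeon's speech — and turns the fused phase
timeline into an assessment of procedural skill. This note documents the
models, the numerical choices, and what the synthetic generator does and
does not establish.

## Phase model

The procedure is described at phase granularity by seven canonical phases
in fixed order: preparation, Calot's triangle dissection, clipping and
cutting of the cystic duct and artery, gallbladder dissection, gallbladder
packaging, cleaning and coagulation, gallbladder extraction. Phase indices
0–6 address this order everywhere. Speech additionally carries a
*pseudo-phase* (always the last, extra index of an audio probability
vector): operating-room talk unrelated to any procedural phase. The
pseudo-phase is consumed during fusion and never appears in segments,
metrics, workflow models or evaluation.

Time is continuous, in seconds from the first video frame. Frames are
instants on a regular grid `t = 0, 1/fps, 2/fps, …`; speech fragments are
half-open intervals `[start, end)` delimited by silences. Half-open
intervals make frame-to-fragment membership unambiguous: frame *i* belongs
to fragment *f* iff `f.start ≤ t_i < f.end`, and a frame at exactly
`f.end` does not.

## Late fusion

Let `a` be a fragment's class posterior over the 7 phases (after removing
the pseudo entry) and `f_1 … f_k` the posteriors of the `k ≥ 1` frames the
fragment covers. The fused distribution of that window is

    fused = w·a + Σ_i ((1−w)/k)·f_i ,   w = audio weight (default 0.5),

a convex combination, assigned with its argmax label to *every* covered
frame. Frames not covered by speech keep their own video posterior
(`video_only` provenance), as do frames under a fragment whose argmax *is*
the pseudo-phase (`audio_eliminated`): such fragments are off-task talk
and are dropped entirely rather than renormalised around the pseudo mass.
Residual pseudo mass on a *kept* fragment is redistributed by
renormalising the procedural entries (configurable; there is no uniquely
right choice, so it is an explicit `FusionConfig` switch).

Numerical conventions:

- **Argmax ties** go to the lowest phase index — deterministic and stable
  under permutation testing. Ties occur only on degenerate inputs
  (e.g. exact 0.5/0.5 after symmetric fusion).
- **`audio_weight = 0`** short-circuits to per-frame video predictions.
  Without the short-circuit the window formula would still average the
  covered frames (labels = argmax of the window *mean*), which is not
  "video only"; treating zero audio weight as "no speech signal" keeps the
  degenerate case equal to the video-only pipeline frame-by-frame.
- **Fragments shorter than one frame period** can cover zero frames; they
  are ignored with a logged warning since there is no frame to carry their
  fused distribution.
- Fused vectors are renormalised to unit mass within 1e-9 on construction;
  convexity keeps them there up to rounding.

## Timeline metrics

The fused timeline is run-length encoded into maximal segments of equal
label. Every frame occupies `1/fps` seconds starting at its timestamp, so
a procedure of `n` frames has total time `n/fps` and the segments tile it
contiguously. From the segments: total time, per-phase time and occupancy
percentage, number of occurrences, and the min/max/mean duration per
occurrence (min = max = mean for a single occurrence; zeros for phases
never visited). Per-phase times sum to the total and occupancies to 100%
by construction.

## Workflow model and comparison

The *workflow* is the embedded Markov chain of the phase sequence:
consecutive duplicate labels are collapsed (self-transitions carry no
routing information — at frame granularity they would dominate the
matrix), and entry `(i, j)` of the transition matrix is the count of
`i → j` jumps divided by all jumps out of `i`, pooled across procedures
when a reference ("average") workflow is built from several recordings.
Phases with no outgoing jump are *terminal*: their rows are all-zero and
they are flagged rather than given an arbitrary distribution.

Two workflows are compared row by row with the first-order Wasserstein
(earth mover's) distance. Phase indices are embedded on the line with unit
spacing in canonical order, so the distance has the closed form

    W(p, q) = Σ_{k=1}^{n−1} |CDF_p(k) − CDF_q(k)| ,

equal to the minimum-cost transport under the `|i − j|` ground metric
(verified against an LP transport solver in the tests). Rows terminal in
*either* model are excluded from the comparison — an all-zero row is not a
probability distribution — and reported explicitly; the summary statistic
is the unweighted mean of the included row distances. The unit-spacing
embedding is a documented choice: it makes "one phase further along the
procedure" cost 1, which is the natural reading when phases are ordered,
but other ground metrics are defensible.

## Evaluation metrics

Predicted frame labels are scored against ground truth with the standard
phase-recognition set: per-class precision, recall, F1 (harmonic mean of
precision and recall) and Jaccard from the confusion matrix,
macro-averaged over the classes **present in the truth** (undefined
per-class ratios contribute 0), plus overall accuracy. Two percentage
summaries are interpretive choices, documented rather than reconstructed:
`avg_error_per_phase = 100·mean_c(1 − recall_c)` over truth-present
classes, and `avg_error = 100·(1 − accuracy)`. sklearn.metrics provides
the arithmetic; an independent hand implementation cross-checks it in the
test suite.

## Synthetic generator

The simulator states a world in which every stage is testable:

- **Procedure**: a phase sequence sampled from a reference embedded chain
  (default: mostly sequential with a packaging ↔ cleaning loop and rare
  back-jumps after unclear dissection planes; extraction terminal), each
  visit drawing a lognormal dwell (moment-matched to a per-phase mean and
  SD; positive and right-skewed like real surgical durations). Default
  dwell means (120, 540, 180, 480, 120, 180, 90 s) give a ~25–30 minute
  procedure; default SDs are 40% of the mean. A `max_transitions` stop
  rule (default 50) guards non-absorbing chains.
- **Video**: frames on the `1/fps` grid (default 1 frame/s — the
  prediction rate is a free parameter of the upstream classifier, not a
  property of this package). Per frame, a predicted class is drawn from
  the confusion-matrix row of the true phase, then a posterior is emitted
  as Dirichlet jitter (concentration 60) around a fixed template with
  `video_peak = 0.85` mass on the predicted class.
- **Speech**: fragment onsets from a renewal process (minimum silence
  1 s plus an exponential gap calibrated to ~4 fragments/min), durations
  clipped normal (6 ± 2 s), each fragment truncated at the end of the
  phase it started in — a narration fragment speaks about one phase, which
  is also what makes silence-cut fragments attributable to a single phase
  annotation-wise. The fragment's true class is the phase at its midpoint,
  replaced by the pseudo-phase with probability 0.15 (off-task talk).
  Emission as for video, over 8 classes with `audio_peak = 0.60`.
- Default confusion matrices are symmetric with diagonals 0.79 (video) and
  0.81 (speech), the reported standalone accuracies of the two modality
  classifiers this package consumes.

Two design points deserve emphasis. First, the **two-stage emission**
(sample a predicted class, then emit a posterior peaked at it) makes the
per-class argmax accuracy equal the confusion diagonal *by construction*,
independent of the concentration; a one-stage Dirichlet centred on the
confusion row would entangle accuracy with posterior sharpness and make
"a classifier with accuracy 0.8" a tuning exercise. Second, the **video
posteriors are sharper than the audio posteriors** (0.85 vs 0.60 peak):
real CNN posteriors are typically more confident than fragment-level
speech models, and with equal 50/50 modality weight an over-confident
wrong fragment would otherwise overrule an arbitrarily long window of
agreeing frames.

Determinism: one `SeedSequence` per simulation spawns three child
generators (procedure + fragment layout; video noise; audio noise), each
consumed in a documented fixed order, so identical configs and seeds give
bit-identical streams and re-rendering one modality cannot desynchronise
the other.

**What a green test does not establish.** The generator emulates the
*data regime*, not the data: conditionally independent classifier errors
given the true phase (real modality errors correlate near phase
boundaries and in visually/verbally ambiguous passages), fragments that
never straddle a phase boundary, no annotation noise, no long-range
temporal error structure. Fusion-benefit results on this world show the
pipeline arithmetic is right and that fusion helps *when modality noise is
independent*; they do not predict the margin on real recordings.

## Known limitations

- Frame-level label noise inflates the number of occurrences and the
  transition counts of the estimated workflow (many spurious one-frame
  segments); the package deliberately applies no temporal smoothing, since
  smoothing belongs to the upstream classifiers. Workflow distances of a
  noisy timeline against a reference are therefore larger than those of a
  human-annotated timeline.
- Timeline quantities are quantized to the frame grid: a phase boundary is
  located at worst `1/fps` seconds from its true position, and noise-free
  recovery of ground truth is exact at frame resolution only.
- The min/max/mean occurrence statistics are reported for every visited
  phase; with a single occurrence they coincide.
- Wasserstein row distances are comparable only between models over the
  same ordered phase set; excluded (terminal) rows make averages across
  procedures with different terminal structure non-trivial to compare.
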