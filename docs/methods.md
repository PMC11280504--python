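# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `fallscore`, and what the synthetic validation does and
does not establish.

## Coordinate and angle conventions

Skeletons are expressed in camera space for a front-facing depth sensor:
x lateral, y vertical, z depth, in metres.  The anatomical planes are mapped
to coordinate pairs — sagittal (z, y), frontal (x, y), transverse (x, z) —
and a joint's planar angle is the included angle between its two projected
segment vectors, both emanating *from* the joint (joint→proximal,
joint→distal).  The angle is arccos of the normalised dot product, with the
cosine clipped into [−1, 1] before arccos, so every channel lies in
[0, 180] degrees by construction.

Joints without two skeleton neighbours (head, hands, hand tips, thumbs,
feet) have no included angle; their channels are emitted as constant zero so
a full series always carries exactly 75 channels.  The spine base, which has
three neighbours, uses its (left hip, right hip) pair — a pelvic included
angle.  None of these conventions affect the modelled channels, which are
restricted to the trunk, hips and knees.

A numerical caveat: arccos is ill-conditioned within ~1° of the collinear
limits, where absolute agreement with an atan2 formulation degrades from
~1e-12 to ~1e-6 degrees.  This is inherent to the formula, far below any
biomechanical signal, and the collinear limits themselves are exact.

## Segmentation

Valley detection smooths the right-knee sagittal trace with a centred
15-frame moving average and finds local minima and maxima with a 20-frame
minimum separation (`scipy.signal.find_peaks`, which unlike a strict
neighbour comparison also handles plateau extrema).  A repetition window
runs from the maximum flanking a valley on the left to the one on the
right; where a flank is missing (movement truncated at a recording
boundary) the boundary frame is used, and adjacent windows may share their
single boundary frame.  Both parameters are configurable; the defaults are
sized for ~30 fps recordings with 2–4 s repetitions.

Quality control applies two rules.  The start/end-angle rule rejects a
repetition whose driving-channel endpoints differ by strictly more than
30°.  The length-outlier rule rejects a repetition whose raw length falls
outside [0.4×, 2.5×] the recording's median repetition length; this is an
automated, reproducible stand-in for a human visual inspection pass, and
the bounds are deliberately loose — they catch gross artefacts (half-cycles,
concatenated double movements) without touching ordinary variation.

Standardisation: Fourier resampling (`scipy.signal.resample`) to 80 frames
per repetition; 60-frame pads on each side (200 frames total) filled by
*edge replication*, chosen over zero padding because a step discontinuity at
the pad boundary would dominate reconstruction error in exactly the region
the distance metric later clips; per-channel scaling of each sample to unit
Euclidean norm (an all-zero channel passes through), with per-channel
min–max as a configurable alternative; and reduction to the 16 modelled
channels, taken as a fixed list.

The pads are 60 frames but the distance clip is 30 frames per side, so the
retained 140-frame window includes 30 pad frames on each side of the
80-frame movement.  Both values are configurable (`pad_frames`,
`clip_frames`); the defaults are kept asymmetric deliberately, which gives
the model a reconstruction target that includes the still lead-in/lead-out.

## Autoencoder

The sequence autoencoder is a bow-tie of LSTM layers: encoder 64 → 16 → 4,
the final hidden state of the 4-unit layer as the latent code, the code
repeated across all 200 time steps, decoder 4 → 16 → 64, and a per-frame
linear map back to 16 channels.  Widths are configurable; the mirrored
structure and latent width 4 are fixed by validation.  The implementation
is pure NumPy — explicit forward pass, full backpropagation through time,
Adam (lr 1e-3, batch 16 by default), global-norm gradient clipping at 5 —
which keeps seeded training bit-reproducible within one software
environment.  Initialisation is Glorot-uniform input kernels, per-gate
orthogonal recurrent kernels, forget-gate bias 1.

Training minimises mean-square reconstruction error on HealthyAdult
repetitions only; a non-healthy sample in the training set is treated as a
label leak and rejected, as is any subject appearing in both the training
and validation splits.  Early stopping interprets "no improvement" as the
validation loss failing to drop by more than 1e-6 for 50 consecutive epochs
(defaults), after which the best-validation weights are restored.

Reconstruction error is the Frobenius norm of the input-minus-reconstruction
difference over the retained 140 frames × 16 channels.

## Scoring and evaluation

For a recording with per-repetition errors ED₁…EDₙ,

score = (1/n) Σ (1 − EDᵢ·σ_ED) = 1 − σ_ED·mean(ED).

σ_ED is the *population variance* of the EDᵢ.  The symbol conventionally
suggests a standard deviation, but the quantity is defined in prose as a
variance and is implemented as such; `sigma_mode="std"` exposes the
alternative.  The score is bounded above by 1 (attained whenever
σ_ED·mean(ED) = 0, e.g. a zero-error or perfectly consistent recording,
including the degenerate single-repetition case, which is logged), is not
clamped below, and decreases monotonically in both the mean error and its
spread.  Lower score = higher risk.

Threshold selection sweeps the unique observed scores plus midpoints,
predicts AtRisk when score < threshold, and picks the threshold maximising
Youden's J = TPR − FPR, breaking ties toward the higher threshold
(favouring sensitivity).  The trapezoidal area under the resulting curve
equals the rank-based Mann–Whitney AUC, which the tests assert to 1e-9.
Binary ground truth groups multiple self-reported fallers and clinically
at-risk subjects as AtRisk; non-fallers and single self-reported fallers as
NotAtRisk.  Scoring operates per recording; where a subject has several
recordings the subject-level score is their mean.

Cross-validated evaluation partitions *all* subjects into k folds —
evaluation subjects stratified by binary class, healthy training subjects
folded alongside so every fold retrains on unseen-by-that-fold healthy
subjects — then scores each fold's evaluation subjects, applying either a
fixed threshold or one selected per fold from the training-side subjects.
Summary statistics are mean, sample SD and a 1.96·SD/√k normal 95% CI.

## Synthetic cohorts

The generator emulates STS-5 recordings at the level the method consumes:
a knee-angle template (standing ~168°, seated ~95°, raised-cosine cycles of
~2.7 s, seated half-cycle lead-in/out) drives a planar two-segment leg
chain per side, constructed so the derived right-knee sagittal channel
reproduces the template to machine precision; the trunk leans forward in
proportion to knee flexion with a slightly curved spine and lateral sway,
so the selected trunk channels vary through the movement; arms and head
ride rigidly on the torso.  Constant per-side lateral offsets keep every
plane projection away from zero length.

Class structure (defaults, chosen once as plausible for the populations
emulated): healthy — relative depth SD 0.03, duration SD 0.04, waveform
distortion scale 0.02, no asymmetry or trunk lag; impaired — 0.15, 0.15,
0.30, 8° left/right depth asymmetry, 0.25 s trunk lag behind the knees.
The per-repetition waveform distortion (amplitude ~N(0, 40·scale) degrees,
envelope vanishing at the boundaries) is the dominant driver of
rep-to-rep reconstruction-error spread, i.e. of the score's separation
between classes.  The default cohort is 50 healthy subjects (40 training
HealthyAdult + 10 held-out NonFaller) and 10 impaired (ClinicallyAtRisk),
5 repetitions each at 30 fps.  All randomness flows from one seed through
spawned per-subject generators, making cohorts byte-identical under a
fixed seed.

What the generator does *not* emulate: sensor noise and joint-tracking
dropouts, a rigid pelvis under asymmetric leg motion, anthropometric
variation between subjects, compensatory strategies (arm push-off,
momentum), and recordings with extraneous movement before or after the
test.  Passing tests therefore demonstrate that the pipeline's machinery —
angles, segmentation, training, scoring, thresholding — behaves correctly
and that the score separates populations whose inconsistency structure
matches its design assumptions; they are not evidence about accuracy on
clinical recordings.

## Problem sizes and numerical choices

End-to-end runs in the test suite use a scaled-down model (encoder widths
16 → 8 → 4, a few dozen epochs, batch 32, lr 3e-3) and the default cohort
sizes; this keeps a full run to roughly a minute on one CPU while leaving
the architecture's topology (3+3 recurrent layers, latent 4) intact.  The
held-out separation check (rank AUC ≥ 0.9 on 10 healthy vs 10 impaired
subjects) passes with margin under these sizes.  Tolerances follow the
quantity's conditioning: exact or 1e-12 for closed-form algebra, 1e-9 for
well-conditioned oracle comparisons, 1e-6 for FFT-based resampling and for
the generator round-trip.

## Known limitations

* The 16-channel selection is taken as given, not re-derived.
* The autoencoder is CPU-bound NumPy; it is sized for cohort-scale studies,
  not large-scale training.
* Scores can in principle go negative for extreme error/spread products;
  they are reported as-is.
* Missing or zero-confidence joints are rejected at ingest rather than
  imputed.
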