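# fallscore

Objective falls-risk scoring from markerless motion capture of the
five-times-sit-to-stand (STS-5) test.

Falls are the leading cause of injury-related death in people over 65, yet
falls risk is usually assessed with a stopwatch: how long do five
sit-to-stand cycles take?  Skeleton tracking from a depth sensor captures far
richer information — how the hips, knees and trunk coordinate through every
repetition.  `fallscore` turns 25-joint skeleton recordings of the STS-5
test into a continuous falls-risk score for clinicians and movement
researchers, using a *representational model*: a recurrent autoencoder
trained only on healthy adults, so that how poorly it reconstructs a new
recording measures how far that movement lies from the healthy norm.

## Method

1. **Joint angles.**  For every joint with two skeleton neighbours, the
   planar angle between the segment vectors *a*, *b* meeting at the joint is

   θ = arccos( *a*·*b* / (‖*a*‖‖*b*‖) )

   computed per frame in the three anatomical planes (sagittal, frontal,
   transverse), giving 25 × 3 = 75 channels in degrees.

2. **Repetition extraction.**  The right-knee sagittal channel traces five
   flexed-knee valleys (seated phases).  Each valley, delimited by its
   flanking local maxima, is one repetition.  A repetition whose start and
   end angles differ by more than 30° is rejected, as is any whose length is
   an outlier for the recording.  Accepted repetitions are Fourier-resampled
   to 80 frames, padded with a 2 s (60-frame) edge buffer to 200 frames,
   per-channel normalised to unit Euclidean norm, and reduced to the 16 most
   informative channels (trunk sagittal/frontal, hips in all planes, knees
   sagittal/frontal).

3. **Representational model.**  A bow-tie LSTM sequence autoencoder
   (3-layer encoder 64→16→4, latent width 4, mirrored decoder, per-frame
   linear output) is trained with mean-square error on healthy-adult
   repetitions only, with patience-based early stopping.  It is implemented
   in pure NumPy (explicit backpropagation through time, Adam) and is
   bit-reproducible under a fixed seed.

4. **Scoring.**  Each repetition's reconstruction error ED is the Euclidean
   distance between input and reconstruction after clipping 30 pad frames
   from each end.  A recording with repetitions ED₁…EDₙ scores

   score = (1/n) Σᵢ (1 − EDᵢ · σ_ED) = 1 − σ_ED · mean(ED)

   where σ_ED is the variance of the EDᵢ.  Healthy movers are *consistent*
   (σ_ED ≈ 0, score ≈ 1); at-risk movers produce larger and more variable
   errors, dragging the score below 1.  An at-risk threshold is chosen from
   a ROC sweep of the observed score range (maximum Youden J); a subject is
   flagged **AtRisk** when score < threshold.

Because the reference dataset of clinic-style recordings is not bundled, the
package ships a first-class synthetic cohort generator that emits skeleton
*positions* with the statistical structure the method relies on: smooth,
low-variance repetitions for healthy subjects; amplitude/duration jitter,
per-repetition waveform distortion, left/right asymmetry and trunk lag for
at-risk subjects.

## Worked example

One command runs the whole chain — generate a cohort, compute angles,
extract repetitions, train the autoencoder on healthy subjects, score the
held-out subjects, and pick a ROC threshold:

```bash
fallscore demo --config demo.yaml --seed 1 --out run/
```

with `demo.yaml`:

```yaml
cohort:
  n_healthy: 12        # 8 train (HealthyAdult) + 4 held-out (NonFaller)
  n_healthy_test: 4
  n_impaired: 4        # held-out ClinicallyAtRisk
model:
  encoder_units: [16, 8, 4]
  decoder_units: [4, 8, 16]
  max_epochs: 25
  patience_epochs: 10
  batch_size: 32
  learning_rate: 0.003
```

prints

```json
{
  "auc": 0.9375,
  "threshold": 0.9999359692450682,
  "accuracy": 0.875,
  "specificity": 0.75,
  "sensitivity": 1.0,
  "n_test_subjects": 8,
  "n_train_subjects": 6,
  "n_val_subjects": 2,
  "stopped_epoch": 25
}
```

and writes `run/scores.csv`, whose first rows look like

```
subject_id,class_label,n_reps,mean_ed,sigma_ed,score,verdict
H008,NonFaller,5,0.883524100412,7.17047776235e-05,0.999936647101,NotAtRisk
H009,NonFaller,5,0.884242795172,2.40771535392e-05,0.99997870995,NotAtRisk
```

Reading: every subject's five repetitions were reconstructed by the
healthy-trained model; `mean_ed` is the average reconstruction error,
`sigma_ed` its variance across the repetitions, and `score` the falls-risk
score — here the held-out healthy subjects sit just below 1 while the
at-risk subjects fall further away, giving a held-out AUC of 0.94 on this
deliberately small 8-subject test set (larger cohorts, e.g. the default
40-train/10+10-test configuration, separate the classes completely).  The
individual stage commands (`fallscore synth/angles/segment/train/score/
evaluate`) expose the same pipeline piecewise; see `fallscore --help`.

## Layout

| module | role |
| --- | --- |
| `fallscore.skeleton_io` | recording/angle containers, CSV + HDF5 I/O |
| `fallscore.kinematics` | planar joint angles (75 channels) |
| `fallscore.segmentation` | valley detection → validated 200×16 repetitions |
| `fallscore.autoencoder` | NumPy LSTM sequence autoencoder + training |
| `fallscore.scoring` | falls-risk score, ROC threshold, cross-validation |
| `fallscore.synthetic_data` | seeded synthetic STS-5 cohorts |
| `fallscore.pipeline` / `fallscore.cli` | end-to-end orchestration and CLI |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
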