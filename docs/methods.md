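# Methods

## The fusion model

The image-augmented deterioration index is a late-fusion classifier. At each
4-hour prediction window it sees four features: the most recent
radiograph-derived risk score, the deterioration-index (DI) value for the last
completed window, hours since that radiograph, and hours since admission. The
network is deliberately tiny — 4 inputs, one hidden layer of five
rectified-linear units, a single sigmoid output — because its job is only to
recalibrate and combine two already-informative probability-like scores with
two recency covariates; anything larger invites overfitting at the cohort
sizes this setting provides.

Training minimizes instance-level binary cross-entropy with mini-batch
gradient descent at learning rate 0.001, batch size 64, for up to 200 epochs
with patience-20 early stopping; the returned weights are the epoch checkpoint
with the lowest validation BCE. The default optimizer is Adam: at the fixed
learning rate of 0.001 plain SGD moves the (fan-in-scaled, uniformly
initialized) weights too slowly to converge within the epoch budget on even a
linearly separable problem, while Adam's per-parameter step normalization
reaches the attainable loss floor reliably; plain SGD remains available via
`TrainConfig(optimizer="sgd")`. Given a seed, initialization and batch
shuffling are fully reproducible and training is bit-deterministic.

The two elapsed-time features are passed in raw hours and z-scored inside the
model with training-set statistics (frozen into the checkpoint). Without this
the hour-scale features dominate the unit-scale scores under a shared learning
rate; the standardizer makes the optimization landscape comparable across
features while keeping the public interface in natural units.

Two tasks, two separately trained models:

* **low_risk** — label: the patient ever deteriorates; instances from the
  first radiograph through the window starting at 48 h.
* **high_risk** — label: deterioration within 120 h; instances through 120 h,
  with the event-containing window and the window immediately before it
  removed. The conservative two-window censoring prevents the model from
  learning the event's immediate prodrome as a shortcut (label leakage).

Splits are by hospitalization, never by instance: all windows of one admission
live in one split. The default validation fraction is 30%.

## Grid and alignment conventions

Windows are half-open `[start, start + 4)` hours, anchored at admission
(admit time = 0). A prediction "at" a window is made at the window's end
(`hours_since_admit = start + 4`), and its features are functions of data
observed at or before the window start:

* the index feature is the maximum raw DI score in the last *completed*
  window `[start-4, start)`, carried forward through observation gaps
  (last-observation-carried-forward, mirroring the image carry-forward);
* the image feature is the most recent radiograph score with radiograph time
  ≤ start, and `hours_since_xray = start − that time` (0 at a radiograph
  exactly on a grid point).

This "last completed window" convention is what makes the leakage probe exact:
perturbing any score after a window's start can never change that window's
features. The first usable window start is the smallest grid point ≥ the first
radiograph time, floored at 4 h (one completed index window must exist), so an
admission yields at most 12 low-risk and 30 high-risk instances. The fused
model emits nothing before the first radiograph by default; the
`pre_xray_policy="di_passthrough"` option instead fills pre-imaging windows
with the raw DI score so the combined index covers the whole stay.

Multi-horizon labels (deterioration within 12/24/48/72/96/120 h of a reference
time, or ever) are provided for training multi-task image models upstream;
nothing in this package consumes them.

## Evaluation protocol

Low-risk triage: per patient, the mean of all window predictions with window
start < `upto` (`upto` ∈ {24, 32, 40, 48} h); patients deteriorating before
`upto` are excluded, since early discharge is moot for them. Patients are
sorted by ascending aggregated risk (ties broken by hospitalization id for
determinism) and the threshold swept: flagging the k lowest, `NPV(k)` is the
fraction of flagged patients who never deteriorate. The reported count at a
target NPV is the **largest k with NPV(k) ≥ target** — NPV is non-monotone in
k and a single swept threshold corresponds to a single k; a conservative
variant (largest prefix never dipping below the target) is available via
`strict_prefix=True`.

High-risk discrimination: per patient, the maximum window prediction (windows
at/after the event were already censored), labelled by deterioration within
120 h; AUROC in the Mann–Whitney form (ties ½), plus specificity at the
highest threshold whose sensitivity reaches 0.8.

Confidence intervals: percentile bootstrap (2.5/97.5) over 1000 resamples of
hospitalizations — the inferential unit is the admission, not the window.
Single-class resamples are redrawn and logged; if more than 10% of resamples
fail the metric, the CI errors out rather than silently shifting.

The DI-only baseline is evaluated with the same machinery on the same grid:
its per-window "prediction" is exactly the index feature the fused model sees.
The baseline can score patients from admission (it needs no radiograph), so
per-model counts have different denominators; `run_pipeline` therefore reports
both each model's counts on its own evaluable patients and a like-for-like
comparison restricted to the patients both models can score, which is what the
headline deltas use.

The exponential-moving-average smoother (`ewma_smooth`,
`y_k = α·x_k + (1−α)·y_{k−1}`) exists for plotting NPV curves only; counts are
always taken from the raw curve.

## The cohort simulator

Real DI streams are proprietary and the source cohorts single-center, so the
package generates synthetic hospitalizations with the latent structure the
method assumes. Per patient: shared severity `s ~ N(0,1)` and image-specific
latent `u ~ N(0,1)`; deterioration
`~ Bernoulli(sigmoid(logit(p0) + w_s·s + w_u·u))` with base rate `p0 = 0.3`
(the deteriorating fraction of a COVID-era oxygen-supported inpatient
population) and unit weights by default. The DI observes only `s`
(`sigmoid(−1 + s + ε)`, ε sd 0.5, at 15-minute or 4-hour cadence); each
radiograph observes both (`sigmoid(−1 + s + u + η)`, η sd 0.5). The intercepts
(−1) skew scores low, as deployed indices do; the noise sds make single
observations clearly informative but far from definitive. `w_u` is the
experiment's control knob: at 1 the radiograph carries outcome signal the DI
cannot see (augmentation should help); at 0 it is only a second noisy view of
`s` (augmentation should be roughly neutral).

Stay and event process: length of stay ~ Gamma(shape 2, mean 96 h); event time
uniform on (4 h, min(stay, 120 h)); event type multinomial with the renormalized
first-event mix of a COVID test cohort (death 4.3%, mechanical ventilation
9.5%, heated high-flow nasal cannula 82%, vasopressors 4.3%) — metadata only,
nothing downstream reads it. The first radiograph is uniform on (0, min(48 h,
stay)); the radiograph count is geometric with mean 1.8 (the images-per-
hospitalization ratio of the motivating data), later radiographs uniform over
the remaining stay. 97% of patients are on supplemental oxygen. Each patient
draws from an RNG stream keyed by (seed, patient index), so cohorts are
reproducible and membership-order independent.

Inclusion filters (first matching reason wins): requires oxygen support; a
radiograph within 48 h; no deterioration or discharge within 4 h of
presentation; no deterioration before the first radiograph. When a patient has
multiple qualifying events the first is the deterioration time.

What the simulator does **not** emulate: vital-sign physiology, wall-clock
prediction schedules (grids are admission-anchored), radiographic phenotypes,
informative imaging times (in real care sicker patients are imaged more
often), score autocorrelation beyond the shared latent, or repeat admissions.
Passing tests therefore demonstrate that the pipeline recovers image-borne
signal under the assumed latent structure — not that augmentation helps in any
particular hospital's data.

## Study conditions and problem sizes

The canned signal-recovery experiment (`detfuse.study`, used by
`scripts/acceptance.py`) simulates disjoint train/validation/test cohorts of
2000/600/3000 admissions before filtering. The evaluated cohort is the largest
of the three because the largest-k-at-NPV count is a tail statistic: at a few
hundred evaluated patients it is dominated by whether a handful of late
deteriorators (whose pre-48 h observations genuinely look clean) land just
inside or outside the flagged prefix, while at ~2000 evaluated patients the
comparison between models is stable. Training cohorts of this size fit the
five-node network to its attainable loss floor in seconds.

## Numerical choices and degenerate inputs

* BCE is computed with predictions clipped to [1e-12, 1−1e-12]; training
  aborts with diagnostics on a non-finite loss.
* Feature standardization floors the sd at 1e-8 (constant features pass
  through centered).
* Single-class training or validation splits are rejected up front, as are
  instances with missing features (the offending field is named).
* Ties: NPV sweep orders by (score, hosp_id); AUROC counts ties ½; the
  sensitivity-0.8 operating point takes the highest qualifying threshold.
* `count_low_risk_at_npv` returns 0 when no k attains the target.
* Empty prediction windows: an admission discharged before its first usable
  window yields an empty instance list with a warning, and is dropped (with a
  warning) from aggregation.
* Checkpoints serialize as versioned JSON — portable, diffable, and loadable
  without pickle.

## Known limitations

The simulator's independence and distributional assumptions are favourable to
the method; effect sizes measured here do not transfer to any real cohort. The
NPV-count statistic remains noisy at small cohort sizes even with a perfect
model. The network is fixed at 4→5→1 by design; there is no hyperparameter
search. Calibration, decision-curve analysis and time-to-event modelling are
out of scope.
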