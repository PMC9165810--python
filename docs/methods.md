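# Methods

## Scope and data model

The package decodes three motor-execution states — rest, left-fist,
right-fist — from 64-channel scalp EEG sampled at 160 Hz. The unit of
analysis is the *epoch*: a 4.5 s window (720 samples) cut at an annotation
onset, half-open in 0-based samples, `[start, start + 720)` with
`start = round(onset x fs)`. Annotations use the T0/T1/T2 convention of
the PhysioNet motor runs (T0 rest, T1 left fist, T2 right fist); rest
epochs are cut from the T0 segments of the same fist-movement runs, one
per onset, with no overlapping windows — the minimal rule consistent with
the roughly 2:1 rest:movement epoch counts such runs produce. Windows
that would extend past the end of a recording are skipped and counted,
never truncated. Recordings at any rate other than 160 Hz are rejected
rather than resampled, because resampling would introduce a processing
step the rest of the pipeline never validates. Subjects 88, 89, 92 and
100 of the PhysioNet cohort (incomplete sessions) are excluded by
default.

Splits are always subject-disjoint. `make_split_plan` draws the test
subjects uniformly without replacement, then shuffles the remainder once
and chunks it into k contiguous validation folds (sizes differing by at
most one); each fold trains on all remaining non-test subjects. All
randomness flows through named substreams (`split`, `init`, `batching`,
`augmentation`, `synthesis`, `permutation`) spawned from one global seed,
so regenerating any one component never perturbs the others.

## Preprocessing and augmentation

Each epoch is standardized to mean 0 / sd 1. The default scope is *per
channel within the trial*, because inter-electrode impedance and noise
differences are the stated motivation for normalizing at all; a
whole-trial pooled scope is available (`zscore_scope="per_trial_pooled"`).
Channels with exactly zero variance raise a degenerate-input error naming
the channel.

Training augmentation adds "10% trial-scale and 3% channel-scale"
Gaussian noise. That phrase admits two readings; the default implements
it as *scalar offsets* — one draw t ~ N(0, 0.10^2) added to every sample
of the trial plus one draw c_k ~ N(0, 0.03^2) per channel k — and the
alternative (`mode="iid_samples"`) draws independent noise per sample at
the same sigmas. Offsets are drawn fresh every time a trial enters a
batch. Augmentation is applied to training batches only; the training
loop accounts for every augmented sample, and the tests assert that
validation and test epochs are never augmented.

## Architecture

The network is assembled from five block types on one implicit input map
(channels x time = 64 x 720); the channel axis is the 2-D "height".
Temporal convolutions — the (1, 64) kernels of the type-0/1 blocks and
the (1, 16) depthwise kernels of the type-3/4 blocks — use 'same'
padding, which is forced by the requirement that the tenth type-1 block
still emit 64 x 720 feature maps (the Grad-CAM target layer). For even
kernels the padding is one sample heavier on the future side
(pad_left = (k-1)//2). The spatial (64, 1) convolution uses no padding
and collapses the electrode axis to 1, doubling the map count to
F1 x D = 16, with a max-norm cap of 1 on each output filter, re-projected
after every optimizer step (the cap applies only to this block).
Type-1/3 blocks are implemented literally as convolution + batch norm +
identity residual with *no* activation function; ELU appears only in the
type-2 and type-4 blocks. A config flag can insert ELU after each
residual add for experimentation (off by default). Depthwise and
pointwise convolutions run in that order with no intermediate activation.
Convolutions carry no biases (each is followed by batch norm); the
classifier head carries one.

Average pooling is non-overlapping with floor division, so a 720-sample
epoch leaves 720/4 = 180 and then 180//8 = 22 time steps. The nominal
classifier kernel width of 23 is inconsistent with those pooling widths;
the classifier kernel is therefore *derived from the traced extent* at
build time (22 for 720-sample inputs) and a warning is logged whenever it
differs from 23. Internal consistency was preferred over a literal
constant.

Batch normalization uses eps = 1e-5 and running-average momentum = 0.1
(conventional defaults, recorded in the layer summary). Ablation toggles
(`use_residual`, `use_batchnorm`, `use_dropout`) remove exactly the named
component and nothing else; the residual shortcut is parameter-free, so
parameter counts are unchanged by its removal.

### Numerical implementation

No deep-learning framework is a dependency; the model runs on a compact
reverse-mode layer engine written for these blocks. Internally tensors
are time-major `(time, maps, batch, channels)` so that the temporal
convolutions can run as circular cross-correlations in the frequency
domain: one real FFT along the leading axis, one batched per-frequency
complex matmul for the map mixing, one inverse FFT. Padding alignment is
folded into precomputed phase factors, and FFT lengths satisfy
L >= T + k - 1 so the circular wrap never touches signal. Adjoints
(input and weight gradients) are derived in closed form and validated
against brute-force loop implementations and central finite differences.
Forward spectra are cached for reuse by the weight-gradient pass, and the
first block skips its (unused) input gradient. Training uses float32 by
default for throughput; gradient-check tests build float64 models.

## Training

Plain SGD with classical momentum (v <- mu v + g, w <- w - lr v),
mu = 0.9, cross-entropy on the log-softmax outputs, batch size 100,
initial learning rate 1e-3 under a single cosine arc
lr(s) = lr0 (1 + cos(pi min(s, T)/T))/2 stepped per optimizer iteration
(T = t_max = 29,000 by default), held at zero beyond t_max, no restarts.
Batches are drawn by reshuffling the pooled training epochs each epoch.
Class imbalance (rest about twice each movement class on real runs) is
left unweighted. Model selection keeps the parameters of the epoch with
the highest validation accuracy — the selection rule is recorded in the
training state together with the full loss/accuracy/learning-rate traces
— and the final-epoch parameters are kept alongside. An optional
`early_stop_val_acc` threshold ends a run once validation accuracy
reaches it; scaled-down experiments use it as a convergence shortcut.
A non-finite loss aborts with diagnostics rather than continuing.

## Evaluation and statistics

Predictions are arg-max over log class scores with exact ties broken
toward the lowest label index (ties are counted and logged). The
confusion matrix is counts[actual][predicted]; accuracy is trace/total;
per-subject accuracies group trials by participant. Cross-validation
trains one model per fold on the fold's training subjects, selects on its
validation subjects and evaluates every fold's model on the *same* fixed
test subjects; subject leakage anywhere raises before any training
starts.

Model variants are compared with Welch's unequal-variance t-test,
two-tailed, with Welch–Satterthwaite degrees of freedom, taking the
cross-validation *fold* as the experimental unit (n = fold count of
accuracies per variant) — the only reading that reproduces the published
p-values from the published per-variant means and sds. The comparison
family (every variant against the reference) is corrected with the
Benjamini–Hochberg step-up procedure; both raw and adjusted values are
reported, since the published table appears to print raw p-values.
`welch_t_test` accepts raw samples or (mean, sd, n) summaries and the two
paths agree to machine precision; `bh_fdr` delegates to statsmodels'
`fdr_bh` and is tested against an exhaustive brute-force step-up rule.

## Grad-CAM attribution

For a trial and class c the differentiated score y^c is the model's
*pre-softmax logit* for c, the convention of common Grad-CAM practice;
the log-softmax output is available via `score="log_softmax"` and the
choice is recorded in result files. The logit is the default because the
log-softmax output of a confident model saturates at 0 on exactly the
correctly classified trials this protocol aggregates, so its gradients —
and with them every map — vanish. Feature maps
A^k and gradients dy^c/dA^k are captured at a named block — by default
the tenth temporal-residual block, whose maps retain full 64 x 720
resolution, so no upsampling is involved. Weights are the
global-average-pooled gradients alpha_k = (1/Z) sum_ij dy^c/dA^k_ij and
the heatmap is L^c = ReLU(sum_k alpha_k A^k). Heatmaps are *not*
rescaled per trial: all group statistics compare scores against a
cross-channel baseline, which any per-trial normalization would distort.

Group analysis keeps correctly classified trials only, computes Grad-CAM
w.r.t. the true class, averages maps per participant and task, and takes
the time mean per channel. The baseline is each participant's mean over
the 64 channel scores. Per task, each channel's scores are tested
against the baselines across participants (Welch, unpaired, two-tailed)
with BH control over the 64 channels; the participant is the
experimental unit, and participants with no correct trial for a task are
excluded from that task's family (logged). Time-resolved tests repeat
this per channel and time point with a per-time-point baseline (mean over
channels at that time point) and BH over the 64 x T family per task; the
per-time-point baseline construction is an assumption of this package,
recorded here because the equivalent published analysis does not state
its own.

## Synthetic data

The generator emulates the geometry and the class structure of the real
recordings: 64 x 720 epochs at 160 Hz, three balanced classes per
subject, subject-level variability as a multiplicative gain
g ~ N(1, 0.1^2). Every channel carries broadband Gaussian noise
(sd 1.0) plus a sinusoid at a per-epoch frequency drawn uniformly in the
mu band (10–13 Hz) with independent per-channel phases and amplitude 1.0;
on a class's planted channels the sinusoid amplitude is multiplied by
(1 - effect_amplitude) for that class's epochs — an event-related
desynchronization surrogate. Everything is deterministic given the spec
seed (bit-identical regeneration).

What it deliberately does not model: volume conduction or any forward
model (channels are independent), non-stationarity within a trial,
artifacts (EOG/EMG), 1/f spectra, or inter-subject differences beyond a
gain. Passing the recovery tests therefore shows the *pipeline* is
correct — the model can find a known band-power effect and Grad-CAM
points at the right electrodes — not that comparable accuracy would be
reached on real EEG, where the effect is weaker and confounded.

## Scaled-down study sizes

The full protocol (105 subjects, 5-fold cross-validation, 29,000 SGD
iterations per model) is far beyond a single-CPU test run, so the
experiments the package validates itself with are scaled down, chosen
once as follows:

* **Overfit sanity**: 2 subjects x 8 trials/class, effect 0.9, reduced
  model (2 type-1 blocks, 1 type-3 block), 30 epochs, batch 16,
  lr0 5e-3. The reduced model must memorize its single training subject
  exactly (training accuracy 1.0); its validation subject measures
  nothing here.
* **Attribution recovery**: 10 subjects x 8 trials/class with one
  planted channel per movement class (8 for LEFT, 12 for RIGHT), an
  almost noise-free mu rhythm (oscillation amplitude 1.0, broadband
  noise sd 0.1) and complete event-related silencing (effect 1.0) — a
  dataset built to be cleanly separable, standing in for the statistical
  power a 100-subject corpus provides at full scale.
  Training uses a small configuration (F1=4, one type-1 and one type-3
  block, kernels 16/8) at lr0 0.01 with the cosine horizon matched to
  the actual number of iterations of the run, since the published
  horizon of 29,000 steps would leave a short run effectively
  un-annealed. The trained model must exceed 90% accuracy on held-out
  subjects; Grad-CAM channel statistics over all 10 subjects must flag
  the planted channel for its class, and a model retrained on
  within-subject label-permuted data (the null) must flag nothing.
* **Cross-validation orchestration** is exercised end-to-end at 2 folds
  on a 6-subject dataset with a few epochs — enough to prove the
  plumbing (leakage guards, per-fold results, aggregation), with the
  accuracy claims carried by the two experiments above.

## Known limitations

* The engine is CPU-only and optimizes for this block family; it is not
  a general autodiff system.
* Batch-norm running statistics make train-mode forward outputs depend
  on batch composition; determinism is guaranteed only for a fixed seed
  and fixed batch schedule (asserted by the tests).
* EDF+ ingestion requires the optional `mne` dependency and is excluded
  from the default test run because real recordings are binary and not
  shipped.
* The classifier kernel follows the traced extent (22 for 720-sample
  input), not the nominal 23; see Architecture above.
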