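# Methods

This note documents the models and procedures implemented in `semgimg`,
the conventions chosen where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Signal model and preprocessing

The unit of input is a `Recording`: a samples × channels matrix of
non-negative envelope amplitudes with a sampling rate and
(subject, stimulus, repetition) provenance.  Recordings are assumed to be
pre-segmented per movement execution (one file per
subject/gesture/repetition, named `SSS_GGG_RRR.mat`), so no movement
onset/offset detection is performed and no rest-period samples are
expected inside a recording.

**Windowing.**  Windows are TW = 200 ms with stride TS = 100 ms by
default.  Sample counts derive from milliseconds as `round(ms · fs /
1000)`; at 100 Hz this gives 20/10 samples exactly.  Only complete windows
are emitted — an incomplete tail is dropped rather than padded, because
padding would distort the Gramian and transition-field encodings, both of
which are functions of the whole window.  The window count for an
n-sample recording is therefore `max(0, floor((n − tw)/ts) + 1)`.

**Wavelet denoising** (arm-band acquisitions).  Each channel is
independently decomposed with the db4 wavelet to level 4, the detail
coefficients are soft-thresholded with the universal (VisuShrink) rule —
σ estimated from the median absolute deviation of the finest detail band,
threshold σ·√(2 ln n) — and the channel is reconstructed to its original
length.  Only the wavelet family is externally constrained; the level and
threshold rule are package defaults chosen as the standard shrinkage
recipe.  A zero threshold (noiseless channel) leaves coefficients
untouched.

**Downsampling.**  Decimation requires an integer factor (500 → 100 Hz is
factor 5) and applies a zero-phase FIR anti-alias low-pass before keeping
every k-th sample, so constants survive to ~1e-7 in the filter interior
and no phase shift is introduced.

## Image encodings

All three encodings operate per window and are self-contained: rescaling
statistics are computed within the window (per channel), never from the
whole recording, so encoding works identically in an online setting.

**Sigimg.**  The tw × C window is tiled horizontally as C blocks, block k
being the window with its columns cyclically rotated by k; block 0 is the
original window and every channel column appears exactly C times, giving
a tw × C² image (20 × 100 for the 10-channel configuration).  Cyclic
rotation makes each channel adjacent to its cyclic neighbours at distance
1 (within blocks) and 2 (across block boundaries); for C ≤ 5 this
realizes every unordered channel pair somewhere in the image, for larger
C it covers the cyclic-neighbour pairs.  The rotation tiling was chosen
as the simplest arrangement reproducing the reference 20 × 100 geometry.

**GADF.**  Each channel is rescaled to [−1, 1] by the two-sided map
x̃ = ((x − max) + (x − min)) / (max − min); a constant channel (zero
range) maps to all zeros, the midpoint, by convention.  Angles are
φ = arccos(x̃) with inputs clipped to [−1, 1] at 1e−12 for floating-point
safety; radii t/N (N = n) are carried in `PolarSeries` for completeness
but the Gramian uses only angles.  The matrix is G[i,j] = cos(φᵢ − φⱼ) —
symmetric with unit diagonal.  The sine-difference variant common in the
wider time-series-imaging literature is available as
`gadf_formula="sin_diff"`; the cosine form is the package default.

**MTF.**  Channel values are assigned to Q empirical quantile bins
(edges `np.quantile(x, linspace(0, 1, Q+1))`, intervals half-open on the
right, last interval closed; duplicate edges from tied data collapse
harmlessly).  The transition matrix is the forward Markov estimate:
W[a,b] = #(bin a → bin b among consecutive pairs) / #(pairs leaving a).
Rows with no outgoing transitions are set to the uniform distribution
1/Q so that row-stochasticity (ΣⱼW[i,j] = 1) holds on every input.  The
field is M[i,j] = W[bin(xᵢ), bin(xⱼ)].  Q is not externally constrained;
the default is Q = 8, exposed in every API that encodes.

**Stitching and normalization.**  Per-channel n × n GADF/MTF sub-images
are concatenated horizontally in channel order (n × C·n; 20 × 200 for
C = 10).  Each of the three final images is min-max normalized to [0, 1]
per image; a constant image maps to zeros.

Numerical caveat: GADF/MTF are invariant to positive affine transforms of
the raw window only up to floating-point conditioning — a transform that
absorbs small value differences (or a sample sitting exactly on a
quantile edge) can flip a bin.  The property tests therefore check
invariance on well-conditioned inputs.

## Architectures

Declarative `BranchSpec`/`ModelSpec` objects describe the networks; a
builder instantiates them as numpy layer stacks.  The reference
three-stream configuration (20-sample, 10-channel windows):

| branch | input | stack | flatten |
|---|---|---|---|
| Sigimg | 20×100×1 | conv16@3×3 (s1,p1) → pool2×2 → conv32@3×3 (s1,p1) → pool2×2 | 4000 |
| GADF | 20×200×1 | conv16@3×3 (s1,p1) → pool2×2 → conv32@5×5 (s1,p2) → pool2×2 | 8000 |
| MTF | 20×200×1 | same as GADF | 8000 |

Features are concatenated (20000) and fused through dense layers
4096 → 2048 → classes.  Single-stream variants reuse one branch with
dense stacks 1024/256 (Sigimg) or 2048/512 (GADF/MTF); dual-stream
variants pair (Sigimg, GADF) or (GADF, MTF) branches with 4096/1024.
Positions of batch norm (conv → BN → ReLU) and dropout (rate 0.5 before
every fusion dense layer) are package conventions — the techniques are
externally constrained, their placement is not.  Weights use fan-in
scaled (He) normal initialization from a seeded generator.

`width_scale` multiplies conv filter counts (0.5 gives the half-width
desk-scale model); `fc_sizes` overrides fusion widths.  Max pooling is
2×2 stride 2 and drops odd trailing rows/columns (floor); in the
reference geometry every pooled dimension is even, so no rounding occurs.

**MAC counting.**  Conv MACs = outH·outW·outC·kH·kW·inC; dense
MACs = in·out; batch norm, biases, pooling, and activations are not
counted.  The counts are used for ordering/complexity comparisons between
the architecture variants; other published counts for equivalent models
may use different conventions and are not comparable digit-for-digit.

## Training and evaluation

The optimizer is Adam on softmax cross-entropy, batch size 100, 30
epochs, dropout 0.5, and a piecewise-constant schedule: initial learning
rate 0.1 divided by 10 at epochs 16 and 24.  "Epoch" means one full pass
over the training set.  Training is bit-reproducible for a fixed seed:
initialization, shuffling, and dropout masks all derive from it.  The
preliminary tuning ranges (lr 0.001–0.01, batch 32–128, dropout 0.3–0.5)
remain legal configurations; desk-scale experiments in the test suite use
Adam at lr 10⁻³ from that range, since the 0.1 schedule is tuned for the
full-scale problem and overshoots on small synthetic datasets.

**Metrics.**  Per-subject accuracy is Aᵢ = correctᵢ/totalᵢ over subject
i's test windows; the headline accuracy Ā is the unweighted mean over
subjects (subjects with no test windows are excluded).  Precision and
recall are per-class one-vs-rest scores averaged macro by default
(configurable to micro); the confusion matrix has true classes as rows.
The split protocol is repetition-wise: train {1, 3, 4, 5, 6, 8, 9, 10},
test {2, 7} — 4:1 — so no window of one movement execution leaks across
the split.  One pooled model is trained on all subjects and evaluated
per subject.

**Cross-validation.**  Repeated stratified k-fold (default 5 folds, 10
repeats), reshuffled per repeat with seeds `seed + r`, reporting the
grand mean and standard deviation; stratification downgrades to plain
k-fold with a warning when a class has fewer samples than folds.

## Synthetic data generator

The generator emulates RMS-rectified envelope recordings: each gesture
owns a fixed non-negative channel-activation weight vector (redrawn until
all pairwise cosine similarities are below 0.95), each repetition is a
sum of 2–4 Gaussian activation bursts (centers uniform in the middle 80%
of the repetition, widths 0.5–2 s) scaled by the gesture weights, a
per-subject log-normal gain, and per-repetition log-normal amplitude
jitter; folded (absolute-value) Gaussian noise is added at a configured
SNR (default 10 dB, defined as clean-RMS over noise σ).  Defaults mirror
the benchmark acquisition: 10 channels at 100 Hz, 5 s per repetition, 10
repetitions; an `armband()` preset gives 8 channels at 500 Hz with 6
gestures and 30 repetitions.

The class signal is a *channel pattern*, deliberately strong enough that
a nearest-centroid classifier on per-channel mean amplitudes exceeds 80%
held-out accuracy — this guarantees that failures to learn indict the
model, not the data.  The generator carries none of the electrode-shift,
crosstalk, inter-session, or fatigue structure of real sEMG, so passing
the synthetic experiments shows that the pipeline is implemented
correctly and can recover a known signal; it does not predict accuracy
on real recordings.

## Problem sizes in the test suite

Desk-scale experiments use 5 subjects × 6 gestures × 10 repetitions at
the default SNR, windowed at a 1 s stride (1200 train / 300 test
windows), and a half-width three-stream model (fusion 1024/256) trained
10 epochs with Adam at lr 10⁻³ — sizes chosen so the whole suite runs on
a single CPU in minutes while leaving the learned signal far above the
16.7% chance level.  The three-stream vs single-stream comparison is
reported (not asserted) at a further reduced scale: a third of the
training windows, 3 epochs, 3 seeds.

## Known limitations

- The CNN engine supports exactly the layer vocabulary these
  architectures need (stride-1 'same' convolution, 2×2/2 max pooling,
  BN, dropout, dense); it is single-threaded numpy and not intended for
  full-benchmark (52-class, 27-subject) training times.
- The Sigimg all-pairs adjacency motivation is fully realized only for
  C ≤ 5 (see above); the geometry and column-multiplicity properties
  hold for all C.
- Quantile-edge ties make MTF sensitive to value perturbations at bin
  boundaries; with Q = 8 and 20-sample windows several bins can be empty,
  in which case their transition rows are the uniform convention.
- No latency/real-time accounting is modeled; wall-clock timings are
  informational only and never asserted.
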