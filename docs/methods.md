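# Methods

## Model

The package implements a late-interaction fusion head over two frozen
per-modality encoders. For a sample with visual feature `fv`, audio feature
`fa` (both length D) and per-modality logits `zv`, `za` (length C):

- calibrated distributions `pv = softmax(zv/Tv)`, `pa = softmax(za/Ta)`;
  confidences `cv = max(pv)`, `ca = max(pa)`;
- power-law weights `wv = cv^α / (cv^α + ca^α)`, `wa = 1 − wv` (exactly
  normalized by construction);
- layer-normalized features `fv,n`, `fa,n`; modulation signals
  `sv = tanh(MLP_a2v(fa,n))`, `sa = tanh(MLP_v2a(fv,n))` with
  `MLP = Linear(D,H) → SiLU → Linear(H,D)`;
- modulated features `fv,cm = fv,n + wv·sa`, `fa,cm = fa,n + wa·sv`
  (the published pairing — see "Modulation routing" below);
- fused vector `ϕ = LayerNorm(concat(fv,cm, fa,cm))` of length 2D, logits
  `z = Head(ϕ)`, prediction `argmax z` with lowest-index tie-break.

For video clips the visual pair `(fv, zv)` is produced by Top-K mean
pooling: 10 uniformly sampled frames (endpoint-inclusive rounding), frame
confidence = max softmax of the frame logits, the k = 5 most confident
frames (ties toward the earlier frame) averaged in feature space and in
logit space. Still images are 1-frame clips.

Because every signal entry is tanh-bounded and the scalar weight is ≤ 1,
the modulation perturbs each normalized feature by at most `w` in max-norm:
fusion can re-weight and nudge a modality but never erase it.

### Modulation routing

As printed, the signal derived from the visual feature (`sa`) is injected
back into the visual stream, and vice versa; the surrounding narrative
("the stronger modality corrects the weaker") suggests the crossed pairing
instead. The default is the as-printed behaviour; `variant="crossed"`
switches to `fv,cm = fv,n + wv·sv`, `fa,cm = fa,n + wa·sa`. Both variants
are implemented, tested and gradient-checked; neither is silently
substituted for the other.

## Training

Only the fusion parameters (two modulation MLPs, three LayerNorm affines,
linear head) and the three calibrator scalars learn; encoders are frozen.
Optimization is AdamW with decoupled weight decay 1e-4 applied to weight
matrices only (not biases, LayerNorm affines or calibrator scalars), two
learning-rate groups (fusion 3e-4, calibrator 1e-2), batch size 64,
label smoothing 0.02. Tv, Ta are clamped to [0.05, 20] and α to [0.1, 10]
after every step — projection keeps the published plain-scalar
parameterization while preventing sign flips and division blow-ups; the
bounds are an engineering choice, generous enough that the canonical runs
never touch them except transiently.

The modulation MLPs' output layers are zero-initialized by default
(`zero_init_last=True` in `TrainConfig`), so optimization starts at the
degenerate LayerNorm-concat point and the modulation path grows from zero.
This measurably stabilizes short (30-epoch) runs; the option can be turned
off, and the module-level constructor defaults to generic fan-in init so
the ops are tested away from the degenerate point.

The default run length is 30 epochs — the desk-scale canonical regression
setting; the published recipe's 100 epochs are supported via
`TrainConfig(epochs=100)`.

The entire head (forward and backward) is written in NumPy in float64.
Gradients — including `∂loss/∂Tv`, `∂Ta`, `∂α` through the max-softmax
confidence and the power-law weights — are derived analytically and
verified against central finite differences to ~1e-8 relative error in the
test suite. Determinism is exact: same config and seed give bit-identical
checkpoints and reports.

## Audio frontend

Decisions where the recipe under-specifies:

- FFT size = window length (1024), periodic Hann window, centered
  reflect-padded framing — the only convention under which a 10 s, 16 kHz
  clip yields exactly `floor(160000/320) + 1 = 501` frames;
- power (magnitude-squared) spectrum, HTK mel scale, unit-peak triangular
  filters, natural log clamped at `log_floor = 1e-10`;
- time-axis fitting keeps a centered window (excess column dropped from the
  trailing side when odd) or pads zeros symmetrically (extra zero trailing);
- normalization is per-sample standardization over all 64 × 501 cells
  (mean 0, std 1, epsilon-guarded for constant input) — it avoids any
  dataset-level statistics dependence;
- resampling uses polyphase filtering; the contract is behavioural (the
  dominant spectral peak survives), not kernel-exact.

All of this sits behind `FrontendParams` and the `frontend` config section,
so cached spectrograms are reproducible from their JSON sidecar.

## The synthetic benchmark

The generator emulates the statistical regime the fusion method assumes,
not bird media. Each class owns one prototype per modality, drawn as a
uniform random direction scaled to norm `prototype_scale` (equal-energy
prototypes, so distance-logit softmax carries no per-class norm bias). A
sample's embedding is `prototype + noise·multiplier` followed by per-sample
energy normalization back to the prototype norm — the embedding-level
analogue of the amplitude/energy normalization every real frontend applies.
This normalization is what makes confidence informative about quality: the
noisier a sample, the more the normalization dilutes its signal component,
and max-softmax confidence genuinely falls with the injected noise
multiplier (without it, distance logits become *more* extreme under noise
and confidence would rise with degradation — the opposite of real encoder
behaviour). A seeded `degrade_fraction` of samples has one modality's noise
multiplied by `degrade_factor`; the multipliers are recorded as per-sample
ground truth, which is what makes the reliability-recovery claim literally
testable: the learned audio weight must rank-anticorrelate with the
injected audio noise.

Canonical conditions (the defaults): 20 classes, D = 64, 100 train and 20
test samples per class, `prototype_scale = 3`, unit base noise in both
modalities, audio degraded ×4 on half the samples, seed 0.

Clips: `clip_frames = 10` frames per clip with within-clip jitter
`frame_jitter = 0.5` — frames of one clip share the capture conditions, so
their spread is set well below the cross-sample noise level.
`corrupt_frames` of them are pulled 80% of the way toward one wrong class's
prototype before jitter (confidently misleading frames), with the corrupted
indices recorded.

What passing tests on this generator do *not* show: anything about real
imagery or vocalization statistics, encoder quality, domain shift, or
asynchronous/missing modalities. The generator isolates the fusion math
from encoder quality by operating on embeddings; raw-media toy generators
(harmonic tone stacks) exist only to exercise the audio frontend end to
end.

### A structural limit of Top-K under distance logits

For quadratic distance logits, the mean of frame logits equals the logits
of the mean frame feature up to a class-independent constant. Hence when
only half of a clip's frames are corrupted toward a single wrong class,
full-mean pooling retains a 60/40 majority toward the true class and is
intrinsically robust — Top-K selection can only match it, not beat it.
Top-K decisively wins once corrupted frames are the majority (at 7 of 10
frames corrupted: 0.70 vs 0.035 visual-only accuracy), which is the regime
the robustness tests use. Real (non-quadratic) encoders do not satisfy the
mean-pooling identity, so this equivalence is a property of the toy
encoder, not of the method.

## Metrics and diagnostics

Accuracy and macro-averaged precision/recall/F1 are computed from the
confusion matrix; a class never predicted has precision 0, one absent from
the truth has recall 0 (cross-checked against scikit-learn to 1e-12 on
random confusions). Macro averaging is used because single reported values
per metric on fine-grained, potentially imbalanced classes conventionally
mean unweighted class means. Reliability diagnostics report per-sample
`(wv, wa, cv, ca, fused confidence)`, per-class mean weights, and
Pearson/Spearman correlations between fused confidence and the weights over
correctly predicted samples; correlations with degenerate variance return
0 with a flag rather than NaN.

## Numerical choices

- softmax always max-subtracted; log-softmax computed stably;
- LayerNorm epsilon 1e-5 everywhere; spectrogram standardization epsilon
  1e-8; argmax/Top-K ties broken toward the lowest index for bit-exact
  reproducibility;
- all randomness flows from explicit seeds through named substreams
  (prototypes / sample noise / degradation assignment / clips / parameter
  init / batch order), so each component is independently reproducible;
- checkpoints serialize every learned parameter plus config and metadata
  as JSON (text only).

## Known limitations

- Real pretrained backbones are out of scope; the encoder contract is the
  integration point and input-side conventions (image size, channel
  statistics) belong to the wrapped encoder.
- Modality reliability is proxied by calibrated confidence; under strong
  domain shift or systematic (non-random) noise the proxy can fail, and the
  synthetic generator does not model that failure mode.
- The score-fusion and shared-fusion baselines follow standard definitions
  (probability averaging; shared LayerNorm-concat trunk then head) since
  their internals are conventional rather than specified.
- On the synthetic benchmark the parameter-free logit/score averaging
  baselines are strong — the toy logits are themselves near-Bayes scores —
  so the comparison harness demonstrates the mechanism and the contracts,
  not a claim that trained fusion dominates every baseline in this regime.
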