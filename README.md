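# cabif

Confidence-calibrated, bidirectionally modulated audio-visual fusion for
fine-grained species classification — a desk-scale, fully tested
implementation of the fusion mechanism, with a synthetic multimodal
benchmark so every component can be exercised without trained backbones or
external datasets.

## The problem and the method

Field recordings of birds pair two modalities of very uneven quality: an
image or short video clip, and an audio recording that is often drowned in
environmental noise. Naive fusion (concatenating features, averaging
scores) lets a degraded modality contaminate a reliable one. This package
implements a fusion head that estimates *per-sample* modality reliability
from classifier confidence and uses it to gate a bounded cross-modal
interaction:

1. **Audio frontend.** The recording is resampled to 16 kHz mono and turned
   into a log-mel spectrogram (1024-sample Hann window, 320-sample hop,
   64 mel bands over 50–8000 Hz), center-cropped/zero-padded to 501 frames
   and standardized per sample: a normalized 64 × 501 matrix.
2. **Frozen encoders.** Each modality supplies a frozen `encode` (item →
   D-dim feature) and `classify` (feature → C-dim logits). Any pretrained
   backbone can be wrapped; the shipped toy encoder scores classes by
   negative half squared distance to fixed class prototypes.
3. **Top-K mean pooling.** For clips, 10 frames are sampled uniformly; each
   frame's confidence is the maximum softmax probability of its logits, and
   the k = 5 most confident frames are mean-pooled (features and logits)
   into the clip representation. Images are 1-frame clips.
4. **Confidence calibration.** Per modality, `p = softmax(z / T)` with a
   learnable temperature, confidence `c = max(p)`, and the visual weight

       wv = cv^α / (cv^α + ca^α),   wa = 1 − wv,

   with learnable α. T and α start at 1 and are learned end to end.
5. **Bidirectional inter-modulation fusion (BIF).** Both features are
   layer-normalized; two lightweight MLPs (`Linear(D,H) → SiLU →
   Linear(H,D)`, tanh-squashed) generate modulation signals that are
   injected as weight-scaled residuals (`f_v,cm = f_v,n + wv·s_a`, …); the
   modulated pair is concatenated (2D = 1024 for D = 512), layer-normalized
   and classified by a linear head, trained with label-smoothed (0.02)
   cross-entropy under AdamW (fusion lr 3e-4, calibrator lr 1e-2).

The whole trainable head is implemented in NumPy with hand-derived,
finite-difference-verified backpropagation.

## Worked example

`python examples/04_train_and_evaluate.py` trains the fusion head on the
canonical synthetic benchmark — 20 classes, 64-dim embeddings per modality,
2,000 train / 400 test samples, audio noise inflated ×4 on half the
samples — and prints:

```
epoch-mean loss: 3.085 -> 0.615
learned calibrator: Tv=0.598 Ta=2.782 alpha=4.792
unimodal accuracy: visual 0.843, audio 0.557 (audio degraded on half the samples)
fused accuracy 0.835, macro-F1 0.834
Spearman rho(injected audio noise, learned audio weight) = -0.390
```

Read: the degraded audio branch alone reaches 55.7%; the fused model
reaches 83.5%, the level of the clean visual branch, because the learned
calibrator flattens audio confidence (Ta ≈ 2.8), sharpens visual
(Tv ≈ 0.6), and the negative rank correlation shows the per-sample audio
weight drops exactly on the samples whose audio was genuinely degraded —
reliability estimated from confidence, recovered without ever seeing the
noise labels.

The other examples walk the frontend (`01`), Top-K pooling on corrupted
clips (`02`), the calibration algebra (`03`) and the baseline comparison
harness (`05`). A thin CLI mirrors the pipeline:
`cabif simulate|train|evaluate|compare|sweep-k|diagnose`.

## Layout

- `src/cabif/audio_frontend.py` — waveform → normalized log-mel spectrogram
- `src/cabif/encoders.py` — frozen encoder contract + toy prototype encoder
- `src/cabif/topk_pooling.py` — confidence-ranked Top-K mean pooling
- `src/cabif/calibration.py` — temperature scaling, power-law weights
- `src/cabif/bif_fusion.py` — BIF module and the full trainable head
- `src/cabif/baselines.py` — concat / logit-avg / score-fusion / shared-fusion
- `src/cabif/synthetic_data.py` — seeded multimodal benchmark generator
- `src/cabif/pipeline.py` — training, metrics, reliability diagnostics, sweeps
- `docs/methods.md` — model assumptions, parameter choices, limitations
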