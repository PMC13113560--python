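"""Compare the fusion head against the simple fusion baselines.

Trains/evaluates Concat, logit averaging, score (probability) averaging,
shared-trunk fusion and the full calibrated bidirectional fusion on the
same synthetic benchmark and prints one metrics row per method.
"""

from cabif import SyntheticSpec, TrainConfig, compare_methods, generate_multimodal_dataset

spec = SyntheticSpec(seed=0)
train = generate_multimodal_dataset(spec, stream=0)
test = generate_multimodal_dataset(spec, samples_per_class=20, stream=1)

table = compare_methods(train, test, TrainConfig(epochs=30, seed=0), seeds=(0,))
print(table.round(4).to_string())
print("\nlogit/score averaging are parameter-free; concat, shared_fusion and "
      "cabif train a head for 30 epochs. cabif additionally learns the "
      "calibrated per-sample modality weights.")
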