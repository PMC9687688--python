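"""Inspect the modified SqueezeNet and the reference baseline.

Prints the layer-by-layer summary of the 7-fire classifier (batchnorm
input, fire modules interleaved with 2x2 pools, global pooling, 2-way
head) and compares parameter counts with canonical SqueezeNet v1.0.
"""

from wavetap import ModelConfig, build_baseline_squeezenet, build_model

model = build_model(ModelConfig())
print(f"{model.name}: input 240x240x3")
print(f"{'layer':18s} {'output shape':16s} {'params':>8s}")
for row in model.summary((240, 240, 3)):
    print(f"{row['layer']:18s} {str(row['output_shape']):16s} {row['params']:>8d}")
print(f"{'total':35s} {model.param_count():>8d}")

baseline = build_baseline_squeezenet((240, 240, 3))
print(f"\nbaseline {baseline.name}: {baseline.param_count()} parameters")
print(
    f"the modified network is {baseline.param_count() / model.param_count():.1f}x smaller; "
    "its palindromic fire sizes expand to 256 channels mid-network then contract"
)
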