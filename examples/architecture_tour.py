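"""Walk the model structure: feature ladder, block counts, ablation variants.

Instantiates the tiny configuration (embed dim 8 — same wiring as the
default 48, just narrower), runs one volume through the encoder, and prints
the six-level feature ladder plus the parameter arithmetic of the four
ablation variants (full / no attention / no shuffle / neither).
"""

import numpy as np

from ecatbrats import ECATBraTS, ModelConfig
from ecatbrats.blocks import AttentionConfig, ShuffleConfig
from ecatbrats.encoder import EncoderConfig
from ecatbrats.model import attention_parameter_count, tiny_model_config
from ecatbrats.nn import Tensor, no_grad

model = ECATBraTS(tiny_model_config(seed=0))
model.eval()
x = Tensor(np.random.default_rng(0).normal(size=(1, 4, 32, 32, 32))
           .astype(np.float32))
with no_grad():
    feats = model.encoder(x)

print("encoder feature ladder for a (4, 32, 32, 32) input:")
for level, f in enumerate(feats):
    c, d, h, w = f.shape[1:]
    print(f"  level {level}: {c:>4} channels at {d}x{h}x{w} (1/{2 ** level})")

print(f"\nCAT blocks: {model.num_cat_blocks}, shuffle blocks: "
      f"{model.num_shuffle_blocks}, decoder blocks: {model.num_decoder_blocks}")
print("default config ladder:", ModelConfig().ladder())


def build(shuffle, attention):
    return ECATBraTS(ModelConfig(
        encoder=EncoderConfig(embed_dim=8, num_heads=(2, 2, 2, 2),
                              window_size=(4, 4, 4)),
        shuffle=ShuffleConfig(enabled=shuffle),
        attention=AttentionConfig(enabled=attention)))


print("\nablation variants (parameter counts):")
for name, sh, at in (("full model", True, True), ("no attention", True, False),
                     ("no shuffle", False, True), ("neither", False, False)):
    print(f"  {name:<14}{build(sh, at).parameter_count():>9}")
print("attention FC parameters (closed form):",
      attention_parameter_count(build(True, True).cfg))
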