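"""Count trainable parameters of transformer classifiers analytically.

No weights are instantiated: each architecture's tensor shapes are summed
from its hyperparameters, reproducing the sizes of the standard base
checkpoints with a 2-class head.
"""

from rankfuse import ArchSpec, count_transformer_params

for name, spec in [
    ("bert-like   (vocab 30522, abs. positions, pooler head)", ArchSpec.bert_base()),
    ("roberta-like (vocab 50265, dense+projection head)", ArchSpec.roberta_base()),
    ("xlnet-like  (vocab 32000, relative attention, summary head)", ArchSpec.xlnet_base()),
]:
    print(f"{name}: {count_transformer_params(spec):,} parameters")
print(
    "\nEach count sums embeddings, 12 encoder layers (attention + feed-forward"
    "\n+ layer norms) and the family-specific classification head."
)
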