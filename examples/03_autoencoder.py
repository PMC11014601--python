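"""Compress both feature blocks to one tenth of their width.

The auto-encoder trains on the metabolite block stacked with the pre-dedup
pathway block (they share one atom-color vocabulary, hence one width), then
each block is encoded separately and min-max rescaled into [0, 1].
"""

from pathpairs import (
    EncoderTrainConfig,
    SynthConfig,
    build_encoded_sets,
    build_feature_sets,
    cross_join,
    generate,
)

matrix, catalog = generate(SynthConfig(n_metabolites=150, n_pathways=4,
                                       n_features=60, seed=0))
sets = build_feature_sets(matrix, catalog)
enc = build_encoded_sets(sets, ratio=0.1,
                         train_cfg=EncoderTrainConfig(max_epochs=200, seed=0))

print(f"input width {enc.model.input_width} -> latent width "
      f"{enc.model.latent_width} (floor of one tenth)")
print(f"encoded metabolite block: {enc.metabolite.values.shape}, "
      f"values in [{enc.metabolite.values.min():.3f}, "
      f"{enc.metabolite.values.max():.3f}]")
ds = cross_join(enc.metabolite, enc.pathway, catalog)
print(f"encoded pair width: {ds.n_features} "
      f"(= {enc.model.latent_width} metabolite + "
      f"{enc.model.latent_width} pathway latents)")
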