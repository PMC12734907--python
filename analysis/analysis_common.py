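"""Shared constants for the numbered analysis drivers."""

from pascdx.synth import SynthConfig

SEED = 1

# Study conditions shared by every driver: the generator's default
# signal structure at a mid-sized scale.
STUDY = SynthConfig(
    n_case=50, n_control=50, n_metabolites=300, n_dysregulated=100, effect_size=1.5,
    n_descriptors=60, n_informative=20, descriptor_shift=0.8, overlap=0.0,
)

MLP_GRID = {"clf__hidden_layer_sizes": [(32,)], "clf__alpha": [1e-2]}
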