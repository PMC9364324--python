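"""Predict adsorption affinities with the BSAI linear free-energy model.

Builds a small synthetic compound set with Abraham solute descriptors
[E, S, A, B, V], pairs it with synthetic nanodescriptor sets [c, r_e, p_s,
a, b, v] (the real per-nanomaterial values are experimental data the user
supplies as a YAML/JSON registry), and prints the resulting log k matrix.
Each cell is the base-10 log of the predicted adsorption affinity of one
compound for one nanomaterial surface.
"""

import numpy as np

from nanosorb import (
    GeneratorConfig,
    NanoDescriptorSet,
    batch_predict,
    gen_abraham_compounds,
)

compounds = gen_abraham_compounds(GeneratorConfig(n=6, seed=42))
print("Abraham descriptors of six synthetic compounds:")
print(compounds.round(2), "\n")

rng = np.random.default_rng(0)
registry = [
    NanoDescriptorSet("metal_oxide_A", *(float(x) for x in rng.uniform(-1, 3, 6))),
    NanoDescriptorSet("carbon_tube_B", *(float(x) for x in rng.uniform(-1, 3, 6))),
]

logk = batch_predict(compounds, registry)
print("predicted log k (rows: compounds, columns: nanomaterials):")
print(logk.round(2))
print(
    "\nHigher log k means stronger predicted adsorption; differences down a"
    "\ncolumn rank compounds by affinity for that surface."
)
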