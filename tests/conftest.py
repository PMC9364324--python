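import numpy as np
import pandas as pd
import pytest

from nanosorb import GeneratorConfig, NanoDescriptorSet, load_frozen_models


@pytest.fixture(scope="session")
def frozen_models():
    return load_frozen_models()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def nano_registry():
    """Synthetic nanodescriptor sets (the real values are user-supplied
    config, not packaged data)."""
    rng = np.random.default_rng(7)
    out = []
    for i in range(3):
        c, r_e, p_s, a, b, v = (float(x) for x in rng.uniform(-2, 4, size=6))
        out.append(NanoDescriptorSet(f"enm_{i}", c, r_e, p_s, a, b, v))
    return out


@pytest.fixture()
def compound_table(rng):
    from nanosorb import gen_abraham_compounds

    return gen_abraham_compounds(GeneratorConfig(n=25, seed=11))
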