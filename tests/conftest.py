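import pytest

import atomatlas as aa


@pytest.fixture(scope="session")
def registry():
    return aa.load_registry()


@pytest.fixture(scope="session")
def label_atlas():
    """Small deterministic synthetic atlas with a label-volume annotation."""
    spec = aa.SynthSpec(seed=7, n_regions=6, shape=(10, 10, 10),
                        hierarchy_depth=3)
    return aa.generate_with_truth(spec)


@pytest.fixture(scope="session")
def prob_atlas():
    """Small deterministic synthetic atlas with probabilistic maps."""
    spec = aa.SynthSpec(seed=11, n_regions=4, shape=(8, 8, 8),
                        annotation_kind="probabilistic_maps")
    return aa.generate_with_truth(spec)
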