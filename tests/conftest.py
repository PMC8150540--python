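import pytest

import mwablate as m


@pytest.fixture(scope="session")
def materials():
    return m.default_materials()


@pytest.fixture(scope="session")
def coupling_medium(materials):
    return materials["coupling_medium"]


@pytest.fixture(scope="session")
def tiny():
    """Fully assembled tiny experiment: grid, array, kernel and SVD.

    Built once per session; everything downstream treats it as read-only.
    """
    bundle = m.make_fixture("tiny")
    ctx = bundle.build()
    return ctx


@pytest.fixture(scope="session")
def tiny_contrast(tiny):
    """Ground-truth contrast of the ongoing-ablation stage on the tiny grid."""
    return m.ground_truth_contrast(
        ("s0", "b1"),
        tiny.grid,
        tiny.config.reference_frequency,
        tiny.materials,
        tiny.phantom,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny, tiny_contrast):
    """Noiseless Born-consistent data for the tiny contrast."""
    return m.born_forward(tiny.kernel, tiny_contrast)
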