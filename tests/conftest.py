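import dataclasses

import pytest

from drgvol import datasets
from drgvol.phantom import PhantomSpec


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    return PhantomSpec(noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def cord_only_spec(noiseless_spec) -> PhantomSpec:
    return dataclasses.replace(
        noiseless_spec,
        drg_left=dataclasses.replace(noiseless_spec.drg_left, present=False),
        drg_right=dataclasses.replace(noiseless_spec.drg_right, present=False),
    )


@pytest.fixture(scope="session")
def reference_pairs():
    """The published ten test-retest CSA pairs."""
    return datasets.testretest_pairs()
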