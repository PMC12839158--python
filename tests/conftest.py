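import numpy as np
import pytest

from faindex.core import MolarProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def control_pseudo_profile():
    """One pseudo-sample at the Control group's published mean composition."""
    return MolarProfile(
        "control-mean",
        "Control",
        {
            "C18:0": 9.27,
            "C18:1n-9": 23.13,
            "C20:3n-6": 1.31,
            "C20:4n-6": 7.53,
            "C22:4n-6": 0.17,
            "C22:5n-3": 0.38,
            "C20:5n-3": 0.59,
            "C22:6n-3": 1.97,
            "C18:2n-6": 24.58,
            "C18:3n-6": 0.35,
            "C20:2n-6": 0.25,
        },
    )


def make_profile(mol_percent, sample_id="s", group="g"):
    return MolarProfile(sample_id, group, dict(mol_percent))
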