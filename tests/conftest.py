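import numpy as np
import pytest
from hypothesis import settings

from islandlineages import SimConfig, StrProfile, simulate
from islandlineages.core_io import YFILER_SINGLE_COPY_LOCI, load_reference
from islandlineages.haplogroups import load_packaged_tree

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference() -> str:
    return load_reference()


@pytest.fixture(scope="session")
def packaged_tree():
    return load_packaged_tree()


@pytest.fixture(scope="session")
def yami_sim():
    """One patrilocal island simulation at the survey-shaped defaults."""
    return simulate(SimConfig(seed=11))


@pytest.fixture()
def make_profile():
    """Factory for Y-STR profiles: base repeat 14 everywhere with per-locus
    overrides given as {locus index or name: repeat}."""

    def factory(sample_id, overrides=None, haplogroup="O1a*-M119",
                dys385=(11, 14), population=""):
        repeats = {locus: 14 for locus in YFILER_SINGLE_COPY_LOCI}
        for key, value in (overrides or {}).items():
            locus = YFILER_SINGLE_COPY_LOCI[key] if isinstance(key, int) else key
            repeats[locus] = value
        return StrProfile(sample_id, haplogroup, repeats, dys385, population)

    return factory


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
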