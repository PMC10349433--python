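import numpy as np
import pytest

from mpseg import synthetic
from mpseg.slide_io import MP


@pytest.fixture(scope="session")
def unit_cohort(tmp_path_factory):
    """A small synthetic RC+TUR cohort on disk; shared across the session."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = synthetic.generate_cohort(n_rc=4, n_tur=9, out_dir=out, seed=1, preset="unit")
    return manifest


@pytest.fixture(scope="session")
def unit_pair():
    """One deterministic synthetic slide pair at the unit canvas size."""
    spec = synthetic.SyntheticSlideSpec(seed=11, mp_fraction=0.45)
    return synthetic.generate_pair(spec, "unit_pair", "RC")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, p=0.5):
    return np.where(rng.random(shape) < p, MP, 0).astype(np.uint8)
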