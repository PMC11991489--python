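import numpy as np
import pytest

from myocortex import RunConfig, gen_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_study():
    """Smallest usable mock study: 3 subjects, 12 s recordings."""
    return gen_study(n_subjects=3, duration_s=12.0, seed=7)


@pytest.fixture
def fast_config(tmp_path):
    """Run configuration scaled for unit tests (few permutations/nulls)."""
    return RunConfig(
        seed=7, out_dir=str(tmp_path / "out"), n_perm=200, n_random=10,
        pdc_segment_s=12.0, pdc_max_order=12,
    )
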