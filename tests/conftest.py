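import numpy as np
import pytest

from mrmediate.instruments import HarmonizedSet
from mrmediate.synthetic_data import make_fixtures


def hset_from(beta_x, beta_y, se_y, se_x=None, **kwargs) -> HarmonizedSet:
    beta_x = np.asarray(beta_x, dtype=float)
    if se_x is None:
        se_x = np.full_like(beta_x, 0.01)
    return HarmonizedSet(
        beta_x=beta_x,
        se_x=np.asarray(se_x, dtype=float),
        beta_y=np.asarray(beta_y, dtype=float),
        se_y=np.asarray(se_y, dtype=float),
        **kwargs,
    )


@pytest.fixture
def hs3():
    """Three SNPs whose per-SNP ratios all equal 0.2 exactly."""
    return hset_from([0.3, 0.4, 0.5], [0.06, 0.08, 0.10], [0.01] * 3)


@pytest.fixture(scope="session")
def fixtures_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    make_fixtures(out)
    return out
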