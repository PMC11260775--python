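import numpy as np
import pandas as pd
import pytest

from ivmr.harmonize import PAIR_COLUMNS, HarmonizedSet
from ivmr.simulate import make_reference_study


def hset_from_arrays(gamma, se_x, Gamma, se_y, rsids=None) -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays (bypassing allele
    bookkeeping) for estimator-level tests."""
    gamma = np.asarray(gamma, float)
    n = len(gamma)
    if rsids is None:
        rsids = [f"rs{i + 1}" for i in range(n)]
    pairs = pd.DataFrame({
        "rsid": rsids,
        "chrom": "1",
        "pos": np.arange(n) * 1_000_000 + 1,
        "effect_allele": "A",
        "other_allele": "G",
        "gamma": gamma,
        "se_x": np.broadcast_to(np.asarray(se_x, float), (n,)).copy(),
        "Gamma": np.asarray(Gamma, float),
        "se_y": np.broadcast_to(np.asarray(se_y, float), (n,)).copy(),
        "eaf_x": 0.3,
        "eaf_y": 0.3,
        "is_proxy": False,
        "provenance": "kept",
    }, columns=PAIR_COLUMNS)
    audit = pd.DataFrame({"rsid": rsids, "action": "kept", "reason": "kept"})
    return HarmonizedSet(pairs, audit)


@pytest.fixture(scope="session")
def reference_study():
    return make_reference_study()


@pytest.fixture
def two_snp_hset():
    """The closed-form IVW example: (gamma, Gamma, se_y) = (0.1, 0.2, 0.1)
    and (0.2, 0.2, 0.1)."""
    return hset_from_arrays([0.1, 0.2], 0.01, [0.2, 0.2], 0.1)
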