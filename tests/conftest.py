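import numpy as np
import pandas as pd
import pytest

from aisle.synth import PlantedAI, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_cfg():
    return SimConfig(seed=11, n_snps=20, n_case=10, n_control=10, rho=0.0)


@pytest.fixture
def planted_cfg():
    return SimConfig(
        seed=23,
        n_snps=10,
        n_case=10,
        n_control=10,
        rho=0.0,
        planted_ai=(PlantedAI(0, 0.65, 0.50),),
    )


def make_sites(rows):
    """Helper: site table from (chrom, pos, mq, qd, fs) tuples."""
    return pd.DataFrame(
        [
            {
                "snp_id": f"s{i}",
                "chrom": chrom,
                "pos": pos,
                "ref": "A",
                "alt": "G",
                "rsid": f"rs{i}",
                "mq": mq,
                "qd": qd,
                "fs": fs,
            }
            for i, (chrom, pos, mq, qd, fs) in enumerate(rows)
        ]
    )
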