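import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from adnakit.io import GenotypeMatrix
from adnakit.simulate import chultun_like_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def tiny_matrix(calls, chroms=None, labels=None, group="G"):
    """Build a small GenotypeMatrix from a call array for hand examples."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if labels is None:
        labels = [f"S{i}" for i in range(n)]
    if chroms is None:
        chroms = ["1"] * m
    snps = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(m)],
            "chrom": [str(c) for c in chroms],
            "pos": np.arange(1, m + 1) * 10,
            "ref": "A",
            "alt": "G",
        }
    )
    ind = pd.DataFrame({"label": labels, "sex": "unknown", "group": group})
    return GenotypeMatrix(calls, ind, snps)


@pytest.fixture(scope="session")
def chultun_cohort():
    """The packaged 64-individual fixture at full size (100k SNPs, 10%
    missingness, seed 1), shared across tests."""
    return chultun_like_cohort(n_snps=100_000, missing_rate=0.10, seed=1)
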