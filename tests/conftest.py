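import numpy as np
import pandas as pd
import pytest

from polyfrs.panel import GenotypePanel


def make_panel(dosages, sample_ids=None, snp_ids=None, batch=None, sex=None):
    """Assemble a GenotypePanel from a raw dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    sample_ids = sample_ids or [f"S{i:03d}" for i in range(n)]
    snp_ids = snp_ids or [f"rs{j:04d}" for j in range(m)]
    samples = pd.DataFrame(
        {
            "family_id": sample_ids,
            "sample_id": sample_ids,
            "sex": sex if sex is not None else ["unknown"] * n,
            "batch": batch if batch is not None else ["A"] * n,
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": 1,
            "position": np.arange(1, m + 1),
            "allele_a1": "A",
            "allele_a2": "C",
        }
    )
    return GenotypePanel(samples=samples, snps=snps, dosages=dosages)


def random_panel(rng, n, m, maf_range=(0.1, 0.5), missing_rate=0.0):
    """HWE panel with uniform allele frequencies, optional missingness."""
    p = rng.uniform(*maf_range, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    if missing_rate > 0:
        dos[rng.random((n, m)) < missing_rate] = np.nan
    return make_panel(dos)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
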