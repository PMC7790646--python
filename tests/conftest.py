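import numpy as np
import pandas as pd
import pytest

from cohortnb.types import GenotypeMatrix


def matrix_from_dosage(dos, sample_ids=None, locus_ids=None, locus_meta=None):
    """Build a diallelic GenotypeMatrix from a dosage array (NaN = missing)."""
    dos = np.asarray(dos, dtype=float)
    n, L = dos.shape
    calls = np.empty((n, L, 2), dtype=np.int16)
    calls[:, :, 0] = np.nan_to_num(dos == 2).astype(np.int16)
    calls[:, :, 1] = np.nan_to_num(dos >= 1).astype(np.int16)
    miss = np.isnan(dos)
    calls[miss] = -1
    if locus_meta is None:
        locus_meta = pd.DataFrame({"alleles": [(0, 1)] * L})
    return GenotypeMatrix(
        sample_ids or [f"s{i}" for i in range(n)],
        locus_ids or [f"l{j}" for j in range(L)],
        calls,
        locus_meta,
    )


@pytest.fixture
def hwe_cohort():
    """60 individuals x 400 loci drawn at exact HW proportions (one deme)."""
    rng = np.random.default_rng(20260101)
    p = rng.uniform(0.1, 0.9, 400)
    dos = rng.binomial(2, p[None, :], size=(60, 400))
    return matrix_from_dosage(dos)
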