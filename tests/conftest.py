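import numpy as np
import pandas as pd
import pytest

from hybridabc.genotypes import MISSING, SnpDataset


def make_dataset(dosages, *, groups=None, reproducibility=None, clones=None):
    """Build a small SnpDataset from a (individuals x loci) array of ints.

    ``None`` entries in ``dosages`` become the missing sentinel.
    """
    arr = np.array(
        [[MISSING if v is None else v for v in row] for row in dosages], dtype=np.int8
    )
    n_ind, n_loci = arr.shape
    groups = groups or ["G"] * n_ind
    individuals = pd.DataFrame(
        {"individual_id": [f"ind{i:02d}" for i in range(n_ind)], "group_label": groups}
    )
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{j:02d}" for j in range(n_loci)],
            "clone_id": clones or [f"C{j:02d}" for j in range(n_loci)],
            "reproducibility": reproducibility if reproducibility is not None else 1.0,
            "allele_ref": "A",
            "allele_alt": "G",
        }
    )
    return SnpDataset(individuals, loci, arr)


@pytest.fixture
def rng():
    return np.random.default_rng(20240417)
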