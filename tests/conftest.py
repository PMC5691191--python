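import numpy as np
import pandas as pd
import pytest

from assortcheck.genio import GenotypeMatrix, PhenotypeTable


def make_geno(dosages, chromosomes=None, sample_ids=None, variant_ids=None):
    """Small GenotypeMatrix from a literal dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    if chromosomes is None:
        chromosomes = ["1"] * m
    variants = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chromosome": [str(c) for c in chromosomes],
            "position": np.arange(1, m + 1),
            "allele1": "A",
            "allele2": "B",
        }
    )
    return GenotypeMatrix(np.array(sample_ids, dtype=object), variants, dosages)


@pytest.fixture
def tiny_geno():
    """3 samples x 4 variants with one missing call."""
    return make_geno([[0, 1, 2, -1], [1, 1, 0, 2], [2, 0, 1, 1]])


@pytest.fixture
def spouse_table():
    pairs = [(160.0, 170.0), (165.0, 172.0), (158.0, 169.0), (175.0, 180.0), (170.0, 178.0)]
    rows = []
    for k, (a, b) in enumerate(pairs):
        rows.append({"sample_id": f"A{k}", "height": a, "age": 30.0 + k, "spouse_id": f"B{k}"})
        rows.append({"sample_id": f"B{k}", "height": b, "age": 32.0 + k, "spouse_id": f"A{k}"})
    return PhenotypeTable(pd.DataFrame(rows))
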