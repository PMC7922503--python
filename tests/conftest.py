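import numpy as np
import pandas as pd
import pytest

from ghfcooc.ghf_io import CountMatrix, GenomeRecord


def make_record(
    strain,
    species="Examplea typica",
    genus="Examplea",
    domain="bacteria",
    phylum="Proteobacteria",
    counts=None,
):
    return GenomeRecord(
        strain_name=strain,
        species=species,
        genus=genus,
        domain=domain,
        phylum=phylum,
        counts=dict(counts or {}),
    )


def make_matrix(values, variant="aveF", domains=None, phyla=None):
    """CountMatrix from a dict-of-columns or DataFrame of integer counts."""
    df = pd.DataFrame(values).astype("int64")
    if df.index.dtype.kind in "iu":
        df.index = [f"Sp{i:03d}" for i in range(len(df))]
    n = len(df)
    tax = pd.DataFrame(
        {
            "domain": domains if domains is not None else ["bacteria"] * n,
            "phylum": phyla if phyla is not None else ["Proteobacteria"] * n,
        },
        index=df.index,
    )
    return CountMatrix(variant=variant, values=df, taxonomy=tax)


def random_records(rng, n_species=6, max_strains=4, ghfs=("GH1", "GH5", "GH13")):
    records = []
    for i in range(n_species):
        for k in range(rng.integers(1, max_strains + 1)):
            records.append(
                make_record(
                    f"Sp{i:02d} str{k}",
                    species=f"Species {i:02d}",
                    genus=f"Genus{i % 3}",
                    counts={g: int(rng.integers(0, 5)) for g in ghfs},
                )
            )
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
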