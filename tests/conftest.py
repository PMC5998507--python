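import numpy as np
import pandas as pd
import pytest

from teboot.models import ExpressionTable, GeneModel, TEInsertion
from teboot.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small single-species dataset shared by read-only tests."""
    cfg = SimulationConfig(
        n_genes=400,
        n_chromosomes=2,
        species=("testsp",),
        tissues=("brain", "liver"),
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def toy_genes():
    return [
        GeneModel("g1", "sp", "chr1", 5000, 6000, "+"),
        GeneModel("g2", "sp", "chr1", 20000, 24000, "-"),
        GeneModel("g3", "sp", "chr2", 500, 800, "+"),
    ]


@pytest.fixture()
def toy_expression():
    values = pd.DataFrame(
        {
            "s1": [2.0, 4.0, 0.0],
            "s2": [1.0, 0.0, 8.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {"species": ["sp", "sp"], "tissue": ["brain", "liver"]},
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    return ExpressionTable(values=values, sample_meta=meta)


def make_te(chrom="chr1", start=100, end=400, te_class="SINE",
            identity=96.0, species="sp"):
    return TEInsertion(chrom=chrom, start=start, end=end, te_class=te_class,
                       percent_identity=identity, species=species)
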