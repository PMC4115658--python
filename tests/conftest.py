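import numpy as np
import pandas as pd
import pytest

from imprintomics.synthetic import (
    AS_PEG,
    TruthConfig,
    default_crosses,
    make_expression_table,
    make_gene_classes,
    simulate_allele_counts,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def recovery_scenario():
    """2000 genes (100 MEGs at 0.95, 50 PEGs at 0.60 paternal, one
    allele-specific PEG) x 3 cross pairs x 3 replicates at depth 300."""
    classes = make_gene_classes(
        n_biallelic=1844,
        n_meg=100,
        n_peg=50,
        allele_specific=[(AS_PEG, "colC", "father")],
        n_seedcoat=5,
    )
    config = TruthConfig(
        seed=2024,
        gene_classes=classes,
        crosses=default_crosses(n_replicates=3),
    )
    counts, truth = simulate_allele_counts(config)
    return config, counts, truth, make_expression_table(config)


def make_cytosines(rows):
    """rows: (chrom, pos, strand, meth, unmeth, context)."""
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "count_methylated", "count_unmethylated", "context"],
    )


@pytest.fixture
def cytosines_factory():
    return make_cytosines
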