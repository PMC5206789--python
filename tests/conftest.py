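import numpy as np
import pandas as pd
import pytest

from surfscore.io import Omics


def make_omics(
    genes,
    samples,
    cna=None,
    expr=None,
    mutation_rows=None,
):
    """Build an Omics bundle from plain nested lists / row tuples."""
    cna_df = (
        pd.DataFrame(np.asarray(cna, dtype=int), index=genes, columns=samples)
        if cna is not None
        else None
    )
    expr_df = (
        pd.DataFrame(np.asarray(expr, dtype=float), index=genes, columns=samples)
        if expr is not None
        else None
    )
    mut_df = pd.DataFrame(
        mutation_rows or [], columns=["sample_id", "gene_id", "variant_class"]
    )
    return Omics(mutations=mut_df, cna=cna_df, expr=expr_df, samples=list(samples))


@pytest.fixture
def omics_factory():
    return make_omics
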