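import numpy as np
import pandas as pd
import pytest

from panelscan.panel import GenePanel


@pytest.fixture
def one_gene_panel():
    """A 100-residue protein with one 20-residue TM interval (p_ri = 0.2)."""
    genes = pd.DataFrame({"symbol": ["GX"], "family": ["F1"], "length": [100]}).set_index("symbol")
    return GenePanel(genes=genes, tm_intervals={"GX": ((1, 20),)})


def make_mutations(positions, gene="GX", sample=None, variant_class="nonsynonymous",
                   sift=None, polyphen=None, cadd=None, cancer_type="C1"):
    """MAF-like record builder for hand-constructed instances."""
    n = len(positions)
    return pd.DataFrame(
        {
            "sample": sample if sample is not None else [f"s{i}" for i in range(n)],
            "cancer_type": cancer_type,
            "gene": gene,
            "protein_pos": positions,
            "variant_class": variant_class,
            "sift": sift if sift is not None else ["NA"] * n,
            "polyphen": polyphen if polyphen is not None else ["NA"] * n,
            "cadd": cadd if cadd is not None else np.ones(n),
        }
    )


@pytest.fixture
def mut_builder():
    return make_mutations
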