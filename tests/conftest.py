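import numpy as np
import pandas as pd
import pytest

from cadep.network_paths import (
    BINDING,
    PTM,
    TF_REGULATION,
    EdgeRecord,
    KnowledgeNetwork,
)


@pytest.fixture
def tiny_de_table(tmp_path):
    path = tmp_path / "de.tsv"
    path.write_text(
        "gene_id\tlog2fc\tpvalue\tfdr\n"
        "geneA\t1.2\t0.0001\t0.0005\n"
        "geneB\t-0.7\t0.004\t0.009\n"
        "geneC\t0.1\t0.6\t0.8\n"
    )
    return path


@pytest.fixture
def chain_network():
    """S -BINDING- X -TF-> T with a decoy two-TF route S -TF-> Y -TF-> T."""
    edges = [
        EdgeRecord("S", "X", BINDING, 0, False),
        EdgeRecord("X", "T", TF_REGULATION, 1, True),
        EdgeRecord("S", "Y", TF_REGULATION, 0, True),
        EdgeRecord("Y", "T", TF_REGULATION, 0, True),
    ]
    return KnowledgeNetwork(edges)


@pytest.fixture
def ct_table_noiseless():
    """Hand-built Ct table: target shifts -2 cycles under treatment
    (fourfold induction); references invariant."""
    rows = []
    for cond, tgt_ct in (("ctrl", 22.0), ("h2o2", 20.0)):
        for rep in (1, 2, 3):
            sample = f"{cond}_{rep}"
            rows.append(dict(gene_id="tgt", sample_id=sample, condition=cond,
                             replicate=rep, ct=tgt_ct))
            rows.append(dict(gene_id="REF_ACTIN", sample_id=sample,
                             condition=cond, replicate=rep, ct=17.0))
            rows.append(dict(gene_id="REF_GAPDH", sample_id=sample,
                             condition=cond, replicate=rep, ct=19.0))
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
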