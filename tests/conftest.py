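import numpy as np
import pytest

from tbkg.corpus import AbstractRecord, build_lexicon, matrix_from_dense


@pytest.fixture
def mini_lexicon():
    """A small hand-written lexicon spanning all four node types."""
    return build_lexicon(
        [
            ("non-small cell lung carcinoma", "C0007131", "T191"),
            ("epidermal growth factor receptor", "C0034802", "T192"),
            ("growth factor", "C0018284", "T116"),
            ("osimertinib", "C3852126", "T121"),
            ("gefitinib tablet", "C1176003", "T200"),
            ("interstitial lung disease", "C0206062", "WHO"),
            ("nephrosclerosis", "C0027716", "WHO"),
            ("dry skin", "C0151908", "WHO"),
        ]
    )


@pytest.fixture
def record_factory():
    def make(doc_id, body, title="a title"):
        return AbstractRecord(doc_id=doc_id, title=title, body=body)

    return make


def dense_matrix(dense, types, doc_prefix="D"):
    """Build a DocEntityMatrix from a dense 0/1 array and a list of
    (concept_id, node_type) column labels."""
    dense = np.asarray(dense)
    doc_ids = [f"{doc_prefix}{i:04d}" for i in range(dense.shape[0])]
    cids = [t[0] for t in types]
    ntypes = [t[1] for t in types]
    return matrix_from_dense(doc_ids, cids, ntypes, dense)
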