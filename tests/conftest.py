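import numpy as np
import pandas as pd
import pytest

from seizurescope import (
    ReportTable,
    build_custom_matrix,
    load_bundled_blosum90,
)
from seizurescope.alignments import AlignmentRow, SegmentAnnotation, SubunitAlignment


@pytest.fixture(scope="session")
def blosum90():
    return load_bundled_blosum90()


@pytest.fixture(scope="session")
def custom_matrix(blosum90):
    return build_custom_matrix(blosum90)


def make_alignment(human_seq, others, subunit_id="SUB1"):
    """Build a SubunitAlignment from a human row and {species: seq} dict."""
    rows = [AlignmentRow(f"{subunit_id}|human|ref", "human", human_seq)]
    rows += [
        AlignmentRow(f"{subunit_id}|{sp}|x", sp, seq) for sp, seq in others.items()
    ]
    return SubunitAlignment(
        subunit_id=subunit_id,
        rows=tuple(rows),
        human_reference_id=f"{subunit_id}|human|ref",
    )


@pytest.fixture()
def alignment_factory():
    return make_alignment


def make_annotation(subunit_id, ecd_end, anchor, segments=None):
    return SegmentAnnotation(
        subunit_id=subunit_id,
        segments=segments or {},
        ecd_end=ecd_end,
        anchor_residue=anchor,
    )


@pytest.fixture()
def annotation_factory():
    return make_annotation


def counts_table(rows):
    """ReportTable from (drug, ae_term, count) triples."""
    return ReportTable.from_counts(
        pd.DataFrame(rows, columns=["drug", "ae_term", "count"])
    )


@pytest.fixture()
def counts_factory():
    return counts_table


@pytest.fixture()
def independence_table():
    """Exact product-margin count table: counts = N * p_i * q_j, integral."""
    # margins chosen so every cell count N*p_i*q_j is an exact integer
    drug_w = np.array([1, 2, 3, 4])  # /10
    term_w = np.array([1, 4, 5])  # /10
    N = 1000
    rows = []
    for i, dw in enumerate(drug_w):
        for j, tw in enumerate(term_w):
            rows.append((f"d{i}", f"t{j}", int(N * dw * tw / 100)))
    return counts_table(rows)
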