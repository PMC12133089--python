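import pandas as pd
import pytest

from celltypeagent import ReferenceMatrix, WorldParams, make_world

# Human adipose toy reference. Pericyte and mural cell show similarly high
# mean expression of the classic pericyte markers (RGS5, KCNJ8, PDGFRB) —
# the ambiguity that defeats database-only annotation — with mural cell
# fractionally higher so the database-only argmax lands on the wrong label.
_ADIPOSE_ROWS = [
    # cell_type, gene, mean_expr
    ("pericyte", "RGS5", 4.2), ("pericyte", "KCNJ8", 3.1), ("pericyte", "PDGFRB", 3.8),
    ("mural cell", "RGS5", 4.3), ("mural cell", "KCNJ8", 3.2), ("mural cell", "PDGFRB", 3.7),
    ("smooth muscle cell", "RGS5", 3.9), ("smooth muscle cell", "KCNJ8", 1.0),
    ("smooth muscle cell", "PDGFRB", 2.5),
    ("fibroblast", "RGS5", 0.3), ("fibroblast", "KCNJ8", 0.1), ("fibroblast", "PDGFRB", 1.9),
    ("fibroblast", "COL1A1", 5.0), ("fibroblast", "LUM", 4.4),
    ("adipocyte", "RGS5", 0.2), ("adipocyte", "KCNJ8", 0.3), ("adipocyte", "PDGFRB", 0.4),
    ("adipocyte", "ADIPOQ", 6.1), ("adipocyte", "LPL", 5.2),
]

PERICYTE_MARKERS = ("RGS5", "KCNJ8", "PDGFRB")


@pytest.fixture(scope="session")
def adipose_ref() -> ReferenceMatrix:
    df = pd.DataFrame(_ADIPOSE_ROWS, columns=["cell_type", "gene", "mean_expr"])
    df.insert(0, "tissue", "adipose tissue")
    return ReferenceMatrix(df, species="Homo sapiens",
                           snapshot_meta={"source": "synthetic adipose toy reference",
                                          "unit": "mean log-normalized expression"})


@pytest.fixture(scope="session")
def clean_world():
    """Noise-free separable world: 1 tissue, 20 types, 3 markers each."""
    return make_world(WorldParams(), seed=7)


@pytest.fixture(scope="session")
def sibling_world():
    """Ambiguous world: every type paired with a sibling sharing 2/3 markers
    that also expresses the remaining markers at foreground level."""
    return make_world(WorldParams(noise_scale=0.2, n_sibling_pairs=10,
                                  sibling_bleed=1.0), seed=11)
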