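from pathlib import Path

import pandas as pd
import pytest

from codonuse.genetic_code import standard_code
from codonuse.sequence_io import CdsRecord

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def published_rscu() -> pd.DataFrame:
    """Published per-gene RSCU table for five human disease genes."""
    return pd.read_csv(DATA_DIR / "published_rscu.csv", comment="#").set_index("codon")


@pytest.fixture
def minimal_cds() -> CdsRecord:
    return CdsRecord(id="t1", gene="NIN", seq="ATGAAATAA")


def make_cds(seq: str, ident: str = "t", gene: str = "g") -> CdsRecord:
    return CdsRecord(id=ident, gene=gene, seq=seq)
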