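from pathlib import Path

import pytest

from fixmark.assay import BSRI
from fixmark.io import Alignment, Enzyme, GroupManifest, SequenceRecord


@pytest.fixture
def bsri() -> Enzyme:
    return BSRI


@pytest.fixture
def kpni() -> Enzyme:
    # palindromic control, GGTAC^C
    return Enzyme(name="KpnI", recognition="GGTACC", cut_top=5, cut_bottom=1)


@pytest.fixture
def enzyme_table_file(tmp_path: Path) -> Path:
    path = tmp_path / "enzymes.tsv"
    path.write_text(
        "# name\trecognition\tcut_top\tcut_bottom\taliases\n"
        "BsrI\tACTGG\t6\t4\tCCAGT\n"
        "KpnI\tGGTACC\t5\t1\n"
        "EcoRI\tGAATTC\t1\t5\n"
        "HindIII\tAAGCTT\t1\t5\n"
        "DraI\tTTTAAA\t3\t3\n"
    )
    return path


def make_alignment(rows: dict[str, str]) -> Alignment:
    return Alignment(tuple(SequenceRecord(i, s) for i, s in rows.items()))


def make_manifest(groups: dict[str, str], focal: str) -> GroupManifest:
    return GroupManifest(groups, focal)


@pytest.fixture
def toy_alignment() -> tuple[Alignment, GroupManifest]:
    """Two wild + three domestic sequences; columns 1 and 4 are diagnostic."""
    rows = {
        "w1": "ACGTA",
        "w2": "ACGTA",
        "d1": "ATGTG",
        "d2": "ATGTG",
        "d3": "ATGTG",
    }
    groups = {"w1": "wild", "w2": "wild", "d1": "dom", "d2": "dom", "d3": "dom"}
    return make_alignment(rows), make_manifest(groups, "wild")
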