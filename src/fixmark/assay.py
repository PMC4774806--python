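"""Reference data for the Indian wild pig (Sus scrofa cristatus) assay.

The published diagnostic panel comprises 15 fixed-difference SNPs across
four mitochondrial fragments — two cytochrome b fragments (421 and 398 bp),
a 12S rRNA fragment (382 bp) and a D-loop fragment (735 bp), 1936 bp in
all — with coordinates on the Lanyu wild boar complete mitogenome
(GenBank EF375877).  Substitutions are written background>focal: the base
carried by all other pig sequences, then the base fixed in Indian wild pig.

Also collected here: the universal D-loop primer pair (~1500 bp product)
and the BsrI enzyme model used by the discriminating PCR-RFLP assay
(three fragments in Indian wild pig, two in domestic pig).
"""

from __future__ import annotations

from .discovery import SnpMarker
from .io import Enzyme
from .pcr import PrimerPair

# fragment label -> length (bp)
FRAGMENT_LENGTHS = {
    "cytochrome b (421)": 421,
    "cytochrome b (398)": 398,
    "12S rRNA (382)": 382,
    "D-loop (735)": 735,
}

# (fragment label, EF375877 position, background allele, focal allele)
_PANEL = (
    ("cytochrome b (421)", 15689, "T", "C"),
    ("cytochrome b (421)", 15693, "A", "G"),
    ("cytochrome b (421)", 15725, "G", "A"),
    ("cytochrome b (421)", 15785, "A", "C"),
    ("cytochrome b (421)", 15825, "C", "T"),
    ("cytochrome b (421)", 15927, "T", "C"),
    ("cytochrome b (421)", 15949, "T", "C"),
    ("cytochrome b (398)", 15452, "C", "T"),
    ("cytochrome b (398)", 15512, "C", "T"),
    ("cytochrome b (398)", 15572, "T", "C"),
    ("12S rRNA (382)", 1870, "T", "C"),
    ("D-loop (735)", 149, "A", "G"),
    ("D-loop (735)", 322, "A", "G"),
    ("D-loop (735)", 407, "T", "A"),
    ("D-loop (735)", 675, "C", "T"),
)


def published_markers() -> list[SnpMarker]:
    """The 15-marker diagnostic panel as :class:`SnpMarker` rows."""
    return [
        SnpMarker.from_alleles(
            fragment_label=fragment,
            reference_position=position,
            alignment_column=position - 1,
            focal_allele=focal,
            background_allele=background,
        )
        for fragment, position, background, focal in _PANEL
    ]


def dloop_markers() -> list[SnpMarker]:
    """Just the four D-loop markers (positions 149, 322, 407, 675)."""
    return [m for m in published_markers() if m.fragment_label == "D-loop (735)"]


# Universal D-loop primers; product ~1500 bp.
DLOOP_PRIMERS = PrimerPair(
    forward="AGGAGACTAACTCCGCCAT",
    reverse="CGCGGATACTTGCATCTGT",
)

# BsrI, ACTGG(1/-1): top-strand cut 1 nt past the recognition 3' end.
# 5'-CCAGT-3' is the bottom-strand reading of the same site.
BSRI = Enzyme(name="BsrI", recognition="ACTGG", cut_top=6, cut_bottom=4, aliases=("CCAGT",))

# Observed digest of the ~1500 bp D-loop product: two BsrI sites (cuts near
# 97 and 375) in Indian wild pig giving fragments 97/278/1125; one site in
# domestic pig.
WILD_PIG_CUTS = (97, 375)
DOMESTIC_PIG_CUTS = (375,)
WILD_PIG_FRAGMENTS = (97, 278, 1125)
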