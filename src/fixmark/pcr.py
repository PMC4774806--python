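"""In-silico PCR: primer-site location and amplicon extraction.

Primers are matched on both strands by Hamming distance, with IUPAC codes
in the primer matching their base sets and an enforced exact match over the
3'-terminal window (polymerase extension requires a matched 3' end).
Template ambiguity codes never satisfy a primer base.  The amplicon spans
both primer footprints, the standard PCR-product convention, so its length
is what a gel would show.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import AmbiguousProductError, FixmarkError, NoAmplificationError
from .io import SequenceRecord

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

MIN_PRIMER_LENGTH = 10


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with binding-tolerance settings.

    Both primers are written 5'->3'.  ``max_mismatches`` bounds the Hamming
    distance of a binding site; ``require_exact_3prime`` is the number of
    3'-terminal primer bases that must match the template exactly.
    """

    forward: str
    reverse: str
    max_mismatches: int = 0
    require_exact_3prime: int = 3

    def __post_init__(self) -> None:
        for label, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if len(primer) < MIN_PRIMER_LENGTH:
                raise FixmarkError(f"{label} primer shorter than {MIN_PRIMER_LENGTH} nt")
            bad = set(primer) - set(IUPAC_SETS)
            if bad:
                raise FixmarkError(f"{label} primer contains invalid character(s) {sorted(bad)}")
        if self.max_mismatches < 0 or self.require_exact_3prime < 0:
            raise FixmarkError("mismatch/3'-window settings must be non-negative")


@dataclass(frozen=True)
class PrimerHit:
    """One binding site: 1-based footprint start on the top strand."""

    position: int
    strand: str  # '+' or '-'
    mismatches: int

    @property
    def is_forward_strand(self) -> bool:
        return self.strand == "+"


@dataclass(frozen=True)
class Amplicon:
    """The predicted PCR product, 1-based inclusive template coordinates."""

    template_id: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _matches(primer_base: str, template_base: str) -> bool:
    # template ambiguity codes never match (conservative)
    return template_base in IUPAC_SETS[primer_base]


def locate_primer(
    template: SequenceRecord,
    primer: str,
    max_mismatches: int = 0,
    require_exact_3prime: int = 3,
) -> list[PrimerHit]:
    """All binding sites of ``primer`` on both strands of ``template``.

    A hit needs Hamming distance <= ``max_mismatches`` with the 3'-terminal
    ``require_exact_3prime`` bases matching exactly.  Returned positions are
    1-based footprint starts on the top strand; a '-' hit means the primer
    anneals to the top strand (its 3' end points left).
    """
    if not template.is_gapless:
        raise FixmarkError(f"template {template.id!r} contains gaps; ungap before PCR")
    hits: list[PrimerHit] = []
    text = template.residues
    n, m = len(text), len(primer)
    if m > n:
        return hits
    rc = reverse_complement(primer)
    exact = min(require_exact_3prime, m)
    for offset in range(n - m + 1):
        window = text[offset : offset + m]
        # forward strand: primer 3' end is the window's right edge
        mm = _hamming(primer, window)
        if mm is not None and mm <= max_mismatches and _exact_block(primer, window, m - exact, m):
            hits.append(PrimerHit(offset + 1, "+", mm))
        # reverse strand: compare the primer's reverse complement; the 3'
        # terminal bases map to the window's LEFT edge
        mm = _hamming(rc, window)
        if mm is not None and mm <= max_mismatches and _exact_block(rc, window, 0, exact):
            hits.append(PrimerHit(offset + 1, "-", mm))
    return hits


def _hamming(pattern: str, window: str) -> int:
    return sum(0 if _matches(p, t) else 1 for p, t in zip(pattern, window))


def _exact_block(pattern: str, window: str, start: int, stop: int) -> bool:
    return all(_matches(pattern[i], window[i]) for i in range(start, stop))


def extract_amplicon(template: SequenceRecord, pair: PrimerPair) -> Amplicon:
    """The product delimited by one forward and one reverse primer site.

    Requires exactly one compatible placement: a forward-strand hit of the
    forward primer strictly upstream of a reverse-strand hit of the reverse
    primer, footprints non-overlapping.  Zero placements raise
    :class:`NoAmplificationError`; several raise
    :class:`AmbiguousProductError` listing every candidate product.
    """
    fwd_hits = locate_primer(template, pair.forward, pair.max_mismatches, pair.require_exact_3prime)
    rev_hits = locate_primer(template, pair.reverse, pair.max_mismatches, pair.require_exact_3prime)
    if not fwd_hits:
        raise NoAmplificationError(f"forward primer does not bind template {template.id!r}")
    if not rev_hits:
        raise NoAmplificationError(f"reverse primer does not bind template {template.id!r}")

    # PCR is orientation-symmetric: either the forward primer sits on the
    # top strand upstream of a bottom-strand reverse site, or (on the
    # template written the other way round) vice versa.
    candidates: set[tuple[int, int]] = set()
    for left_hits, left_len, right_hits, right_len in (
        (fwd_hits, len(pair.forward), rev_hits, len(pair.reverse)),
        (rev_hits, len(pair.reverse), fwd_hits, len(pair.forward)),
    ):
        for f in (h for h in left_hits if h.strand == "+"):
            f_end = f.position + left_len - 1
            for r in (h for h in right_hits if h.strand == "-"):
                if f_end < r.position:  # footprints non-overlapping
                    candidates.add((f.position, r.position + right_len - 1))
    if not candidates:
        raise NoAmplificationError(
            f"no compatible primer orientation on template {template.id!r}"
        )
    if len(candidates) > 1:
        listing = ", ".join(f"{s}..{e} ({e - s + 1} bp)" for s, e in sorted(candidates))
        raise AmbiguousProductError(
            f"{len(candidates)} candidate products on template {template.id!r}: {listing}",
            products=sorted(candidates),
        )
    (start, end) = next(iter(candidates))
    return Amplicon(
        template_id=template.id,
        start=start,
        end=end,
        sequence=template.residues[start - 1 : end],
    )
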