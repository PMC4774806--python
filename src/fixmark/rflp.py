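"""Restriction digestion in silico: site scanning, fragment prediction,
pattern comparison and enzyme screening.

Recognition sequences may contain IUPAC degeneracy and need not be
palindromic; non-palindromic enzymes (e.g. BsrI, ACTGG with bottom-strand
reading 5'-CCAGT-3') are scanned on both strands, palindromic ones are
reported once per locus.  Cut positions come from the enzyme's top-strand
offset on '+' sites and from the mirrored bottom-strand offset on '-'
sites; fragment sizes are computed from top-strand cut positions alone,
since gel mobility reflects overall length and sticky-end overhangs are
below gel resolution.

Pattern comparison bins fragment lengths at a gel resolution: by default
5% of fragment length or 10 bp, whichever is larger, approximating
agarose resolving power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .errors import AmbiguousTemplateError, EnzymeTableError, FixmarkError
from .io import UNAMBIGUOUS, Enzyme, SequenceRecord
from .pcr import IUPAC_SETS, reverse_complement

Topology = Literal["linear", "circular"]


@dataclass(frozen=True)
class RecognitionSite:
    """A matched recognition locus and the resulting top-strand scission.

    ``position`` is the 1-based start of the recognition match on the
    forward strand; ``cut_position`` is the 1-based index of the base
    immediately 5' of the top-strand cut (0 = cut before base 1).
    """

    position: int
    strand: str  # '+' or '-'
    cut_position: int


@dataclass(frozen=True)
class DigestResult:
    enzyme_name: str
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]
    topology: Topology

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_lengths)


@dataclass(frozen=True)
class PatternComparison:
    distinguishable: bool
    differing_fragments: int


@dataclass(frozen=True)
class ScreenResult:
    enzyme: Enzyme
    discriminates: bool
    within_group_consistent: bool
    total_sites: int


def _check_template(sequence: SequenceRecord, allow_ambiguous: bool) -> None:
    if not sequence.is_gapless:
        raise FixmarkError(f"sequence {sequence.id!r} contains gaps; digestion needs ungapped input")
    if not allow_ambiguous:
        bad = set(sequence.residues) - UNAMBIGUOUS
        if bad:
            raise AmbiguousTemplateError(
                f"sequence {sequence.id!r} contains ambiguity code(s) {sorted(bad)}; "
                "pass allow_ambiguous=True to scan anyway (ambiguous positions never match)"
            )


def _is_palindromic(recognition: str) -> bool:
    return reverse_complement(recognition) == recognition


def _pattern_matches_at(text: str, pattern: str, offset: int) -> bool:
    # degenerate codes in the PATTERN match their base sets; ambiguity in
    # the TEMPLATE never matches
    return all(text[offset + k] in IUPAC_SETS[p] for k, p in enumerate(pattern))


def _all_matches(text: str, pattern: str) -> list[int]:
    """0-based start offsets of every (possibly overlapping) degenerate match."""
    m = len(pattern)
    return [i for i in range(len(text) - m + 1) if _pattern_matches_at(text, pattern, i)]


def scan_sites(
    sequence: SequenceRecord, enzyme: Enzyme, allow_ambiguous: bool = False
) -> list[RecognitionSite]:
    """Every recognition locus of ``enzyme`` on either strand of ``sequence``.

    Overlapping matches are all reported and palindromic recognition is
    reported once per locus.  A top-strand cut that would fall past either
    end of the molecule is clamped to the boundary (there is no bond to
    cleave, so the digest sees no cut there); clamping rather than dropping
    keeps site counts strand-symmetric.
    """
    _check_template(sequence, allow_ambiguous)
    text = sequence.residues
    n = len(text)
    rec = enzyme.recognition
    L = len(rec)
    sites: list[RecognitionSite] = []
    for off in _all_matches(text, rec):
        p = off + 1
        cut = min(max(p + enzyme.cut_top - 1, 0), n)
        sites.append(RecognitionSite(p, "+", cut))
    if not _is_palindromic(rec):
        for off in _all_matches(text, reverse_complement(rec)):
            q = off + 1
            # mirrored offset: the enzyme reads the bottom strand 5'->3',
            # so its bottom-strand scission is the template's top-strand cut
            cut = min(max(q + L - 1 - enzyme.cut_bottom, 0), n)
            sites.append(RecognitionSite(q, "-", cut))
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def digest(
    sequence: SequenceRecord,
    enzyme: Enzyme,
    topology: Topology = "linear",
    allow_ambiguous: bool = False,
) -> DigestResult:
    """Predict the fragment lengths of a complete digest.

    Cuts are the sorted distinct top-strand cut positions from every site;
    zero-length fragments (coincident or terminal cuts) are dropped.
    """
    if topology not in ("linear", "circular"):
        raise FixmarkError(f"unknown topology {topology!r}")
    sites = scan_sites(sequence, enzyme, allow_ambiguous)
    n = len(sequence.residues)
    if topology == "linear":
        cuts = sorted({s.cut_position for s in sites if 0 < s.cut_position < n})
        bounds = [0, *cuts, n]
        fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    else:
        cuts = sorted({s.cut_position % n for s in sites})
        if not cuts:
            fragments = (n,)
        elif len(cuts) == 1:
            fragments = (n,)
        else:
            around = [*cuts, cuts[0] + n]
            fragments = tuple(b - a for a, b in zip(around, around[1:]))
    return DigestResult(enzyme.name, tuple(cuts), fragments, topology)


def _pair_tolerance(a: float, b: float, resolution: Optional[float]) -> float:
    if resolution is not None:
        return resolution
    return max(10.0, 0.05 * max(a, b))


def compare_patterns(
    a: DigestResult | Sequence[int],
    b: DigestResult | Sequence[int],
    resolution: Optional[float] = None,
) -> PatternComparison:
    """Would two digest patterns look different on a gel?

    Fragment multisets are matched greedily in sorted order; two fragments
    co-migrate when their lengths differ by at most the resolution (default:
    5% of the larger fragment or 10 bp, whichever is larger).  The patterns
    are distinguishable iff any fragment is left unmatched; the comparison
    is symmetric.
    """
    fa = sorted(a.fragment_lengths if isinstance(a, DigestResult) else a)
    fb = sorted(b.fragment_lengths if isinstance(b, DigestResult) else b)
    i = j = unmatched = 0
    while i < len(fa) and j < len(fb):
        if abs(fa[i] - fb[j]) <= _pair_tolerance(fa[i], fb[j], resolution):
            i += 1
            j += 1
        elif fa[i] < fb[j]:
            i += 1
            unmatched += 1
        else:
            j += 1
            unmatched += 1
    unmatched += (len(fa) - i) + (len(fb) - j)
    return PatternComparison(distinguishable=unmatched > 0, differing_fragments=unmatched)


def screen_enzymes(
    focal_sequences: Sequence[SequenceRecord],
    other_sequences: Sequence[SequenceRecord],
    enzyme_table: Sequence[Enzyme],
    resolution: Optional[float] = None,
    topology: Topology = "linear",
    allow_ambiguous: bool = False,
) -> list[ScreenResult]:
    """Rank enzymes by their power to separate two sequence groups on a gel.

    An enzyme discriminates iff every focal digest pattern differs from
    every other-group pattern at the given resolution AND each group is
    internally pattern-consistent.  Results are ranked discriminating
    first, then by fewest total sites (cheapest assay), then name.
    """
    if not enzyme_table:
        raise EnzymeTableError("empty enzyme table")
    if not focal_sequences or not other_sequences:
        raise FixmarkError("need at least one sequence per group")
    results = []
    for enzyme in enzyme_table:
        focal_digests = [digest(s, enzyme, topology, allow_ambiguous) for s in focal_sequences]
        other_digests = [digest(s, enzyme, topology, allow_ambiguous) for s in other_sequences]
        consistent = _internally_consistent(focal_digests, resolution) and _internally_consistent(
            other_digests, resolution
        )
        separates = all(
            compare_patterns(f, o, resolution).distinguishable
            for f in focal_digests
            for o in other_digests
        )
        total_sites = sum(
            len(scan_sites(s, enzyme, allow_ambiguous))
            for s in [*focal_sequences, *other_sequences]
        )
        results.append(
            ScreenResult(
                enzyme=enzyme,
                discriminates=consistent and separates,
                within_group_consistent=consistent,
                total_sites=total_sites,
            )
        )
    results.sort(key=lambda r: (not r.discriminates, r.total_sites, r.enzyme.name))
    return results


def _internally_consistent(digests: Sequence[DigestResult], resolution: Optional[float]) -> bool:
    first = digests[0]
    return all(not compare_patterns(first, d, resolution).distinguishable for d in digests[1:])


def format_virtual_gel(lanes: dict[str, Sequence[int]]) -> str:
    """An ASCII 'gel': one line per lane, fragments largest first."""
    width = max((len(name) for name in lanes), default=0)
    lines = []
    for name, fragments in lanes.items():
        sizes = " | ".join(str(f) for f in sorted(fragments, reverse=True))
        lines.append(f"{name.ljust(width)}  {sizes if sizes else '(uncut)'}")
    return "\n".join(lines)
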