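"""Diagnostic (fixed-difference) SNP discovery in group-labeled alignments.

A diagnostic SNP for a focal taxon is an alignment column where every focal
sequence carries one unambiguous base, every non-focal sequence carries a
single different unambiguous base, and the two differ.  Such fixed
interspecific differences are the markers used in wildlife-forensic species
assignment (e.g. separating Indian wild pig mitochondrial sequences from all
other pig sequences in an alignment).

Two calling policies are offered:

* ``strict`` (default): a column containing any gap or ambiguity code in any
  sequence is disqualified.  A forensic marker must hold for every observed
  sequence.
* ``permissive``: sequences with a gap or ambiguity code at the column are
  ignored, provided at least one informative sequence remains per group.

Marker coordinates are reported 1-based on the forward strand of a reference
sequence (GenBank-style numbering), mapped through a :class:`ReferenceMap`
that skips reference-gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping, Optional, Sequence

from .errors import FixmarkError, ManifestError, NoCoordinateError
from .io import GAP, UNAMBIGUOUS, Alignment, GroupManifest

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

TRANSITION = "transition"
TRANSVERSION = "transversion"
PURINE_PURINE = "purine-purine"
PYRIMIDINE_PYRIMIDINE = "pyrimidine-pyrimidine"
PURINE_PYRIMIDINE = "purine-pyrimidine"

PAIRING_CLASSES = (PYRIMIDINE_PYRIMIDINE, PURINE_PURINE, PURINE_PYRIMIDINE)

Policy = Literal["strict", "permissive"]


def classify_substitution(a: str, b: str) -> tuple[str, str]:
    """Classify the substitution a->b.

    Returns ``(mutation_class, pairing_class)`` where mutation_class is
    ``"transition"`` (A<->G or C<->T) or ``"transversion"``, and
    pairing_class is purine-purine, pyrimidine-pyrimidine or
    purine-pyrimidine.  Both bases must be unambiguous and distinct.
    """
    for base in (a, b):
        if base not in UNAMBIGUOUS:
            raise FixmarkError(f"cannot classify ambiguous or gap base {base!r}")
    if a == b:
        raise FixmarkError(f"{a}->{b} is not a substitution")
    pair = {a, b}
    if pair <= PURINES:
        return TRANSITION, PURINE_PURINE
    if pair <= PYRIMIDINES:
        return TRANSITION, PYRIMIDINE_PYRIMIDINE
    return TRANSVERSION, PURINE_PYRIMIDINE


@dataclass(frozen=True)
class ColumnProfile:
    """Per-group allele counts for one alignment column (0-based)."""

    column: int
    counts: Mapping[str, Mapping[str, int]]  # group -> {A,C,G,T,gap,ambiguous} -> count

    def group_total(self, group: str) -> int:
        return sum(self.counts[group].values())


def column_profiles(alignment: Alignment, manifest: GroupManifest) -> list[ColumnProfile]:
    """Profile every column of the alignment, partitioning counts by group."""
    groups = manifest.groups
    for rec in alignment:
        manifest.group_of(rec.id)  # raises ManifestError naming the id
    group_rows: dict[str, list[str]] = {g: [] for g in groups}
    for rec in alignment:
        group_rows[manifest.group_of(rec.id)].append(rec.residues)

    profiles = []
    for col in range(alignment.length):
        counts: dict[str, dict[str, int]] = {}
        for group, rows in group_rows.items():
            tally = {"A": 0, "C": 0, "G": 0, "T": 0, "gap": 0, "ambiguous": 0}
            for row in rows:
                base = row[col]
                if base in UNAMBIGUOUS:
                    tally[base] += 1
                elif base == GAP:
                    tally["gap"] += 1
                else:
                    tally["ambiguous"] += 1
            counts[group] = tally
        profiles.append(ColumnProfile(col, counts))
    return profiles


@dataclass(frozen=True)
class ReferenceMap:
    """Alignment column -> 1-based reference coordinate.

    ``offset`` is the reference coordinate of the first non-gap reference
    column; reference-gap columns map to no position.  When built without a
    reference sequence the mapping is the identity shifted by ``offset``.
    """

    reference_id: str
    offset: int
    column_positions: tuple[Optional[int], ...]

    def map_column(self, column: int) -> int:
        if not 0 <= column < len(self.column_positions):
            raise NoCoordinateError(
                f"column {column} outside alignment of length {len(self.column_positions)}"
            )
        pos = self.column_positions[column]
        if pos is None:
            raise NoCoordinateError(
                f"column {column} aligns to a gap in reference {self.reference_id!r}"
            )
        return pos


def build_reference_map(
    alignment: Alignment, reference_id: Optional[str] = None, offset: int = 1
) -> ReferenceMap:
    """Build the column->coordinate map from the named reference sequence.

    With ``reference_id=None`` the alignment is assumed gapless relative to
    the reference, i.e. column k maps to ``offset + k``.
    """
    if reference_id is None:
        positions = tuple(offset + k for k in range(alignment.length))
        return ReferenceMap("<identity>", offset, positions)
    reference = alignment.get(reference_id)
    positions_list: list[Optional[int]] = []
    seen = 0
    for base in reference.residues:
        if base == GAP:
            positions_list.append(None)
        else:
            positions_list.append(offset + seen)
            seen += 1
    return ReferenceMap(reference_id, offset, tuple(positions_list))


def map_column(reference_map: ReferenceMap, column: int) -> int:
    """1-based reference position of alignment column ``column`` (0-based)."""
    return reference_map.map_column(column)


@dataclass(frozen=True)
class SnpMarker:
    """One diagnostic SNP: reference coordinate, alleles, substitution classes.

    ``substitution`` is written background>focal, e.g. ``A>G`` for a column
    where all non-focal sequences carry A and all focal sequences carry G.
    """

    fragment_label: str
    reference_position: int
    alignment_column: int
    focal_allele: str
    background_allele: str
    substitution: str
    mutation_class: str
    pairing_class: str

    @classmethod
    def from_alleles(
        cls,
        fragment_label: str,
        reference_position: int,
        alignment_column: int,
        focal_allele: str,
        background_allele: str,
    ) -> "SnpMarker":
        mutation_class, pairing_class = classify_substitution(background_allele, focal_allele)
        return cls(
            fragment_label=fragment_label,
            reference_position=reference_position,
            alignment_column=alignment_column,
            focal_allele=focal_allele,
            background_allele=background_allele,
            substitution=f"{background_allele}>{focal_allele}",
            mutation_class=mutation_class,
            pairing_class=pairing_class,
        )


def find_diagnostic_snps(
    alignment: Alignment,
    manifest: GroupManifest,
    reference_map: Optional[ReferenceMap] = None,
    policy: Policy = "strict",
    fragment_label: str = "",
) -> list[SnpMarker]:
    """Call fixed-difference SNPs separating the focal group from all others.

    Returns the columns where all focal sequences share one unambiguous base,
    all non-focal sequences share one (different) unambiguous base, subject to
    the gap/ambiguity ``policy``.  Markers are ordered by reference position;
    columns that align to a reference gap are never reported.
    """
    if policy not in ("strict", "permissive"):
        raise FixmarkError(f"unknown policy {policy!r}")
    if len(manifest.groups) < 2:
        raise ManifestError("need at least 2 groups to call diagnostic SNPs")
    if not any(manifest.group_of(r.id) == manifest.focal for r in alignment):
        raise ManifestError(f"focal group {manifest.focal!r} has no sequences in the alignment")
    if reference_map is None:
        reference_map = build_reference_map(alignment)

    focal_rows = [r.residues for r in alignment if manifest.group_of(r.id) == manifest.focal]
    other_rows = [r.residues for r in alignment if manifest.group_of(r.id) != manifest.focal]

    markers = []
    for col in range(alignment.length):
        focal_base = _column_fixed_base([row[col] for row in focal_rows], policy)
        if focal_base is None:
            continue
        other_base = _column_fixed_base([row[col] for row in other_rows], policy)
        if other_base is None or other_base == focal_base:
            continue
        try:
            position = reference_map.map_column(col)
        except NoCoordinateError:
            continue
        markers.append(
            SnpMarker.from_alleles(
                fragment_label=fragment_label,
                reference_position=position,
                alignment_column=col,
                focal_allele=focal_base,
                background_allele=other_base,
            )
        )
    markers.sort(key=lambda m: m.reference_position)
    return markers


def _column_fixed_base(bases: Sequence[str], policy: Policy) -> Optional[str]:
    informative = [b for b in bases if b in UNAMBIGUOUS]
    if policy == "strict" and len(informative) != len(bases):
        return None
    if not informative:
        return None
    first = informative[0]
    return first if all(b == first for b in informative) else None


@dataclass(frozen=True)
class MarkerSummary:
    """Census of a marker panel: totals and substitution-spectrum percentages."""

    total_markers: int
    fragment_lengths: tuple[int, ...]
    total_fragment_length: int
    class_counts: Mapping[str, int]
    class_percentages: Mapping[str, int]


def _round_half_up(x: float) -> int:
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def summarize_markers(markers: Sequence[SnpMarker], fragment_lengths: Sequence[int]) -> MarkerSummary:
    """Count markers per pairing class and express them as integer percentages.

    Percentages are round-half-up of 100*count/total and are not forced to
    sum to 100.  ``fragment_lengths`` are the lengths (bp) of the surveyed
    fragments; their sum is reported alongside.
    """
    if not markers:
        raise FixmarkError("cannot summarize an empty marker list")
    counts = {cls: 0 for cls in PAIRING_CLASSES}
    for m in markers:
        counts[m.pairing_class] += 1
    total = len(markers)
    percentages = {cls: _round_half_up(100.0 * n / total) for cls, n in counts.items()}
    return MarkerSummary(
        total_markers=total,
        fragment_lengths=tuple(fragment_lengths),
        total_fragment_length=sum(fragment_lengths),
        class_counts=counts,
        class_percentages=percentages,
    )
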