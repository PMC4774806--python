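"""Readers and writers for all external representations.

Formats handled here:

* FASTA (aligned and unaligned), parsed with Bio.SeqIO; residues are
  uppercased on read and validated against the IUPAC DNA alphabet plus the
  alignment gap character ``-``.
* Group manifests: tab-delimited ``id<TAB>group`` lines, ``#`` comments.
* Restriction-enzyme tables: tab-delimited
  ``name<TAB>recognition<TAB>cut_top<TAB>cut_bottom[<TAB>aliases]`` with cut
  offsets measured in nucleotides from the recognition start on the top
  strand read 5'->3' (so BsrI, ACTGG(1/-1), is ``BsrI  ACTGG  6  4``).
  The optional comma-separated alias column admits alternative names or
  bottom-strand site spellings (e.g. CCAGT for BsrI).
* Marker reports: tab-delimited tables with one diagnostic SNP per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import (
    AlignmentError,
    EnzymeTableError,
    FastaFormatError,
    ManifestError,
)

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
GAP = "-"
_VALID_RESIDUES = IUPAC_DNA | {GAP}
UNAMBIGUOUS = frozenset("ACGT")

FASTA_WRAP = 70


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence: identifier, free-text description, residue string."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaFormatError(f"invalid sequence id {self.id!r}: must be a non-empty token")
        if not self.residues:
            raise FastaFormatError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise FastaFormatError(
                f"sequence {self.id!r} contains non-IUPAC character(s) "
                f"{', '.join(sorted(repr(c) for c in bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_gapless(self) -> bool:
        return GAP not in self.residues

    def ungapped(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.residues.replace(GAP, ""), self.description)


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped sequences (>= 2 records)."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError(f"an alignment needs at least 2 sequences, got {len(self.records)}")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            detail = ", ".join(f"{r.id}={len(r)}" for r in self.records)
            raise AlignmentError(f"sequences have unequal lengths: {detail}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence id(s): {', '.join(dupes)}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def column(self, index: int) -> str:
        """Residues of alignment column ``index`` (0-based), in record order."""
        return "".join(r.residues[index] for r in self.records)


@dataclass(frozen=True)
class GroupManifest:
    """Mapping of sequence id to group label, with a designated focal group."""

    assignments: Mapping[str, str]
    focal: str

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        if len(labels) < 2:
            raise ManifestError(f"need at least 2 distinct group labels, got {sorted(labels)}")
        if self.focal not in labels:
            raise ManifestError(f"focal group {self.focal!r} not among assigned labels {sorted(labels)}")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.assignments.values())))

    def group_of(self, seq_id: str) -> str:
        try:
            return self.assignments[seq_id]
        except KeyError:
            raise ManifestError(f"sequence {seq_id!r} has no group assignment") from None

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(i for i, g in self.assignments.items() if g == group)


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease recognition/cleavage model.

    ``cut_top`` / ``cut_bottom`` are distances, in nucleotides, from the
    recognition-sequence start to the scission on the top / bottom strand
    (top strand read 5'->3'); offsets may exceed the recognition length for
    outside cutters such as BsrI.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int
    aliases: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise EnzymeTableError(f"invalid enzyme name {self.name!r}")
        if len(self.recognition) < 4:
            raise EnzymeTableError(
                f"enzyme {self.name}: recognition {self.recognition!r} shorter than 4 nt"
            )
        bad = set(self.recognition) - IUPAC_DNA
        if bad:
            raise EnzymeTableError(
                f"enzyme {self.name}: recognition contains non-IUPAC character(s) "
                f"{', '.join(sorted(bad))}"
            )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved."""
    path = Path(path)
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise FastaFormatError(f"{path}: empty or not FASTA-formatted")
    records = []
    for rec in parsed:
        residues = str(rec.seq).upper()
        bad = set(residues) - _VALID_RESIDUES
        if bad:
            char = sorted(bad)[0]
            raise FastaFormatError(
                f"{path}, line {_find_line(path, char)}: "
                f"non-IUPAC character {char!r} in sequence {rec.id!r}"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(rec.id, residues, desc))
    return records


def _find_line(path: Path, char: str) -> int:
    """Line number (1-based) of the first sequence line containing ``char``."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if char in line.upper():
                return lineno
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = FASTA_WRAP) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file, validating equal lengths (>= 2 records)."""
    return Alignment(tuple(read_fasta(path)))


def read_manifest(path: str | Path, focal: str) -> GroupManifest:
    """Read ``id<TAB>group`` lines into a :class:`GroupManifest`."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ManifestError(f"{path}, line {lineno}: expected 'id<TAB>group', got {raw!r}")
            seq_id, group = parts
            if seq_id in assignments:
                raise ManifestError(f"{path}, line {lineno}: duplicate assignment for {seq_id!r}")
            assignments[seq_id] = group
    if not assignments:
        raise ManifestError(f"{path}: no assignments found")
    return GroupManifest(assignments, focal)


def write_manifest(manifest: GroupManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, group in manifest.assignments.items():
            fh.write(f"{seq_id}\t{group}\n")


def read_enzyme_table(path: str | Path) -> list[Enzyme]:
    """Parse a tab-delimited enzyme table (see module docstring for the dialect)."""
    enzymes: list[Enzyme] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise EnzymeTableError(
                    f"{path}, line {lineno}: expected 4 or 5 tab-delimited fields, got {len(parts)}"
                )
            name, recognition = parts[0], parts[1].upper()
            try:
                cut_top, cut_bottom = int(parts[2]), int(parts[3])
            except ValueError:
                raise EnzymeTableError(
                    f"{path}, line {lineno}: cut offsets must be integers, got {parts[2]!r}/{parts[3]!r}"
                ) from None
            aliases = tuple(a.strip() for a in parts[4].split(",") if a.strip()) if len(parts) == 5 else ()
            if name in seen:
                raise EnzymeTableError(f"{path}, line {lineno}: duplicate enzyme name {name!r}")
            seen.add(name)
            try:
                enzymes.append(Enzyme(name, recognition, cut_top, cut_bottom, aliases))
            except EnzymeTableError as exc:
                raise EnzymeTableError(f"{path}, line {lineno}: {exc}") from None
    if not enzymes:
        raise EnzymeTableError(f"{path}: no enzymes found")
    return enzymes


def find_enzyme(enzymes: Sequence[Enzyme], key: str) -> Enzyme:
    """Look an enzyme up by name or alias (case-insensitive)."""
    low = key.lower()
    for enz in enzymes:
        if enz.name.lower() == low or any(a.lower() == low for a in enz.aliases):
            return enz
    raise EnzymeTableError(f"no enzyme named {key!r} in table")


MARKER_REPORT_COLUMNS = (
    "fragment",
    "reference_position",
    "alignment_column",
    "focal_allele",
    "background_allele",
    "substitution",
    "mutation_class",
    "pairing_class",
)


def write_marker_report(markers, path: str | Path) -> None:
    """Write diagnostic markers as a tab-delimited table (one row per SNP)."""
    with open(path, "w") as fh:
        fh.write("\t".join(MARKER_REPORT_COLUMNS) + "\n")
        for m in markers:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        m.fragment_label,
                        m.reference_position,
                        m.alignment_column,
                        m.focal_allele,
                        m.background_allele,
                        m.substitution,
                        m.mutation_class,
                        m.pairing_class,
                    )
                )
                + "\n"
            )


def read_marker_report(path: str | Path):
    """Read a marker report back into :class:`~fixmark.discovery.SnpMarker` rows."""
    from .discovery import SnpMarker

    markers = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MARKER_REPORT_COLUMNS:
            raise FastaFormatError(f"{path}: not a marker report (unexpected header)")
        for raw in fh:
            if not raw.strip():
                continue
            (frag, pos, col, focal, background, _sub, _mut, _pair) = raw.rstrip("\n").split("\t")
            markers.append(
                SnpMarker.from_alleles(
                    fragment_label=frag,
                    reference_position=int(pos),
                    alignment_column=int(col),
                    focal_allele=focal,
                    background_allele=background,
                )
            )
    return markers
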