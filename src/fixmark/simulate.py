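"""Group-structured alignment simulation with planted diagnostic SNPs.

The generator emulates the design of a mitochondrial species-identification
study: a focal group of wild-pig sequences against a larger background of
other wild and domestic pig sequences, with a handful of fixed
interspecific differences (the planted markers), low within-group
polymorphism, a transition-biased mutation process, and optional N
ambiguities.  Defaults reproduce the D-loop study design: a 735 bp
fragment, 14 focal + 44 background sequences, and four planted markers.

Outputs are gapless, so alignment column k corresponds to reference
position k+1; every draw comes from a single seeded generator stream
(reference first, then mutations group by group, sequence by sequence,
then ambiguities) so identical configs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .io import UNAMBIGUOUS, Alignment, GroupManifest, SequenceRecord
from .discovery import SnpMarker, classify_substitution

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSION_PARTNERS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}

# Defaults emulate the published D-loop design: a 735 bp fragment, 14 Indian
# wild pig vs 44 other sequences, four fixed differences (three transitions,
# one transversion), ~1% within-group divergence, strong transition bias.
DEFAULT_PLANTED = (
    (149, "G", "A"),
    (322, "G", "A"),
    (407, "A", "T"),
    (675, "T", "C"),
)


@dataclass(frozen=True)
class SimulationConfig:
    reference_length: int = 735
    gc_fraction: float = 0.40
    group_sizes: Mapping[str, int] = field(default_factory=lambda: {"indian_wild": 14, "other": 44})
    focal: str = "indian_wild"
    planted_markers: tuple[tuple[int, str, str], ...] = DEFAULT_PLANTED
    within_group_mutation_rate: float = 0.01
    tsv_bias: float = 0.9  # probability a within-group mutation is a transition
    ambiguity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_length < 1:
            raise ConfigError(f"reference_length must be >= 1, got {self.reference_length}")
        for rate, name in (
            (self.gc_fraction, "gc_fraction"),
            (self.within_group_mutation_rate, "within_group_mutation_rate"),
            (self.tsv_bias, "tsv_bias"),
            (self.ambiguity_rate, "ambiguity_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {rate}")
        if len(self.group_sizes) < 2:
            raise ConfigError("need at least 2 groups")
        if self.focal not in self.group_sizes:
            raise ConfigError(f"focal group {self.focal!r} not in group_sizes")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ConfigError("every group needs at least 1 sequence")
        positions = [p for p, _, _ in self.planted_markers]
        if len(set(positions)) != len(positions):
            raise ConfigError("planted marker positions collide")
        for pos, focal_allele, background_allele in self.planted_markers:
            if not 1 <= pos <= self.reference_length:
                raise ConfigError(f"planted position {pos} outside [1, {self.reference_length}]")
            for allele in (focal_allele, background_allele):
                if allele not in UNAMBIGUOUS:
                    raise ConfigError(f"planted allele {allele!r} not in A/C/G/T")
            if focal_allele == background_allele:
                raise ConfigError(f"planted alleles identical at position {pos}")


@dataclass(frozen=True)
class SyntheticTruth:
    """The planted ground truth paired with a generated alignment."""

    config: SimulationConfig
    group_labels: Mapping[str, str]  # sequence id -> group
    markers: tuple[SnpMarker, ...]


def study_config(**overrides) -> SimulationConfig:
    """The default study-design configuration, with optional field overrides."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def generate_reference(length: int, gc_fraction: float, seed: int) -> SequenceRecord:
    """An i.i.d. random reference with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ConfigError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ConfigError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    residues = _draw_sequence(rng, length, gc_fraction)
    return SequenceRecord("reference", residues, f"simulated reference gc={gc_fraction}")


def _draw_sequence(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    return "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=length, p=p))


def _mutate(base: str, tsv_bias: float, rng: np.random.Generator) -> str:
    if rng.random() < tsv_bias:
        return TRANSITION_PARTNER[base]
    return TRANSVERSION_PARTNERS[base][rng.integers(0, 2)]


def simulate_alignment(
    config: SimulationConfig,
) -> tuple[Alignment, GroupManifest, SyntheticTruth]:
    """Generate (Alignment, GroupManifest, SyntheticTruth) from ``config``.

    Every focal sequence carries the focal allele and every non-focal
    sequence the background allele at each planted position; within-group
    mutations and N ambiguities are rejection-sampled away from planted
    columns so the truth table stays exact.
    """
    rng = np.random.default_rng(config.seed)
    reference = list(_draw_sequence(rng, config.reference_length, config.gc_fraction))

    planted = sorted(config.planted_markers)
    planted_cols = {pos - 1 for pos, _, _ in planted}
    # background consensus: reference forced to the background allele at
    # planted positions, so all non-focal groups agree there.
    for pos, _, background_allele in planted:
        reference[pos - 1] = background_allele
    focal_consensus = list(reference)
    for pos, focal_allele, _ in planted:
        focal_consensus[pos - 1] = focal_allele

    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for group in sorted(config.group_sizes):
        consensus = focal_consensus if group == config.focal else reference
        for i in range(config.group_sizes[group]):
            seq = list(consensus)
            if config.within_group_mutation_rate > 0:
                for col in range(config.reference_length):
                    if col in planted_cols:
                        continue
                    if rng.random() < config.within_group_mutation_rate:
                        seq[col] = _mutate(seq[col], config.tsv_bias, rng)
            if config.ambiguity_rate > 0:
                for col in range(config.reference_length):
                    if col in planted_cols:
                        continue
                    if rng.random() < config.ambiguity_rate:
                        seq[col] = "N"
            seq_id = f"{group}_{i + 1:02d}"
            records.append(SequenceRecord(seq_id, "".join(seq), f"simulated {group}"))
            labels[seq_id] = group

    alignment = Alignment(tuple(records))
    manifest = GroupManifest(labels, config.focal)
    truth_markers = tuple(
        SnpMarker.from_alleles(
            fragment_label="simulated",
            reference_position=pos,
            alignment_column=pos - 1,
            focal_allele=focal_allele,
            background_allele=background_allele,
        )
        for pos, focal_allele, background_allele in planted
    )
    return alignment, manifest, SyntheticTruth(config, labels, truth_markers)


def plant_recognition_sites(
    length: int,
    recognition: str,
    start_positions: Sequence[int],
    seed: int,
    gc_fraction: float = 0.40,
    forbid: Sequence[str] = (),
) -> SequenceRecord:
    """A random sequence carrying a recognition word exactly at given starts.

    Generates an i.i.d. sequence, scrubs every accidental occurrence of the
    recognition word, its reverse complement and any ``forbid`` words (by
    redrawing one base inside the occurrence), then writes the recognition
    word at each requested 1-based start.  Useful for constructing templates
    whose digestion pattern is known by design.
    """
    from Bio.Seq import Seq  # local import: only needed here in this module

    if any(not 1 <= p <= length - len(recognition) + 1 for p in start_positions):
        raise ConfigError("a requested site does not fit inside the sequence")
    rng = np.random.default_rng(seed)
    words = {recognition, str(Seq(recognition).reverse_complement())}
    words.update(forbid)
    words.update(str(Seq(w).reverse_complement()) for w in list(words))

    seq = list(_draw_sequence(rng, length, gc_fraction))
    protected: set[int] = set()
    for p in start_positions:
        for k, base in enumerate(recognition):
            seq[p - 1 + k] = base
            protected.add(p - 1 + k)

    for _ in range(10_000):
        text = "".join(seq)
        hit = _find_unwanted(text, words, start_positions, len(recognition))
        if hit is None:
            break
        start, word = hit
        free = [i for i in range(start, start + len(word)) if i not in protected]
        if not free:  # a spurious word living entirely inside planted sites
            raise ConfigError("cannot scrub a site overlapping only planted bases")
        i = free[rng.integers(0, len(free))]
        seq[i] = "ACGT"[rng.integers(0, 4)]
    else:
        raise ConfigError("failed to scrub accidental recognition sites")
    return SequenceRecord("constructed", "".join(seq), "template with planted sites")


def _find_unwanted(text, words, start_positions, reclen):
    wanted = {p - 1 for p in start_positions}
    for word in words:
        start = text.find(word)
        while start != -1:
            if not (start in wanted and len(word) == reclen and text[start : start + reclen] == word):
                return start, word
            start = text.find(word, start + 1)
    return None
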