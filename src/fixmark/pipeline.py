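"""End-to-end orchestration: simulate/load -> discover -> PCR -> digest -> screen.

Each stage logs its parameters to stderr and writes plain-text,
tab-delimited outputs (forensic workflows favor auditable text reports):

* ``alignment.fasta`` / ``manifest.tsv`` / ``truth.tsv`` (simulated runs)
* ``markers.tsv``  — the diagnostic marker report
* ``summary.txt``  — key/value census and substitution spectrum
* ``amplicon.fasta`` — predicted PCR product (when primers are configured)
* ``digest.tsv`` / ``gel.txt`` — fragment report and ASCII virtual gel

A stage failure is re-raised as :class:`PipelineError` with the stage name
in the message; the CLI turns that into a nonzero exit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import discovery, io, pcr, rflp, simulate
from .errors import FixmarkError, PipelineError

log = logging.getLogger("fixmark")


@dataclass
class PipelineConfig:
    output_dir: Path = Path("fixmark-out")
    seed: int = 0

    # input files; alignment_path=None triggers simulation
    alignment_path: Optional[Path] = None
    manifest_path: Optional[Path] = None
    focal: str = "indian_wild"
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)

    # coordinate mapping
    reference_id: Optional[str] = None
    offset: int = 1

    policy: str = "strict"
    fragment_label: str = "fragment"

    # optional PCR stage
    template_path: Optional[Path] = None
    forward_primer: Optional[str] = None
    reverse_primer: Optional[str] = None
    max_mismatches: int = 0
    exact_3prime: int = 3

    # optional digestion stage
    enzyme_table_path: Optional[Path] = None
    enzyme_name: Optional[str] = None
    topology: str = "linear"
    resolution: Optional[float] = None


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            log.info("stage %s: starting", name)
            try:
                out = fn(*args, **kwargs)
            except FixmarkError as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
            except OSError as exc:
                raise PipelineError(f"[{name}] I/O error: {exc}") from exc
            log.info("stage %s: done", name)
            return out

        return run

    return wrap


@_stage("inputs")
def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.alignment_path is None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        log.info("simulating alignment: %d groups, length %d, seed %d",
                 len(sim.group_sizes), sim.reference_length, sim.seed)
        alignment, manifest, truth = simulate.simulate_alignment(sim)
        io.write_fasta(alignment.records, outdir / "alignment.fasta")
        io.write_manifest(manifest, outdir / "manifest.tsv")
        io.write_marker_report(truth.markers, outdir / "truth.tsv")
        return alignment, manifest
    log.info("reading alignment %s", config.alignment_path)
    alignment = io.read_alignment(config.alignment_path)
    if config.manifest_path is None:
        raise FixmarkError("a manifest is required when an alignment file is given")
    manifest = io.read_manifest(config.manifest_path, config.focal)
    return alignment, manifest


@_stage("discover")
def _discover(config: PipelineConfig, alignment, manifest, outdir: Path):
    refmap = discovery.build_reference_map(alignment, config.reference_id, config.offset)
    markers = discovery.find_diagnostic_snps(
        alignment, manifest, refmap, policy=config.policy, fragment_label=config.fragment_label
    )
    io.write_marker_report(markers, outdir / "markers.tsv")
    log.info("discovered %d diagnostic marker(s)", len(markers))
    if markers:
        summary = discovery.summarize_markers(markers, [alignment.length])
        _write_summary(summary, outdir / "summary.txt")
    else:
        (outdir / "summary.txt").write_text("total_markers\t0\n")
    return markers


def _write_summary(summary: discovery.MarkerSummary, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"total_markers\t{summary.total_markers}\n")
        fh.write(f"fragment_lengths\t{','.join(map(str, summary.fragment_lengths))}\n")
        fh.write(f"total_fragment_length\t{summary.total_fragment_length}\n")
        for cls in discovery.PAIRING_CLASSES:
            fh.write(f"count[{cls}]\t{summary.class_counts[cls]}\n")
        for cls in discovery.PAIRING_CLASSES:
            fh.write(f"percent[{cls}]\t{summary.class_percentages[cls]}\n")


@_stage("pcr")
def _run_pcr(config: PipelineConfig, outdir: Path):
    templates = io.read_fasta(config.template_path)
    pair = pcr.PrimerPair(
        forward=config.forward_primer,
        reverse=config.reverse_primer,
        max_mismatches=config.max_mismatches,
        require_exact_3prime=config.exact_3prime,
    )
    amplicons = []
    for template in templates:
        amp = pcr.extract_amplicon(template, pair)
        log.info("amplicon on %s: %d..%d (%d bp)", template.id, amp.start, amp.end, amp.length)
        amplicons.append(
            io.SequenceRecord(
                f"{template.id}_amplicon",
                amp.sequence,
                f"predicted product {amp.start}..{amp.end} ({amp.length} bp)",
            )
        )
    io.write_fasta(amplicons, outdir / "amplicon.fasta")
    return amplicons


@_stage("digest")
def _run_digest(config: PipelineConfig, sequences, outdir: Path):
    enzymes = io.read_enzyme_table(config.enzyme_table_path)
    enzyme = io.find_enzyme(enzymes, config.enzyme_name)
    lanes = {}
    with open(outdir / "digest.tsv", "w") as fh:
        fh.write("sequence\tenzyme\tn_sites\tcut_positions\tfragment_lengths\n")
        for seq in sequences:
            result = rflp.digest(seq, enzyme, topology=config.topology)
            lanes[seq.id] = result.fragment_lengths
            fh.write(
                f"{seq.id}\t{enzyme.name}\t{len(result.cut_positions)}\t"
                f"{','.join(map(str, result.cut_positions))}\t"
                f"{','.join(map(str, result.fragment_lengths))}\n"
            )
            log.info("digest %s with %s: fragments %s", seq.id, enzyme.name, result.fragment_lengths)
    (outdir / "gel.txt").write_text(rflp.format_virtual_gel(lanes) + "\n")
    return lanes


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns a dict of stage outputs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    alignment, manifest = _load_inputs(config, outdir)
    results["alignment"] = alignment
    results["manifest"] = manifest
    results["markers"] = _discover(config, alignment, manifest, outdir)

    amplicons = None
    if config.template_path and config.forward_primer and config.reverse_primer:
        amplicons = _run_pcr(config, outdir)
        results["amplicons"] = amplicons

    if config.enzyme_table_path and config.enzyme_name:
        targets = amplicons
        if targets is None and config.template_path:
            targets = io.read_fasta(config.template_path)
        if targets:
            results["digest"] = _run_digest(config, targets, outdir)
    return results


def read_flat_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` (or ``key<TAB>value``) config file."""
    values: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line:
                key, _, value = line.partition("=")
            elif "\t" in line:
                key, _, value = line.partition("\t")
            else:
                raise FixmarkError(f"{path}, line {lineno}: expected 'key = value'")
            values[key.strip()] = value.strip()
    return values
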