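"""Exception hierarchy.

Every error raised by fixmark derives from :class:`FixmarkError`, so callers
(notably the CLI) can catch one type and report a stage-labeled message.
"""


class FixmarkError(Exception):
    """Base class for all fixmark errors."""


class FastaFormatError(FixmarkError):
    """Malformed FASTA input (empty file, illegal residue character, ...)."""


class AlignmentError(FixmarkError):
    """Sequences that do not form a valid alignment (unequal lengths, <2 records)."""


class ManifestError(FixmarkError):
    """Bad group manifest: missing assignments, unknown focal label, ..."""


class EnzymeTableError(FixmarkError):
    """Malformed restriction-enzyme table line or duplicate enzyme name."""


class NoCoordinateError(FixmarkError):
    """An alignment column has no reference coordinate (reference gap)."""


class AmbiguousTemplateError(FixmarkError):
    """A digestion/PCR template contains IUPAC ambiguity codes (or gaps)."""


class NoAmplificationError(FixmarkError):
    """No compatible primer-pair binding; PCR would yield no product."""


class AmbiguousProductError(FixmarkError):
    """More than one compatible primer-pair placement (multiple products)."""

    def __init__(self, message: str, products=None):
        super().__init__(message)
        self.products = list(products or [])


class ConfigError(FixmarkError):
    """Invalid simulation or pipeline configuration."""


class PipelineError(FixmarkError):
    """A pipeline stage failed; message is prefixed with the stage name."""
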