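"""Exception types shared across the pipeline."""


class PoolDiverError(Exception):
    """Base class for all package errors."""


class ArgumentError(PoolDiverError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(PoolDiverError, ValueError):
    """Input is structurally valid but degenerate (e.g. constant vector)."""


class PedigreeError(PoolDiverError, ValueError):
    """Pedigree is malformed (cycle, unknown parent id, duplicate id)."""


class FormatError(PoolDiverError, ValueError):
    """A file or record does not conform to its documented schema."""


class StructureError(PoolDiverError, ValueError):
    """Gene-model structure violates its invariants (e.g. CDS outside exons)."""


class DataError(PoolDiverError, ValueError):
    """Data inconsistency, e.g. a variant's reference allele does not match
    the reference sequence."""
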