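"""Exception types shared across modules."""


class CretraceError(Exception):
    """Base class for all package errors."""


class InvalidSequenceError(CretraceError):
    """Sequence is empty or contains characters outside {A,C,G,T}.

    Raised in particular for sequences containing undetermined bases (N),
    which are rejected at load rather than silently dropped.
    """


class AlignmentError(CretraceError):
    """Invalid alignment input or inconsistent scoring parameters."""


class MutationError(CretraceError):
    """A mutation event does not belong to the alignment it is applied to."""


class MotifError(CretraceError):
    """Invalid motif model, normalizer, or scan input."""


class PhyloError(CretraceError):
    """Invalid tree, missing node, or inconsistent lineage request."""


class OracleError(CretraceError):
    """Scoring oracle failure (bad config, zero null, plug-in error)."""


class MPRAError(CretraceError):
    """Invalid count table, barcode map, or degenerate sample totals."""


class EpistasisError(CretraceError):
    """Missing mutation ids or degenerate effect-model input."""
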