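"""Exception hierarchy for prskit.

Every error the library raises deliberately derives from :class:`PrsKitError`
so callers (and the CLI) can distinguish expected failure modes from bugs.
"""


class PrsKitError(Exception):
    """Base class for all prskit errors."""


class FormatError(PrsKitError):
    """An input file violates its documented dialect (missing columns,
    malformed genotype token, broken sparse-store schema)."""


class EmptyTableError(PrsKitError):
    """A weight table parsed to zero usable rows."""


class InvariantError(PrsKitError):
    """A data-structure invariant is violated (overlapping reference
    blocks, hom-ref entry in a sparse store, misaligned call vector)."""


class ContractViolation(PrsKitError):
    """An operation was called outside its precondition, e.g. asking for
    an effect dosage with an UNMATCHED allele role."""


class StatisticsError(PrsKitError):
    """A statistic is undefined on the given input (single-class labels,
    zero variance in both vectors, too few observations)."""


class SeparationError(StatisticsError):
    """Logistic fit failed: perfect separation or non-convergence.

    Raised explicitly rather than returning numerically meaningless
    coefficients.
    """
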