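"""Exception hierarchy shared across the pipeline."""


class WormdriftError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(WormdriftError):
    """A file did not conform to the expected format or dialect."""


class SizingError(WormdriftError):
    """Requested feature counts exceed the available placement space."""


class CoordinateMismatchError(WormdriftError):
    """A coordinate-indexed sequence disagreed with its annotation.

    Raised e.g. when a SNP's reference allele does not match the base
    recorded for a transposable element at that offset, which signals that
    the annotations and the genome are out of register.
    """


class PipelineError(WormdriftError):
    """A pipeline stage failed; the message names the stage."""
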