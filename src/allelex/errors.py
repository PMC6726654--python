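"""Exception hierarchy for allelex."""


class AllelexError(Exception):
    """Base class for all allelex errors."""


class MutationFileError(AllelexError):
    """A mutation table is malformed (missing columns or invalid rows)."""


class ChromosomeNotFoundError(AllelexError):
    """A requested chromosome is absent from the reference genome."""


class BoundsError(AllelexError):
    """A coordinate falls outside the sequence or gene span it refers to."""


class RefMismatchError(AllelexError):
    """A mutation's reference allele disagrees with the extracted sequence."""


class OverlapError(AllelexError):
    """Two mutations within one gene occupy overlapping positions."""


class OrderingError(AllelexError):
    """A stream that must be coordinate-sorted is not."""


class ReferenceMismatchError(AllelexError):
    """Alignment contigs share nothing with the mutation index."""


class CompletenessError(AllelexError):
    """A counts table does not cover the mutation list it is joined with."""


class CapacityError(AllelexError):
    """Requested mutations cannot be placed in the available gene span."""


class ConfigError(AllelexError):
    """Invalid configuration or inconsistent inputs."""
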