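"""Exception types shared across the package."""


class MutascanError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MutascanError, ValueError):
    """A model or configuration parameter violates its constraints."""


class AlleleLostError(MutascanError):
    """The deterministic trajectory reaches loss before the present, so no
    carrier haplotypes can be sampled."""


class NoLossError(MutascanError):
    """No simulation replicate ended in allele loss, so a mean loss time is
    undefined."""


class NumericalFailureError(MutascanError):
    """An iterative numerical routine failed to converge."""


class PhasingRequiredError(MutascanError):
    """Input genotypes must be phased for haplotype-level counting."""


class PairingError(MutascanError):
    """Haplotypes cannot be paired into diploid samples."""


class InsufficientHaplotypesError(MutascanError):
    """Too few haplotypes for the requested summary statistic."""


class SingularFitError(MutascanError):
    """The regression design is degenerate (e.g. all predictor values equal)."""


class NoHDClassError(MutascanError):
    """No separable class of highly derived haplotypes exists in the counts."""


class TestNotApplicableError(MutascanError):
    """An association test cannot be performed (e.g. too few carriers)."""
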