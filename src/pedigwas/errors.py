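"""Exception hierarchy shared across the package."""


class PedigwasError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PedigwasError):
    """Invalid configuration value or combination."""


class PedigreeStructureError(PedigwasError):
    """Cyclic parent links, half-specified parents, or similar defects."""


class UnknownIndividualError(PedigwasError, KeyError):
    """An individual id was requested that is not in the pedigree."""


class MendelianInconsistencyError(PedigwasError):
    """Observed genotypes are impossible under Mendelian transmission.

    ``trio`` names (child, father, mother) when a violating trio could be
    localized, otherwise ``None``.
    """

    def __init__(self, message: str, trio: tuple | None = None):
        super().__init__(message)
        self.trio = trio


class DegenerateInputError(PedigwasError):
    """Input with no usable variation (e.g. all values identical)."""
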