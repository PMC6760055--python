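"""Exception hierarchy shared across the pipeline stages."""


class NtsQbdError(Exception):
    """Base class for all package errors."""


class DomainError(NtsQbdError, ValueError):
    """An input violates a physical or contractual invariant."""


class RangeError(DomainError):
    """A factor level lies outside its investigated range."""


class SingularModelError(NtsQbdError):
    """The design matrix for a requested term set is rank deficient."""

    def __init__(self, terms, rank, needed):
        self.terms = list(terms)
        super().__init__(
            f"rank-deficient design matrix (rank {rank} < {needed}) "
            f"for terms {self.terms}"
        )


class ConfigError(NtsQbdError, ValueError):
    """A pipeline or generator configuration is inconsistent."""


class CorruptFixtureError(NtsQbdError):
    """A bundled data table failed its checksum verification."""
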