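"""Exception hierarchy shared across the package."""


class MwsipError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MwsipError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class InvalidDesignError(MwsipError, ValueError):
    """A simulation or analysis design is internally inconsistent."""


class FormatError(MwsipError, ValueError):
    """An input file violates the expected on-disk format."""


class AnalysisError(MwsipError, RuntimeError):
    """An analysis stage cannot produce a result from its inputs."""
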