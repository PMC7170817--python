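"""Exception hierarchy shared across the package."""


class AbctransError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(AbctransError):
    """An input file violated the expected dialect.

    ``line`` is the 1-based line number in the offending file (header = line 1)
    when it could be determined.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class UndefinedFrequencyError(AbctransError):
    """A frequency was requested where every allele number is zero."""


class ModeOfInheritanceError(AbctransError):
    """Recessive-prevalence arithmetic requested for a non-AR gene."""


class MonomorphicLocusError(AbctransError):
    """Two-locus LD requested where one locus carries a single allele."""
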