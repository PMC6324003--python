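"""Exception hierarchy shared across the package."""


class SiftsForgeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SiftsForgeError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(SiftsForgeError):
    """A file could not be parsed under the requested dialect."""


class ConsistencyError(SiftsForgeError):
    """Internally inconsistent data (e.g. ATOM residues disagreeing with SEQRES)."""


class MissingAccessionError(SiftsForgeError, KeyError):
    """An accession could not be resolved in the sequence collection."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""
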