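"""Exception hierarchy for table validation, degenerate networks and undefined indices."""


class MycorrnetError(Exception):
    """Base class for all package errors."""


class FormatError(MycorrnetError):
    """A file could not be parsed into the expected tabular schema."""


class ValidationError(MycorrnetError):
    """A parsed table violates a type invariant (names the offending cell/row)."""


class DegenerateMatrixError(MycorrnetError):
    """A species-level matrix is too small for network indices (<2 plants or <2 OTUs)."""


class UndefinedIndexError(MycorrnetError):
    """An index is mathematically undefined for this input (e.g. zero null spread)."""


class EnsembleError(MycorrnetError):
    """A null-model ensemble failed to produce enough usable randomizations."""
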