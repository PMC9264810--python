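"""Exception hierarchy for sersdisc.

Every error raised on bad data names the offending sample, wavenumber or
stage so that failures on real spectral tables are diagnosable.
"""


class SersdiscError(Exception):
    """Base class for all package errors."""


class SpectraParseError(SersdiscError):
    """A spectral table or sidecar could not be parsed or validated."""


class DegenerateSpectrumError(SersdiscError):
    """A spectrum is unusable for the requested transform (zero sd, zero area)."""


class GridRangeError(SersdiscError):
    """A target grid extends beyond a spectrum's native wavenumber range."""


class BandError(SersdiscError):
    """A band restriction selected no grid columns, or the band spec is invalid."""


class RankError(SersdiscError):
    """Requested more components than the data's numerical rank supports."""


class SingularScatterError(SersdiscError):
    """Within-class scatter is singular and no regularization was supplied."""


class ConvergenceError(SersdiscError):
    """An iterative solver exhausted its iteration cap without converging."""


class FoldError(SersdiscError):
    """A cross-validation fold lost an entire class."""


class ReportError(SersdiscError):
    """An evaluation report is empty or inconsistent."""
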