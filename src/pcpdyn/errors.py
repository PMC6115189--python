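"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration problems -> 2,
data/validation problems -> 3, numerical failures -> 4.
"""


class PcpdynError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PcpdynError):
    """Invalid or infeasible configuration (bad parameter, impossible schedule)."""


class DataValidationError(PcpdynError):
    """Malformed or inconsistent input data (meshes, traces, tables)."""


class DegenerateGeometryError(DataValidationError):
    """Geometric input with no defined answer (coincident points, zero-area polygon)."""


class MeasurementError(PcpdynError):
    """An image measurement is undefined (empty mask, fully trimmed polyline)."""


class FitError(PcpdynError):
    """A model fit failed to converge; carries diagnostics in ``args``."""
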