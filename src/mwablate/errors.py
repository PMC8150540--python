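"""Exception hierarchy.

The CLI maps these onto distinct exit codes: configuration problems (2),
numerical failures (3), I/O failures (4).
"""


class MwablateError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MwablateError):
    """Invalid configuration or construction arguments."""


class ContractError(MwablateError):
    """Objects passed together do not share grid/frequency/shape contracts."""


class GeometryError(MwablateError):
    """Geometric impossibility, e.g. a grid node colliding with a source."""


class FrequencyRangeError(MwablateError):
    """Evaluation requested outside a material's tabulated validity range."""


class CalibrationError(MwablateError):
    """Noise calibration requested on a signal with zero power."""


class RankError(MwablateError):
    """Truncation index exceeds the numerical rank of the kernel."""
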