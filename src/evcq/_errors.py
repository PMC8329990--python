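"""Exception hierarchy."""


class EvcqError(Exception):
    """Base class for all evcq errors."""


class ConfigError(EvcqError, ValueError):
    """Invalid configuration or parameter value."""


class SimulationError(EvcqError, RuntimeError):
    """Synthetic-data generation failed (e.g. field overcrowded)."""


class CalibrationError(EvcqError, RuntimeError):
    """A calibration could not be established (e.g. underpowered)."""
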