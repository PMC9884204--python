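"""Exception hierarchy. Every stage raises a subclass of :class:`PeriopError`."""


class PeriopError(Exception):
    """Base class for all package errors."""


class InputError(PeriopError):
    """Invalid argument or malformed input data."""


class ConfigError(PeriopError):
    """Invalid analysis configuration."""


class SimulationError(PeriopError):
    """Physical model became degenerate during synthesis."""


class SessionError(PeriopError):
    """Session-level problem (empty overlap, no ventilation activity...)."""


class AnalysisError(PeriopError):
    """Breath extraction or statistics could not proceed."""


class FilterDesignError(PeriopError):
    """Requested filter specification cannot be met."""
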