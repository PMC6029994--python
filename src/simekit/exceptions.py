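"""Exception hierarchy used across simekit."""


class SimekitError(Exception):
    """Base class for all simekit errors."""


class InvalidParameterError(SimekitError, ValueError):
    """A model parameter set violates its invariants."""


class ScheduleError(SimekitError, ValueError):
    """A frame schedule is malformed (overlaps, gaps, nonpositive durations)."""


class DegenerateFitError(SimekitError, RuntimeError):
    """The data cannot identify the requested parameters (e.g. constant input)."""


class UndefinedMetricError(SimekitError, ZeroDivisionError):
    """A derived quantity is undefined for the given inputs."""
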