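"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter set violates a precondition (bands, rates, Nyquist...)."""


class ResolutionError(ValueError):
    """The output sampling rate cannot represent the pulse phase width."""


class SchedulingError(ValueError):
    """A pulse-timing parameter combination produces overlapping pulses."""


class SweepNotFoundError(RuntimeError):
    """A swept search range does not bracket the sought transition."""
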