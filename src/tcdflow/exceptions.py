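"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


class DegenerateWaveformError(ValueError):
    """Raised when a waveform is constant (no pulsatile range to normalize)."""
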