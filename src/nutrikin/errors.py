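"""Exception hierarchy.

All physically meaningful failure modes get their own class so that callers
(and the CLI exit-code mapping) can distinguish a bad configuration from a
cell that simply cannot transport fast enough.
"""


class NutrikinError(ValueError):
    """Base class for all package errors."""


class ConfigError(NutrikinError):
    """A configuration file or parameter set failed validation."""


class InfeasibleConfigError(NutrikinError):
    """The transporter rate density needed to sustain G_max exceeds the
    physical ceiling TRD_max: this organism cannot grow at G_max."""


class SaturationError(NutrikinError):
    """Demanded transport meets or exceeds the instantaneous maximum
    transport capacity; no finite substrate concentration can supply it."""


class FitError(NutrikinError):
    """A nonlinear fit failed to converge."""
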