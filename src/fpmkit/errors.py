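"""Exception hierarchy shared by all fpmkit modules."""


class FPMError(Exception):
    """Base class for all fpmkit errors."""


class ConfigError(FPMError):
    """A configuration value violates a type invariant, or an unknown key was given."""


class GeometryError(FPMError):
    """Illumination or frequency-plane geometry is physically inconsistent
    (LED beyond grazing incidence, pupil window outside the spectrum extent, ...)."""


class InputError(FPMError):
    """Operation inputs are malformed or mutually inconsistent."""


class FormatError(FPMError):
    """A file on disk does not match the documented layout."""


class CapabilityError(FPMError):
    """A requested feature needs an optional dependency that is not installed."""


class TrainingDivergedError(FPMError):
    """Training loss became non-finite; carries the last finite-loss parameters."""

    def __init__(self, message, checkpoint=None, history=None):
        super().__init__(message)
        self.checkpoint = checkpoint
        self.history = history
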