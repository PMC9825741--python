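"""Exception hierarchy used across the package."""


class TumorsimError(Exception):
    """Base class for all package errors."""


class InputError(TumorsimError):
    """A user-supplied file is missing, malformed or inconsistent."""


class ValidationError(TumorsimError):
    """A parsed profile or plan violates its contract."""


class ModelError(TumorsimError):
    """A reference model is empty, corrupt or of an unsupported version."""


class GenerationError(TumorsimError):
    """Read generation cannot proceed (e.g. all sampling weights are zero)."""
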