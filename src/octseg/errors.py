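"""Exception hierarchy.

All package errors derive from :class:`OctsegError` so callers can catch one
base type; the subclasses distinguish bad inputs, malformed files, invalid
configuration and algorithmic (detection) failures.
"""


class OctsegError(Exception):
    """Base class for all errors raised by octseg."""


class InputError(OctsegError, ValueError):
    """An in-memory argument violates a precondition."""


class FormatError(OctsegError, ValueError):
    """A file on disk is malformed or inconsistent."""


class ConfigurationError(OctsegError, ValueError):
    """Missing or invalid configuration (resolutions, phantom spec, ...)."""


class DetectionError(OctsegError, RuntimeError):
    """A boundary could not be detected or violated an ordering constraint.

    Carries enough context (boundary label, frame index) to locate the
    failure; ordering violations are never silently clamped.
    """

    def __init__(self, message: str, *, boundary: str | None = None,
                 frame: int | None = None):
        ctx = []
        if boundary is not None:
            ctx.append(f"boundary={boundary}")
        if frame is not None:
            ctx.append(f"frame={frame}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.boundary = boundary
        self.frame = frame
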