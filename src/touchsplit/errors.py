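"""Typed errors and control-flow signals shared across the package."""


class TouchsplitError(Exception):
    """Base class; carries a stable machine-readable code."""

    code = "ERROR"

    def __init__(self, message: str = "", **details):
        super().__init__(message or self.code)
        self.details = details


class EmptyMaskError(TouchsplitError):
    code = "EMPTY_MASK"


class MultiComponentError(TouchsplitError):
    code = "MULTI_COMPONENT"


class BadCutError(TouchsplitError):
    code = "BAD_CUT"


class DegenerateShapeError(TouchsplitError):
    code = "DEGENERATE_SHAPE"


class DegenerateHullError(TouchsplitError):
    code = "DEGENERATE_HULL"


class NoValidCutError(TouchsplitError):
    code = "NO_VALID_CUT"


class UnseparableError(TouchsplitError):
    code = "UNSEPARABLE"


class Fallback(Exception):
    """Control-flow signal: the box-based stage declines and the caller
    must route the blob to the shape-analysis stage.  Not an error."""

    def __init__(self, reason: str = ""):
        super().__init__(reason)
        self.reason = reason
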