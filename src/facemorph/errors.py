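"""Exception hierarchy shared across the pipeline."""


class FacemorphError(Exception):
    """Base class for all package errors."""


class SchemaError(FacemorphError):
    """A landmark name outside the canonical vocabulary."""


class DuplicateLandmarkError(SchemaError):
    """The same landmark name appears more than once in one file."""


class LandmarkParseError(FacemorphError):
    """A landmark file could not be parsed; the message names the offending line."""


class MissingLandmarkError(FacemorphError):
    """An operation's required landmark is absent from the set."""

    def __init__(self, *names: str):
        self.names = tuple(names)
        super().__init__(f"missing landmark(s): {', '.join(names)}")


class MissingFieldError(FacemorphError):
    """A measurement field required by a ratio is missing."""


class DegenerateGeometryError(FacemorphError):
    """Coincident or zero-length landmark geometry where a direction is needed."""


class GenerationError(FacemorphError):
    """The synthetic generator could not produce a feasible face."""
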