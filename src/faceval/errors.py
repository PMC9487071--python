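"""Exception hierarchy shared across the toolkit."""


class FacevalError(Exception):
    """Base class for all faceval errors."""


class ValidationError(FacevalError):
    """Input violates a documented invariant or precondition."""


class ParseError(FacevalError):
    """A file could not be parsed; message names the offending line."""


class VocabularyError(ValidationError):
    """A landmark name is outside the controlled vocabulary."""


class MissingLandmarkError(ValidationError):
    """A required landmark is absent; ``names`` lists the missing ones."""

    def __init__(self, names):
        self.names = tuple(names)
        super().__init__(f"missing landmark(s): {', '.join(self.names)}")


class DegenerateGeometryError(ValidationError):
    """Point configuration too degenerate for the requested operation."""


class NoOverlapError(FacevalError):
    """All ICP correspondences were rejected; ``iteration`` records where."""

    def __init__(self, iteration):
        self.iteration = iteration
        super().__init__(
            f"all correspondences rejected at ICP iteration {iteration}"
        )


class InfeasibleError(ValidationError):
    """A geometric equation has no solution for the given inputs."""
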