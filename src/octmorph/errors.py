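"""Exception hierarchy for octmorph.

All package-specific failures derive from :class:`OctMorphError` so callers can
catch one base class; the leaf classes mirror the distinct failure modes of the
pipeline (bad arguments, unreadable files, profiles too short for a cubic fit,
no detectable tissue surface, phantom object placement failure).
"""


class OctMorphError(Exception):
    """Base class for all octmorph errors."""


class InvalidArgumentError(OctMorphError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(OctMorphError, ValueError):
    """A file exists but cannot be interpreted in the stated format."""


class InsufficientProfileError(OctMorphError):
    """A surface profile has fewer than 4 distinct lateral positions.

    Four distinct x values are the minimum for the third-degree polynomial
    baseline, so shorter profiles cannot enter the NSL computation.
    """


class NoSurfaceFoundError(OctMorphError):
    """No lateral column of a B-scan contains a valid threshold crossing."""


class PlacementError(OctMorphError):
    """A phantom object could not be placed without overlap.

    The message names the offending object class (outgrowth, detached,
    chamber) so cohort drivers can report which scene element failed.
    """

    def __init__(self, object_class: str, message: str | None = None):
        self.object_class = object_class
        super().__init__(
            message or f"could not place {object_class!r} object without overlap"
        )
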