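"""Exception hierarchy for the mvquant pipeline.

Every error raised by the package derives from :class:`MVQuantError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors with a single ``except`` clause.
"""


class MVQuantError(Exception):
    """Base class for all mvquant errors."""


class ImageIOError(MVQuantError):
    """A raster file could not be read or written."""


class FormatError(MVQuantError):
    """A file was readable but its contents violate the expected format
    (unsupported bit depth, malformed annotation JSON, incompatible model)."""


class ParameterError(MVQuantError):
    """A parameter is out of its documented range (e.g. inverted gray bounds,
    ``n_trees < 1``)."""


class DegenerateInputError(MVQuantError):
    """The input is too small or too uniform for the requested operation
    (e.g. image smaller than the largest feature window)."""


class EmptySelectionError(MVQuantError):
    """An ellipse annotation selects no pixels because it lies entirely
    outside the image bounds."""


class IncompleteTrainingSetError(MVQuantError):
    """A class required for training has no labelled pixels."""

    def __init__(self, missing_classes):
        self.missing_classes = tuple(sorted(missing_classes))
        super().__init__(
            "training set is missing samples for class(es): "
            + ", ".join(str(c) for c in self.missing_classes)
        )


class LeakageError(MVQuantError):
    """Train and evaluation pixel sets overlap; performance on the shared
    pixels would not measure generalisation."""


class UndefinedROCError(MVQuantError):
    """ROC analysis requested on labels containing a single class."""


class DegenerateRegressionError(MVQuantError):
    """Agreement regression requested with too few points or a constant
    predictor."""


class PlacementError(MVQuantError):
    """The synthetic generator could not place the requested structures or
    annotations without violating the overlap/purity constraints."""
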