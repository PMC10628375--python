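"""Exception types shared across the package."""


class GridQuantError(Exception):
    """Base class for all gridquant errors."""


class InvalidParameterError(GridQuantError, ValueError):
    """A parameter is outside its admissible range."""


class DetectionError(GridQuantError):
    """Field-of-view circle detection failed and no manual override was given."""


class UndefinedRatioError(GridQuantError, ZeroDivisionError):
    """A ratio's denominator is zero (no assessable squares of the required kind)."""


class ShapeMismatchError(GridQuantError, ValueError):
    """An array or label matrix does not match the expected shape."""


class InputFormatError(GridQuantError, ValueError):
    """A CSV/JSON input file is malformed; message carries the offending row."""
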