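"""Exception hierarchy for glufield."""


class GlufieldError(ValueError):
    """Base class for all glufield errors."""


class FormatError(GlufieldError):
    """A file or table does not match the expected dialect/columns."""


class EmptyInputError(GlufieldError):
    """An operation that requires data received none."""


class InvalidRoiError(GlufieldError):
    """ROI polygon is degenerate, self-intersecting or has too few vertices."""


class ParameterError(GlufieldError):
    """A numeric parameter is outside its valid range."""


class SelectionError(GlufieldError):
    """An automatic parameter-selection rule found no admissible value."""
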