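"""Exception hierarchy shared across the package."""


class ColumnMorphError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ColumnMorphError):
    """A landmark or metadata file could not be parsed.

    Carries the offending file and (1-based) line number when known.
    """

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class DimensionError(ColumnMorphError):
    """Landmark count or array shape does not match what a region expects."""


class ConfigurationError(ColumnMorphError):
    """Invalid or incomplete configuration / metadata (e.g. missing Tdiaph)."""


class VocabularyError(ColumnMorphError):
    """An ecological category outside the supported vocabulary."""


class DegenerateShapeError(ColumnMorphError):
    """A landmark configuration with zero centroid size (all points coincide)."""


class DesignError(ColumnMorphError):
    """An ANOVA design that cannot be fitted (e.g. single-level factor)."""


class AlignmentError(ColumnMorphError):
    """Series or datasets that should share an index do not line up."""


class TreeError(ColumnMorphError):
    """Phylogeny problems: unmatched tips, zero-length branches, bad Newick."""
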