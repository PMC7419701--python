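"""Exception hierarchy for the language-network mapping pipeline.

Every stage raises a subclass of :class:`LangmapError` so callers (and the CLI)
can distinguish configuration, data, and numerical failures.
"""


class LangmapError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(LangmapError, ValueError):
    """A scalar parameter is outside its valid range (e.g. negative FWHM)."""


class ConfigurationError(LangmapError, ValueError):
    """A structured configuration is inconsistent (schema, layer accounting...)."""


class CapacityError(LangmapError, ValueError):
    """Requested parcels cannot be packed into the phantom grid."""


class InsufficientDataError(LangmapError, ValueError):
    """Too few frames (or voxels) for the requested operation."""


class MaskError(LangmapError, ValueError):
    """Empty or inconsistent brain mask."""


class SingularityError(LangmapError, ValueError):
    """Rank-deficient regression design; message names collinear columns."""


class DegenerateSeedError(LangmapError, ValueError):
    """Seed time series has zero variance: correlation undefined."""


class CoverageError(LangmapError, ValueError):
    """A parcel or inference stream does not cover the required voxels."""


class DesignError(LangmapError, ValueError):
    """Task block design inconsistent with the acquisition protocol."""


class RoiLookupError(LangmapError, KeyError):
    """Reference to a parcel id absent from the atlas."""


class LabelDegeneracyError(LangmapError, ValueError):
    """Training set contains fewer than two classes."""


class InsufficientClusterError(LangmapError, ValueError):
    """Fewer than two supra-threshold clusters in a meta-analytic map."""


class DegeneracyError(LangmapError, ValueError):
    """ROC truth contains a single class inside the evaluation mask."""


class ComparisonError(LangmapError, ValueError):
    """ROC results computed against different truth definitions."""


class ShapeError(LangmapError, ValueError):
    """Volumes on mismatched grids."""


class CohortParseError(LangmapError, ValueError):
    """Malformed cohort table row; message names the offending line."""
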