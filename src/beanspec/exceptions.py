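"""Exception hierarchy for beanspec.

All package-specific failures derive from :class:`BeanspecError` so callers can
catch everything with one clause; most also derive from the matching builtin
(ValueError / KeyError) so generic handling keeps working.
"""


class BeanspecError(Exception):
    """Base class for all beanspec errors."""


class ConfigurationError(BeanspecError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(BeanspecError, ValueError):
    """Malformed or inconsistent ENVI header/payload."""


class CalibrationError(BeanspecError, ValueError):
    """Dark/white reference frames unusable for reflectance calibration."""


class LayoutError(BeanspecError, ValueError):
    """Bean layout does not fit the scene or overlaps."""


class AlignmentError(BeanspecError, ValueError):
    """Spectra on incompatible wavelength grids or modes."""


class DegenerateInputError(BeanspecError, ValueError):
    """Input that is formally valid but information-free (all-zero, constant)."""


class RosterError(BeanspecError, ValueError):
    """Compound roster fails schema validation or a profile names an unknown compound."""
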