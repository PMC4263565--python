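"""Exception hierarchy for lfaquant.

Everything raised on bad scientific input derives from :class:`LfaError`
so callers (and the CLI) can catch one base class.
"""


class LfaError(Exception):
    """Base class for all lfaquant errors."""


class DomainError(LfaError, ValueError):
    """A physical quantity is outside its admissible domain (e.g. c < 0)."""


class GeometryError(LfaError, ValueError):
    """A zone, ROI or flank window does not fit inside the image."""


class ConfigError(LfaError, ValueError):
    """Invalid configuration: unknown mode, missing metadata, bad channel count."""


class DetectionError(LfaError, RuntimeError):
    """Zone detection found no component and no fallback ROI was configured."""


class FitError(LfaError, RuntimeError):
    """A regression could not be performed (degenerate or insufficient data)."""


class UndefinedRatioError(FitError):
    """The S/NSB ratio is undefined because the NSB slope is not positive."""
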