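"""Exception hierarchy for cvrkit.

All pipeline errors derive from :class:`CvrkitError` so callers (and the CLI)
can catch one base class and report the failing stage.
"""


class CvrkitError(Exception):
    """Base class for all cvrkit errors."""


class FormatError(CvrkitError):
    """Malformed or unsupported input file / in-memory container."""


class CapnogramError(CvrkitError):
    """CO2 trace cannot be converted into a usable EtCO2 curve."""


class AlignmentError(CvrkitError):
    """EtCO2-to-BOLD temporal alignment cannot be performed."""


class MaskError(CvrkitError):
    """Brain-mask computation failed or produced a degenerate mask."""


class ModelError(CvrkitError):
    """A regression/quantification step received degenerate inputs."""
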