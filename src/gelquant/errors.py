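"""Exception hierarchy.

Every contract violation raises a named subclass of :class:`GelQuantError`
so callers (and the CLI) can distinguish validation failures from I/O
failures.  Plain ``OSError``/``FileNotFoundError`` are left to propagate for
genuinely missing or unwritable paths.
"""


class GelQuantError(ValueError):
    """Base class for all contract violations raised by gelquant."""


class DegenerateImageError(GelQuantError):
    """Image smaller than the 16x16 minimum, or otherwise unusable."""


class UnsupportedImageError(GelQuantError):
    """Image file with a bit depth or layout the tool does not accept."""


class LadderSpecError(GelQuantError):
    """Ladder size table malformed: too few, non-positive or duplicate sizes."""


class BandTableError(GelQuantError):
    """Band CSV malformed or fields violate Band invariants."""


class PedigreeError(GelQuantError):
    """Pedigree CSV malformed, or a record fails its range invariants."""


class ProfileError(GelQuantError):
    """Intensity profile malformed, or an invalid window/range requested."""


class DetectionError(GelQuantError):
    """Lane or band detection could not satisfy its contract."""


class CalibrationError(GelQuantError):
    """Ladder calibration failed, or a position is outside its domain."""


class QuantError(GelQuantError):
    """Per-lane statistics requested on inputs violating their contract."""


class EditError(GelQuantError):
    """Manual band edit that matches nothing or collides with an existing band."""


class SimulationError(GelQuantError):
    """Synthetic gel specification violates its invariants."""


class ConfigError(GelQuantError):
    """Unknown or invalid configuration key/value."""
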