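"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`ScreenError` so the CLI can abort
with the stage name and the offending unit (plate / well / field).
"""


class ScreenError(Exception):
    """Base class for all pipeline errors."""


class ImageFormatError(ScreenError):
    """Raster violates the 16-bit single-channel grayscale contract."""


class PlateMapError(ScreenError):
    """Malformed plate-map CSV or invalid well identifier."""


class DegenerateInputError(ScreenError):
    """Input carries no usable signal (e.g. constant intensity sample)."""


class PlacementError(ScreenError):
    """Synthetic objects could not be placed under the stated constraints."""


class ConsistencyError(ScreenError):
    """Cross-referenced objects disagree (e.g. punctum owner missing)."""


class DesignError(ScreenError):
    """Invalid screen design request (compound count, replicate count...)."""


class StatsError(ScreenError):
    """Invalid input to a statistical routine."""
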