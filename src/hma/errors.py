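"""Exception hierarchy for the HMA pipeline.

Every stage raises a subclass of :class:`HmaError` so the CLI can map
failures onto its documented exit codes (2 = configuration, 3 = I/O).
"""


class HmaError(Exception):
    """Base class for all pipeline errors."""


class FormatError(HmaError):
    """A file exists but is not a raster the pipeline can read."""


class CapacityError(HmaError):
    """A label map exceeds the 16-bit on-disk label capacity (65535)."""


class ParameterError(HmaError):
    """An operation received parameters outside its documented domain."""


class ConfigError(HmaError):
    """A run configuration or strategy/layer specification is invalid."""


class StrategyParseError(ConfigError):
    """A combination-strategy expression violates the grammar."""


class PlacementError(HmaError):
    """The synthetic generator could not place all cells after bounded retries."""


class DegenerateRegionError(HmaError):
    """A region has too few distinct intensities for the requested thresholds."""


class TrainingError(HmaError):
    """The patch-filter training set is unusable (e.g. single class)."""
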