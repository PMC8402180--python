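"""Exception hierarchy.

All domain errors derive from :class:`VitisimError` so callers (and the CLI)
can distinguish bad input from internal failures.
"""


class VitisimError(ValueError):
    """Base class for all input/domain errors raised by this package."""


class PolarLatitudeError(VitisimError):
    """Latitude outside the band where every day has a sunrise and sunset."""


class CoverageError(VitisimError):
    """Weather and canopy series do not cover the same simulation days."""
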