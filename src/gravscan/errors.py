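"""Exception and warning types used across gravscan."""


class GravscanError(Exception):
    """Base class for all gravscan errors."""


class FormatError(GravscanError):
    """A file could not be parsed into the expected structure."""


class MetricError(GravscanError):
    """A scanpath metric is undefined for the given inputs."""


class NumericalError(GravscanError):
    """A numerical procedure diverged or produced non-finite values."""


class GravscanWarning(UserWarning):
    """Base class for gravscan warnings (clamped coordinates, truncation...)."""
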