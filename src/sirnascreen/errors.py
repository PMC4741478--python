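"""Exception hierarchy for screen-analysis failures."""


class ScreenError(Exception):
    """Base class for all errors raised by this package."""


class PlateMapError(ScreenError):
    """Malformed or inconsistent plate map / library annotation."""


class MeasurementError(ScreenError):
    """Malformed measurement table (bad FI, duplicates, orphan wells)."""


class NormalizationError(ScreenError):
    """Plate-level normalization failure (unusable NT controls)."""


class DegenerateDistributionError(ScreenError):
    """A distribution statistic is undefined (zero spread)."""


class FitError(ScreenError):
    """Dose-response curve fit failed or is undefined."""


class SimulationError(ScreenError):
    """Invalid synthetic-screen configuration or request."""
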