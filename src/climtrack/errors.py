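"""Exception hierarchy for the climtrack pipeline.

Every error raised by the package derives from :class:`ClimtrackError`,
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class ClimtrackError(Exception):
    """Base class for all climtrack errors."""


class ValidationError(ClimtrackError, ValueError):
    """An input value violates a documented precondition."""


class SchemaError(ClimtrackError):
    """A tabular or vector input is missing a required column/attribute."""


class ConflictError(ClimtrackError):
    """Duplicate rows describe the same (plot, era, species) observation."""


class RegistryError(ClimtrackError, KeyError):
    """A species code is not present in the active species registry."""


class EmptyInputError(ClimtrackError):
    """An operation received an empty collection where data are required."""


class FormatError(ClimtrackError):
    """A raster or vector file could not be parsed."""


class UnsupportedFormatError(FormatError):
    """The file parsed but uses features outside the supported profile."""


class EmptyOverlapError(ClimtrackError):
    """A range polygon includes no raster cell centers."""

    def __init__(self, species: str, message: str | None = None):
        self.species = species
        super().__init__(message or f"range polygon for {species!r} overlaps no raster cells")


class RankDeficiencyError(ClimtrackError):
    """A model factor has a single observed level, so the design is singular."""

    def __init__(self, factor: str):
        self.factor = factor
        super().__init__(f"factor {factor!r} has a single observed level; design matrix is rank deficient")


class JoinError(ClimtrackError):
    """A species is missing one of the pieces needed to assemble the change table."""


class DegenerateDesignError(ClimtrackError):
    """Regression predictor is constant."""


class InsufficientDataError(ClimtrackError):
    """Too few observations to fit the requested model."""


class ScenarioError(ClimtrackError, ValueError):
    """A simulation scenario is internally inconsistent."""


class ConfigError(ClimtrackError):
    """A run configuration value is invalid."""
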