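"""Exception hierarchy for the SRH pipeline.

Two broad classes matter for the CLI exit codes: configuration/parameter
problems (exit code 2) and data/geometry problems (exit code 3).
"""


class SRHError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(SRHError):
    """A parameter, configuration value or registry key is invalid."""


class ParameterError(ValidationError):
    """A numeric parameter is out of its documented range."""


class ConfigError(ValidationError):
    """The pipeline configuration is malformed (unknown key, bad block)."""


class RegistryError(ValidationError):
    """Unknown LUT family or shade variant."""


class DataError(SRHError):
    """Input data violates a structural precondition."""


class GeometryError(DataError):
    """Raster shapes are inconsistent or too small."""


class SizingError(DataError):
    """Phantom field / pixel size do not yield a usable raster."""


class PackingError(DataError):
    """Rejection sampling could not place the requested crypt count."""


class SamplingError(DataError):
    """Time-series sampling is not commensurate with the modulation period."""


class CalibrationError(DataError):
    """Power-calibration reference values are unusable."""


class CompletenessError(DataError):
    """A tile grid is missing tiles."""


class SchemaError(DataError):
    """On-disk tile data does not match the expected schema."""


class ProvenanceWarning(UserWarning):
    """Thresholds do not appear to derive from the images being composited."""
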