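"""Domain-specific exceptions shared across modules."""


class ConfigError(ValueError):
    """Invalid cohort/acquisition/run configuration."""


class SchemaError(ConfigError):
    """Configuration file contains unknown or malformed keys."""


class GeometryError(ValueError):
    """Phantom geometry is inconsistent (compartments do not nest)."""


class LesionTooSmallError(ValueError):
    """Too few eligible lesion pixels to place an ROI."""


class PlacementError(ValueError):
    """No valid parenchyma ROI placement exists."""


class UndefinedContrastError(ZeroDivisionError):
    """Lesion-to-liver contrast is undefined because SI_liver is zero."""


class CompletenessError(ValueError):
    """A lesion is missing one or more acquisition conditions."""


class FormatError(ValueError):
    """On-disk artifacts are inconsistent (e.g. sidecar/series mismatch)."""
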