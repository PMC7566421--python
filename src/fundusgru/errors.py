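"""Exception types shared across the package."""


class FundusGruError(Exception):
    """Base class for package errors."""


class ConfigError(FundusGruError):
    """A configuration value is invalid; the message names the field."""


class BlankImageError(FundusGruError):
    """No pixel differs from the background by more than the offset."""


class SchemaError(FundusGruError):
    """A manifest/table is malformed (missing columns, unordered times)."""


class EmptyCohortError(FundusGruError):
    """A cohort operation received zero patients/eyes."""


class UndefinedMetricError(FundusGruError):
    """A metric is undefined for the given labels (e.g. single-class AUC)."""
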