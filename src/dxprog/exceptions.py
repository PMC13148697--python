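"""Exception hierarchy used across the package."""


class DxprogError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DxprogError):
    """Invalid configuration value or inconsistent strategy/init pairing."""


class GenerationError(DxprogError):
    """Cohort generation failed (e.g. empty prognosis cohort after exclusions)."""


class SplitError(DxprogError):
    """Cross-validation split could not be constructed."""


class UndefinedMetricError(DxprogError):
    """A metric is undefined for the given inputs (e.g. single-class labels)."""


class LeakageError(DxprogError):
    """Patient-level disjointness was violated somewhere in the pipeline."""
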