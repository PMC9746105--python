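"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid run or cohort configuration."""


class DomainError(ValueError):
    """Inputs outside the mathematical or covariate domain of a model."""


class InputError(ValueError):
    """Malformed input files or mismatched tables."""


class FitError(RuntimeError):
    """Model fitting failed for every candidate specification."""
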