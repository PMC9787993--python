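"""Exception hierarchy for the prsdelta pipeline."""


class PrsDeltaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PrsDeltaError, ValueError):
    """Invalid configuration; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid config field '{field}': {message}")


class VcfParseError(PrsDeltaError):
    """A VCF file could not be read or a record was malformed."""


class MissingVariantError(PrsDeltaError):
    """A variant has no usable calls (e.g. fully missing at imputation)."""


class DegenerateScoreError(PrsDeltaError):
    """A score vector has zero variance or too few observations."""


class NoScoringSnpsError(PrsDeltaError):
    """No weight-table SNP matched the genotype matrix."""


class CollinearityError(PrsDeltaError):
    """The regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )
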