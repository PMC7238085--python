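"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """An invalid parameter value; the message names the offending field."""


class SchemaError(ValueError):
    """A malformed input table (unknown/missing column, bad row value)."""


class UnknownServiceError(KeyError):
    """Resource use names a service type with no unit price."""

    def __init__(self, missing_keys):
        self.missing_keys = sorted(missing_keys)
        super().__init__(
            "no unit price for service type(s): " + ", ".join(self.missing_keys)
        )


class DegenerateFitError(ValueError):
    """A regression system that cannot be estimated (rank deficiency,
    zero-variance outcome, or n smaller than the parameter count)."""


class UndefinedICERError(ZeroDivisionError):
    """ICER requested for a zero incremental effect."""


class UnattainedCertaintyError(ValueError):
    """The acceptability curve never reaches the requested certainty level
    on the supplied willingness-to-pay grid."""
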