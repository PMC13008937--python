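"""Exception hierarchy shared across the package."""


class MRMediationError(Exception):
    """Base class for all package errors."""


class FormatError(MRMediationError):
    """A summary-statistics file does not match the declared dialect."""


class EmptyInputError(MRMediationError):
    """An operation received (or produced) zero usable records."""


class ConfigError(MRMediationError):
    """A simulation or analysis configuration is invalid or infeasible."""


class HarmonizationError(MRMediationError):
    """Exposure and outcome share no usable instruments."""


class EstimationError(MRMediationError):
    """A causal-effect estimator cannot be computed on the given input."""


class InsufficientInstrumentsError(EstimationError):
    """Fewer instruments than the method-specific minimum."""


class PipelineError(MRMediationError):
    """A multi-stage analysis failed; the message names the failing stage."""
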