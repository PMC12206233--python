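"""Exception hierarchy for the NAT pipeline."""


class PipelineError(Exception):
    """Base class for all natpipe errors."""


class ConfigurationError(PipelineError, ValueError):
    """Invalid configuration values (counts, probabilities, spreads)."""


class AtlasError(PipelineError, ValueError):
    """Malformed ROI atlas (duplicate ROIs, overlapping subnetworks)."""


class DegenerateInputError(PipelineError, ValueError):
    """Numerically degenerate input, e.g. a zero-variance ROI series."""


class DomainError(PipelineError, ValueError):
    """Argument outside its mathematical domain (density, NAT fraction)."""


class ContractError(PipelineError, ValueError):
    """Caller violated an interface contract (wrong count, wrong graph type)."""


class NotConvergedError(PipelineError, RuntimeError):
    """Iterative estimation failed to converge."""
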