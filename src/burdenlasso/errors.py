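"""Exception hierarchy for the pipeline."""


class BurdenLassoError(Exception):
    """Base class for package errors."""


class ConfigurationError(BurdenLassoError):
    """Invalid configuration value or distribution specification."""


class AlignmentError(BurdenLassoError):
    """Individual identifiers do not line up across inputs."""


class ParseError(BurdenLassoError):
    """Malformed input record."""


class PipelineError(BurdenLassoError):
    """Failure inside an orchestrated stage, annotated with context."""

    def __init__(self, stage: str, message: str, **context):
        self.stage = stage
        self.context = context
        detail = ", ".join(f"{k}={v}" for k, v in context.items())
        super().__init__(f"[{stage}] {message}" + (f" ({detail})" if detail else ""))
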