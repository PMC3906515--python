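"""Exception hierarchy shared across the pipeline stages."""


class ColdJetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ColdJetError):
    """A configuration value is invalid; the message names the field."""


class FormatError(ColdJetError):
    """An input file does not conform to the declared tabular/OBO format."""


class InputError(ColdJetError):
    """Inputs are structurally incompatible (e.g. mismatched probe universes)."""


class StageError(ColdJetError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
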