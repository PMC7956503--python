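"""Exception hierarchy for the pipeline.

All pipeline-raised errors derive from :class:`UvepError` so callers can
catch everything the package raises with one clause; validation problems
(bad files, bad config) are distinguished from runtime stage failures
because the command-line layer maps them to different exit codes.
"""


class UvepError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(UvepError):
    """An input file does not match its declared schema."""


class ValidationError(UvepError):
    """Input data violates a contract (negative counts, duplicates...)."""


class ConfigError(UvepError):
    """Pipeline configuration is invalid (unknown key, out-of-range value)."""


class PipelineError(UvepError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
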