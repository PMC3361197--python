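"""Exception types shared across the pipeline.

Exit-code mapping in the CLI relies on this split: configuration problems
(bad parameter values, missing config entries) versus data problems
(malformed or inconsistent inputs).  Genuine computation failures raise
ordinary exceptions.
"""


class ConfigurationError(ValueError):
    """A parameter or configuration field is invalid; the message names it."""


class DataError(ValueError):
    """Input data are malformed or internally inconsistent."""
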