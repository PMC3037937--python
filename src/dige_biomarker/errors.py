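"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """An invalid parameter value; the message names the offending field."""


class FormatError(ValueError):
    """A malformed input file or table; the message locates the problem."""


class AnalysisError(RuntimeError):
    """A precondition of an analysis step is violated at run time."""
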