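"""Exception hierarchy shared across the pipeline.

Two broad failure classes map onto the CLI exit codes: problems with the
*data* being read (``InputError`` → exit 1) and problems with how the run
was *configured* (``ConfigError`` → exit 2).
"""


class ComplaintLensError(Exception):
    """Base class for all package errors."""


class InputError(ComplaintLensError):
    """Malformed or unusable input data (bad bytes, bad lines, empty input)."""


class ConfigError(ComplaintLensError):
    """Invalid configuration: unknown option, missing column, bad parameter."""


class NoStableClusteringError(ComplaintLensError):
    """The parameter search found no stable run of cluster counts.

    Carries the full (k, eps, pmin, n_clusters) trace so the caller can
    inspect why stability was never reached.
    """

    def __init__(self, message: str, trace):
        super().__init__(message)
        self.trace = trace
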