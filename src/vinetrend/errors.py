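"""Exception hierarchy shared across the pipeline.

Two broad classes matter to callers: problems with the data handed in
(:class:`InputError`) and problems with a configuration object or file
(:class:`ConfigurationError`).  The CLI maps them to exit codes 1 and 2.
"""


class VinetrendError(Exception):
    """Base class for all package-specific errors."""


class InputError(VinetrendError):
    """Raised when input data violates a precondition (bad shape, gaps, n too small)."""


class ConfigurationError(VinetrendError):
    """Raised when a configuration value is invalid; the message names the field."""


class GridImportError(InputError):
    """Raised when an external gridded file cannot be adapted to a ClimateGrid.

    Carries the full list of defects found so users can fix a file in one pass.
    """

    def __init__(self, defects):
        self.defects = list(defects)
        super().__init__("cannot import grid: " + "; ".join(self.defects))
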