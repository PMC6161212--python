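"""Exception hierarchy shared across meltflow modules."""


class MeltflowError(Exception):
    """Base class for all meltflow-specific errors."""


class SchemaError(MeltflowError):
    """A CSV input is missing required columns or a cell cannot be parsed."""


class FitError(MeltflowError):
    """A least-squares fit is under-determined or failed to converge."""


class OverlapError(MeltflowError):
    """Two frequency sweeps cannot be superposed (no usable overlap)."""


class OutOfRangeError(MeltflowError):
    """A requested value lies outside the attainable range of a model curve."""
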