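"""Exception hierarchy shared by all panscape modules."""


class PanscapeError(Exception):
    """Base class for all panscape errors."""


class FormatError(PanscapeError):
    """A file violated the expected on-disk format or validation rules."""


class ParameterError(PanscapeError):
    """A function was called with out-of-range or inconsistent parameters."""


class InputError(PanscapeError):
    """Input data (in-memory) violated a precondition of an analysis step."""
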