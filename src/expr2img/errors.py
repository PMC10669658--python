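"""Exception hierarchy for the pipeline."""


class Expr2ImgError(Exception):
    """Base class for all package errors."""


class ConfigError(Expr2ImgError, ValueError):
    """Invalid configuration values."""


class FormatError(Expr2ImgError, ValueError):
    """A file does not parse under the declared dialect."""


class LabelingError(Expr2ImgError, ValueError):
    """Sample labels are missing or unmappable."""


class EmptySelectionError(Expr2ImgError, RuntimeError):
    """LASSO selected no genes; advise a smaller lambda."""


class DegeneracyError(Expr2ImgError, ValueError):
    """Geometric input is degenerate (collinear / zero range)."""


class StageOrderError(Expr2ImgError, FileNotFoundError):
    """A CLI stage was invoked before its upstream artifact exists."""


class LeakageError(Expr2ImgError, RuntimeError):
    """A fitted artifact was exposed to held-out samples."""
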