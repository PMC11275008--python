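"""Exception hierarchy shared across the package."""


class PanelomicsError(ValueError):
    """Base class for all validation and computation errors raised here."""


class UnitError(PanelomicsError):
    """Concentration unit missing, unknown, or mixed without conversion."""


class UndefinedCorrelationError(PanelomicsError):
    """Correlation requested on fewer than 3 pairs or on a constant vector."""


class InsufficientDataError(PanelomicsError):
    """Not enough observations to carry out the requested computation."""


class FitError(PanelomicsError):
    """Nonlinear fit failed to converge; carries the best iterate if any."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
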