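"""Exception hierarchy shared across the package."""


class ChangescopeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ChangescopeError, ValueError):
    """A parameter is outside its admissible range."""


class DimensionError(ChangescopeError, ValueError):
    """Arrays that must share a geometry do not."""


class UndefinedContrastError(ChangescopeError):
    """Local contrast is undefined (windowed mean luminance is zero)."""


class NoChangeError(ChangescopeError):
    """Two images expected to differ are identical within tolerance."""


class DegenerateSplitError(ChangescopeError):
    """Median split impossible because all values coincide."""


class InfeasibleDesignError(ChangescopeError):
    """No covariate-balanced selection found within the iteration budget."""

    def __init__(self, message, best_report=None):
        super().__init__(message)
        self.best_report = best_report


class InfeasibleSubsetsError(ChangescopeError):
    """Subset layout unsatisfiable under the unique-source constraint."""


class DegenerateReportError(ChangescopeError):
    """Balance statistics undefined (empty or too-small condition cell)."""


class NoDataError(ChangescopeError):
    """An operation was handed an empty trial table."""


class UnbalancedDesignError(ChangescopeError):
    """A subject is missing trials in one or more conditions."""


class MissingConditionError(ChangescopeError):
    """A required condition has no trials."""


class FitError(ChangescopeError):
    """A model fit failed to converge or is degenerate."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
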