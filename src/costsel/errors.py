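"""Exception hierarchy shared across the package."""


class CostselError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CostselError, ValueError):
    """A parameter is outside the mathematical domain of an operation."""


class NumericalError(CostselError, ArithmeticError):
    """A numerical routine failed to converge; the message carries diagnostics."""


class ValidationError(CostselError, ValueError):
    """Structured input (table, config, life cycle) violates its invariants."""


class UndefinedResultError(CostselError):
    """The requested quantity is mathematically undefined for this input
    (e.g. a proportion of selective deaths when no deaths occurred)."""
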