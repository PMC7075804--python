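"""Exception hierarchy for snacknrf.

All package errors derive from :class:`SnackNRFError` so callers can catch
one base class at pipeline boundaries.
"""


class SnackNRFError(Exception):
    """Base class for all snacknrf errors."""


class InvalidInputError(SnackNRFError, ValueError):
    """An argument violates a precondition (e.g. non-positive mass)."""


class UnscorableProductError(SnackNRFError):
    """A product's energy density is too low for the 100-kcal basis.

    The per-100-kcal normalization divides by energy density; products
    below ``ED_MIN`` cannot be scored and must be skipped explicitly.
    """

    def __init__(self, product_id: str, energy_density: float):
        self.product_id = product_id
        self.energy_density = energy_density
        super().__init__(
            f"product {product_id!r} has energy density "
            f"{energy_density:g} kcal/100 g below the scorable minimum"
        )


class ConfigurationError(SnackNRFError):
    """A nutrient name or reference-standard entry is unknown or invalid."""


class EmptyLabelError(SnackNRFError, ValueError):
    """An ingredient label is empty after trimming."""


class LabelParseError(SnackNRFError, ValueError):
    """An ingredient label cannot be parsed (e.g. unbalanced parentheses)."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


class UnknownCategoryError(SnackNRFError, KeyError):
    """A WWEIA code is not present in the category map."""

    def __init__(self, code: int):
        self.code = code
        super().__init__(f"WWEIA code {code} is not in the category map")


class EmptySummaryError(SnackNRFError, ValueError):
    """No products were supplied to a summary operation."""


class DegenerateGroupError(SnackNRFError, ValueError):
    """A comparison group has fewer than two members (SEM/ANOVA undefined)."""


class SchemaError(SnackNRFError, ValueError):
    """A product CSV is missing mandatory columns."""


class RowValidationError(SnackNRFError, ValueError):
    """One or more CSV rows violate product invariants."""

    def __init__(self, failures: list[tuple[int, str]]):
        self.failures = failures
        lines = "; ".join(f"row {row}: {msg}" for row, msg in failures)
        super().__init__(f"{len(failures)} invalid row(s): {lines}")
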