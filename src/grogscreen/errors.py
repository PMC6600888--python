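"""Exception types shared across the package."""


class GrogScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(GrogScreenError, ValueError):
    """An input value or record violates a documented precondition."""


class CatalogLookupError(GrogScreenError, LookupError):
    """A beverage entry references a product_id absent from the catalog."""

    def __init__(self, product_ids):
        ids = sorted(set(product_ids)) if not isinstance(product_ids, str) else [product_ids]
        self.product_ids = ids
        super().__init__(f"unknown product_id(s): {', '.join(ids)}")


class UndefinedStatisticError(GrogScreenError, ValueError):
    """A statistic is undefined for the given data (empty margin, no occasions, zero variance)."""


class InsufficientDataError(GrogScreenError, ValueError):
    """Too few eligible records to compute the requested analysis."""
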