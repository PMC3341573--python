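"""Exception hierarchy for the likelihood-ratio toolkit."""


class CatLRError(Exception):
    """Base class for all package errors."""


class DomainError(CatLRError, ValueError):
    """An input is outside its mathematical domain (probability, odds, LR)."""


class ParseError(CatLRError, ValueError):
    """A delimited-text or JSON input could not be validated."""


class CategoryNotFoundError(CatLRError, LookupError):
    """A category path matches no disease in the taxonomy."""


class DegenerateCategoryError(CatLRError, ValueError):
    """A category or its complement carries zero total prevalence."""


class DegenerateEvidenceError(CatLRError, ValueError):
    """Observed evidence has probability zero under the generative model."""


class StratumEmptyError(CatLRError, ValueError):
    """A cohort stratum needed for estimation contains no patients."""


class TraversalError(CatLRError, ValueError):
    """A scheme traversal could not proceed (unanswered router, bad branch)."""
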