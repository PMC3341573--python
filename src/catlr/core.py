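"""Probability/odds algebra and sequential Bayesian (likelihood-ratio) updating.

The diagnostic calculus implemented here works on the odds scale: a pre-test
probability ``p`` is converted to odds ``p/(1-p)``, each observed finding
multiplies the odds by its likelihood ratio (LR), and the final odds are
converted back to a post-test probability ``o/(1+o)``.  Everything is kept at
full floating-point precision; rounding happens only in the display helpers.

Likelihood ratios come from a finding's diagnostic accuracy:

    LR(+) = sensitivity / (1 - specificity)
    LR(-) = (1 - sensitivity) / specificity

A probability of exactly 1 maps to infinite odds (``math.inf``), which the
updating chain propagates correctly: 0 and 1 are absorbing states of Bayes'
rule and are returned unchanged with a warning recorded on the trace.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Literal, Sequence

from .errors import DomainError

__all__ = [
    "DiagnosticAccuracy",
    "LikelihoodRatioPair",
    "UpdateStep",
    "UpdateTrace",
    "prob_to_odds",
    "odds_to_prob",
    "lr_from_accuracy",
    "sequential_update",
    "classify_lr_strength",
    "round_half_even",
    "format_odds",
    "format_percent",
]

Direction = Literal["positive", "negative"]
StrengthBand = Literal["conclusive", "moderate", "small"]


def _check_fraction(value: float, name: str) -> float:
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise DomainError(f"{name} must lie in [0, 1], got {value!r}")
    return float(value)


def prob_to_odds(p: float) -> float:
    """Convert a probability to odds, ``p / (1 - p)``.

    ``p == 1`` yields ``math.inf`` (the infinite-odds flag).
    """
    p = _check_fraction(p, "probability")
    if p == 1.0:
        return math.inf
    return p / (1.0 - p)


def odds_to_prob(o: float) -> float:
    """Convert odds to a probability, ``o / (1 + o)``; infinite odds give 1."""
    if math.isnan(o) or o < 0:
        raise DomainError(f"odds must be non-negative, got {o!r}")
    if math.isinf(o):
        return 1.0
    return o / (1.0 + o)


@dataclass(frozen=True)
class DiagnosticAccuracy:
    """Sensitivity/specificity of a finding against a target proposition."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        _check_fraction(self.sensitivity, "sensitivity")
        _check_fraction(self.specificity, "specificity")


@dataclass(frozen=True)
class LikelihoodRatioPair:
    """LR for a positive result (``lr_pos``) and a negative one (``lr_neg``)."""

    lr_pos: float
    lr_neg: float

    def __post_init__(self) -> None:
        if math.isnan(self.lr_pos) or self.lr_pos < 0:
            raise DomainError(f"lr_pos must be non-negative, got {self.lr_pos!r}")
        if math.isnan(self.lr_neg) or self.lr_neg < 0:
            raise DomainError(f"lr_neg must be non-negative, got {self.lr_neg!r}")


def lr_from_accuracy(acc: DiagnosticAccuracy) -> LikelihoodRatioPair:
    """Derive the LR pair from sensitivity and specificity.

    ``specificity == 1`` flags an infinite LR(+); ``specificity == 0`` flags an
    infinite LR(-) (the respective denominators vanish).
    """
    sens, spec = acc.sensitivity, acc.specificity
    lr_pos = math.inf if spec == 1.0 else sens / (1.0 - spec)
    lr_neg = math.inf if spec == 0.0 else (1.0 - sens) / spec
    return LikelihoodRatioPair(lr_pos=lr_pos, lr_neg=lr_neg)


@dataclass(frozen=True)
class UpdateStep:
    """One applied LR and the running odds after applying it."""

    lr: float
    odds: float
    label: str = ""


@dataclass(frozen=True)
class UpdateTrace:
    """Ordered record of an odds-updating chain.

    ``prior_prob``/``prior_odds`` are the starting point (always both filled,
    consistently), ``steps`` the applied LRs with running odds, and the
    ``posterior_*`` properties the endpoint.  ``warnings`` collects notes such
    as skipped findings or absorbing priors.
    """

    prior_prob: float
    prior_odds: float
    steps: tuple[UpdateStep, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def posterior_odds(self) -> float:
        return self.steps[-1].odds if self.steps else self.prior_odds

    @property
    def posterior_prob(self) -> float:
        return odds_to_prob(self.posterior_odds)

    @property
    def lrs(self) -> tuple[float, ...]:
        return tuple(step.lr for step in self.steps)


def sequential_update(
    lrs: Iterable[float],
    *,
    prior_prob: float | None = None,
    prior_odds: float | None = None,
    labels: Sequence[str] | None = None,
    warnings: Sequence[str] = (),
) -> UpdateTrace:
    """Apply a chain of likelihood ratios to a prior, on the odds scale.

    Exactly one of ``prior_prob`` and ``prior_odds`` must be given (worked
    examples in the literature often quote the rounded prior *odds*, so both
    entry points are first-class).  The posterior odds are
    ``prior_odds * prod(lrs)``; every intermediate running-odds value is kept
    in the returned trace at full precision.

    Priors of exactly 0 or 1 are absorbing: the chain leaves them unchanged
    and a warning is recorded.
    """
    if (prior_prob is None) == (prior_odds is None):
        raise DomainError("give exactly one of prior_prob or prior_odds")
    if prior_prob is not None:
        p = _check_fraction(prior_prob, "prior probability")
        o = prob_to_odds(p)
    else:
        assert prior_odds is not None
        if math.isnan(prior_odds) or prior_odds < 0:
            raise DomainError(f"prior odds must be non-negative, got {prior_odds!r}")
        o = float(prior_odds)
        p = odds_to_prob(o)

    lr_list = [float(lr) for lr in lrs]
    for lr in lr_list:
        if math.isnan(lr) or lr <= 0:
            raise DomainError(f"likelihood ratios must be positive, got {lr!r}")
    if labels is not None and len(labels) != len(lr_list):
        raise DomainError("labels must match the number of likelihood ratios")

    warn = list(warnings)
    if o == 0.0 or math.isinf(o):
        state = "0" if o == 0.0 else "1"
        warn.append(
            f"prior probability is exactly {state}: an absorbing state of Bayes' "
            "rule; likelihood ratios leave it unchanged"
        )
        steps = tuple(
            UpdateStep(lr=lr, odds=o, label=labels[i] if labels else "")
            for i, lr in enumerate(lr_list)
        )
        return UpdateTrace(prior_prob=p, prior_odds=o, steps=steps, warnings=tuple(warn))

    steps = []
    running = o
    for i, lr in enumerate(lr_list):
        running *= lr
        steps.append(UpdateStep(lr=lr, odds=running, label=labels[i] if labels else ""))
    return UpdateTrace(prior_prob=p, prior_odds=o, steps=tuple(steps), warnings=tuple(warn))


def with_warnings(trace: UpdateTrace, extra: Sequence[str]) -> UpdateTrace:
    """Return a copy of ``trace`` with additional warnings appended."""
    return dataclasses.replace(trace, warnings=trace.warnings + tuple(extra))


def classify_lr_strength(lr: float, direction: Direction) -> StrengthBand:
    """Band an LR by the rule-of-thumb strength of the shift it produces.

    Positive direction: LR > 10 is conclusive, 5-10 (inclusive) moderate,
    below 5 small.  Negative direction: LR < 0.1 conclusive, 0.1-0.2
    (inclusive) moderate, above small.  Boundaries fall in the moderate band.
    """
    if math.isnan(lr) or lr <= 0:
        raise DomainError(f"likelihood ratio must be positive, got {lr!r}")
    if direction == "positive":
        if lr > 10:
            return "conclusive"
        if 5 <= lr <= 10:
            return "moderate"
        return "small"
    if direction == "negative":
        if lr < 0.1:
            return "conclusive"
        if 0.1 <= lr <= 0.2:
            return "moderate"
        return "small"
    raise DomainError(f"direction must be 'positive' or 'negative', got {direction!r}")


# ---------------------------------------------------------------------------
# Display helpers (rounding lives here, never in the computation layer)

def round_half_even(x: float, decimals: int = 2) -> float:
    """Round to ``decimals`` places with banker's (half-even) rounding."""
    if math.isinf(x) or math.isnan(x):
        return x
    q = Decimal(1).scaleb(-decimals) if decimals > 0 else Decimal(1)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def format_odds(o: float, decimals: int = 2) -> str:
    if math.isinf(o):
        return "inf"
    return f"{round_half_even(o, decimals):.{decimals}f}"


def format_percent(p: float, decimals: int = 0) -> str:
    """Format a probability fraction as a percentage string."""
    pct = round_half_even(p * 100.0, decimals)
    return f"{pct:.{decimals}f}%"
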