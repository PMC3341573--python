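"""Category priors, category-oriented likelihood ratios, and category revision.

A *category-oriented LR* quantifies how much more likely a finding is in a
patient whose disease belongs to a category (e.g. "organic") than in a patient
whose disease does not.  Under cross-sectional cohort sampling — one disease
``d`` drawn with prevalence ``pi_d``, a binary finding present with
probability ``p_d`` given the disease — the category-level accuracy is the
prevalence-weighted mixture over member and non-member diseases:

    sensitivity = sum_{d in C} pi_d p_d / sum_{d in C} pi_d
    specificity = 1 - sum_{d not in C} pi_d p_d / sum_{d not in C} pi_d

and the category LR pair follows from the usual sensitivity/specificity
formulas.  The complement is taken over *all* non-member diseases in the
taxonomy, including symptomatic-but-undiagnosed rows.

Revising a category probability with several findings multiplies their LRs
sequentially, which treats findings as conditionally independent given which
side of the category boundary the disease falls on.  For a single finding, or
when finding probabilities are homogeneous within the category and within its
complement, this equals the exact Bayes posterior; otherwise it is a
naive-Bayes approximation whose error the simulator quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import (
    DiagnosticAccuracy,
    LikelihoodRatioPair,
    UpdateTrace,
    lr_from_accuracy,
    sequential_update,
)
from .errors import (
    CategoryNotFoundError,
    DegenerateCategoryError,
    DomainError,
)
from .io import AccuracyRow, AccuracyTable, DiseaseTable, PatientProfile, Status

__all__ = [
    "CategoryNode",
    "FindingModel",
    "category_node",
    "category_prior",
    "derive_category_accuracy",
    "category_lr",
    "select_lrs",
    "revise_category",
]


@dataclass(frozen=True)
class CategoryNode:
    """A node of the disease-category hierarchy with its member diseases."""

    path: tuple[str, ...]
    member_ids: frozenset[str]

    @property
    def label(self) -> str:
        return "/".join(self.path)


def _as_path(category: str | Sequence[str]) -> tuple[str, ...]:
    if isinstance(category, str):
        parts = tuple(p.strip() for p in category.split("/") if p.strip())
    else:
        parts = tuple(category)
    if not parts:
        raise CategoryNotFoundError("empty category path")
    return parts


def category_node(diseases: DiseaseTable, category: str | Sequence[str]) -> CategoryNode:
    """Resolve a path string like ``"organic/neoplasm"`` against a taxonomy.

    Membership is by path prefix: a disease with category path
    ``organic/neoplasm`` is a member of both ``organic`` and
    ``organic/neoplasm``.  A path matching no disease raises
    :class:`CategoryNotFoundError`.
    """
    path = _as_path(category)
    members = frozenset(
        e.disease_id for e in diseases if e.category_path[: len(path)] == path
    )
    if not members:
        raise CategoryNotFoundError(
            f"category {'/'.join(path)!r} matches no disease in the table"
        )
    return CategoryNode(path=path, member_ids=members)


def category_prior(
    diseases: DiseaseTable, category: CategoryNode | str | Sequence[str]
) -> float:
    """Pre-test probability of a category: the sum of member prevalences.

    Accepts a resolved :class:`CategoryNode` (which may be empty, giving 0.0)
    or a path, which is resolved first.
    """
    node = (
        category
        if isinstance(category, CategoryNode)
        else category_node(diseases, category)
    )
    return float(sum(e.prevalence for e in diseases if e.disease_id in node.member_ids))


@dataclass(frozen=True)
class FindingModel:
    """Per-disease probability of one binary finding being present."""

    finding_id: str
    per_disease_prob: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for did, p in self.per_disease_prob.items():
            if not (0.0 <= p <= 1.0) or math.isnan(p):
                raise DomainError(
                    f"finding {self.finding_id!r}: probability for disease "
                    f"{did!r} must lie in [0, 1], got {p!r}"
                )

    def prob(self, disease_id: str) -> float:
        try:
            return self.per_disease_prob[disease_id]
        except KeyError:
            raise DomainError(
                f"finding {self.finding_id!r} has no probability for disease "
                f"{disease_id!r}"
            ) from None


def derive_category_accuracy(
    diseases: DiseaseTable,
    model: FindingModel,
    category: CategoryNode | str | Sequence[str],
) -> DiagnosticAccuracy:
    """Category-level sensitivity/specificity of a finding.

    Prevalence-weighted mixture over member diseases (sensitivity) and over
    all non-member diseases (one minus specificity); requires positive total
    prevalence on both sides of the category boundary.
    """
    node = (
        category
        if isinstance(category, CategoryNode)
        else category_node(diseases, category)
    )
    w_in = w_out = f_in = f_out = 0.0
    for entry in diseases:
        p = model.prob(entry.disease_id)
        if entry.disease_id in node.member_ids:
            w_in += entry.prevalence
            f_in += entry.prevalence * p
        else:
            w_out += entry.prevalence
            f_out += entry.prevalence * p
    if w_in <= 0.0:
        raise DegenerateCategoryError(
            f"category {node.label!r} has zero total prevalence"
        )
    if w_out <= 0.0:
        raise DegenerateCategoryError(
            f"complement of category {node.label!r} has zero total prevalence"
        )
    return DiagnosticAccuracy(sensitivity=f_in / w_in, specificity=1.0 - f_out / w_out)


def category_lr(
    diseases: DiseaseTable,
    model: FindingModel,
    category: CategoryNode | str | Sequence[str],
) -> LikelihoodRatioPair:
    """Category-oriented LR pair of a finding, from its derived accuracy."""
    return lr_from_accuracy(derive_category_accuracy(diseases, model, category))


# ---------------------------------------------------------------------------
# LR selection under dependence groups

def _log_distance(lr: float) -> float:
    """|ln LR| — the symmetric measure of a finding's discriminatory value."""
    if lr == 0.0 or math.isinf(lr):
        return math.inf
    return abs(math.log(lr))


def applicable_findings(
    profile: PatientProfile, table: AccuracyTable
) -> list[tuple[AccuracyRow, Status, float]]:
    """Findings of ``table`` observed in ``profile`` with their applicable LR.

    Present findings contribute LR(+), absent ones LR(-), unknown ones are
    excluded.  Within each dependence group only the single applicable LR with
    the largest ``|ln LR|`` is kept (ties break toward the earlier table row),
    since dependent findings must not be multiplied together.  Output order is
    table row order.
    """
    chosen: list[tuple[AccuracyRow, Status, float]] = []
    best_in_group: dict[str, int] = {}  # group -> index into `chosen`
    for row in table:
        status = profile.status(row.finding_id)
        lr = row.lr_for(status)
        if lr is None:
            continue
        if lr <= 0 and status == "present":
            # LR(+) of exactly 0 would force the posterior to 0; treat as the
            # strongest possible evidence but keep the chain well-defined.
            raise DomainError(
                f"finding {row.finding_id!r}: lr_pos of 0 cannot enter a "
                "sequential chain"
            )
        if not row.dependence_group:
            chosen.append((row, status, lr))
            continue
        prev = best_in_group.get(row.dependence_group)
        if prev is None:
            best_in_group[row.dependence_group] = len(chosen)
            chosen.append((row, status, lr))
        elif _log_distance(lr) > _log_distance(chosen[prev][2]):
            chosen[prev] = (row, status, lr)
    return chosen


def select_lrs(profile: PatientProfile, table: AccuracyTable) -> list[float]:
    """Ordered LRs to apply for a profile, after dependence-group filtering."""
    return [lr for _, _, lr in applicable_findings(profile, table)]


def revise_category(
    prior: float,
    profile: PatientProfile,
    table: AccuracyTable,
    *,
    prior_is_odds: bool = False,
) -> UpdateTrace:
    """Revise a category probability with a patient's findings.

    Applies the table's LR(+) for present findings and LR(-) for absent ones
    (after dependence-group filtering), sequentially on the odds scale.
    Findings in the profile that the table does not cover are skipped with a
    warning on the trace; unknown findings contribute nothing.
    """
    selected = applicable_findings(profile, table)
    warnings = [
        f"finding {fid!r} not in accuracy table {table.target!r}; skipped"
        for fid in profile.results
        if fid not in table
    ]
    labels = [f"{row.finding_id} {status}" for row, status, _ in selected]
    lrs = [lr for _, _, lr in selected]
    kwargs = {"prior_odds": prior} if prior_is_odds else {"prior_prob": prior}
    return sequential_update(lrs, labels=labels, warnings=warnings, **kwargs)
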