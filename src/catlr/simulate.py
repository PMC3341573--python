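"""Virtual-cohort simulation and exact-Bayes validation of category updating.

The generative model is the minimal one consistent with sequential LR use:
each patient carries exactly one disease, drawn from a prevalence vector, and
binary findings are drawn conditionally independently given that disease.
From a simulated cohort the empirical category-level sensitivity/specificity
and LRs can be estimated and compared with their analytic values; an
enumeration oracle computes the exact posterior

    P(d | evidence) ∝ pi_d * prod_f p_d(f)^[present] (1 - p_d(f))^[absent]

so that the error of the sequential (naive-Bayes) category update can be
measured rather than assumed away.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence, Union

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .categories import (
    CategoryNode,
    FindingModel,
    category_node,
    derive_category_accuracy,
    revise_category,
)
from .core import LikelihoodRatioPair, lr_from_accuracy, prob_to_odds
from .errors import (
    DegenerateEvidenceError,
    DomainError,
    ParseError,
    StratumEmptyError,
)
from .io import (
    AccuracyRow,
    AccuracyTable,
    DiseaseEntry,
    DiseaseTable,
    PatientProfile,
    _open_text,
    _write_text,
)

__all__ = [
    "GenerativeModel",
    "Cohort",
    "EstimateWithCI",
    "DiscrepancyReport",
    "simulate_cohort",
    "estimate_category_accuracy",
    "estimate_category_lr",
    "exact_posterior",
    "naive_vs_exact",
    "category_accuracy_table",
    "sequential_category_posteriors",
    "exact_category_posteriors",
    "discrepancy_summary",
    "calibration_table",
    "demo_abdominal_model",
]


@dataclass
class GenerativeModel:
    """Joint specification: disease prevalences + per-disease finding probs.

    Prevalences are renormalized to a simplex (published prevalence columns
    sum to slightly less than 100% because each row is rounded).  Findings
    are mutually independent given the disease — the model's defining
    contract.
    """

    diseases: DiseaseTable
    findings: list[FindingModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(e.prevalence for e in self.diseases)
        if total <= 0:
            raise DomainError("disease table has zero total prevalence")
        seen: set[str] = set()
        for f in self.findings:
            if f.finding_id in seen:
                raise DomainError(f"duplicate finding_id {f.finding_id!r}")
            seen.add(f.finding_id)
            for e in self.diseases:
                f.prob(e.disease_id)  # raises if any disease is uncovered

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return self.diseases.disease_ids

    @property
    def finding_ids(self) -> tuple[str, ...]:
        return tuple(f.finding_id for f in self.findings)

    @property
    def prevalence(self) -> np.ndarray:
        """Prevalence simplex over diseases (renormalized to sum to 1)."""
        raw = np.array([e.prevalence for e in self.diseases], dtype=float)
        return raw / raw.sum()

    @property
    def prob_matrix(self) -> np.ndarray:
        """Shape (n_diseases, n_findings): P(finding present | disease)."""
        return np.array(
            [
                [f.prob(d) for f in self.findings]
                for d in self.disease_ids
            ],
            dtype=float,
        )

    def category(self, path: str | Sequence[str]) -> CategoryNode:
        return category_node(self.diseases, path)

    def category_prior(self, category: CategoryNode | str) -> float:
        """Category prior on the renormalized prevalence simplex."""
        node = category if isinstance(category, CategoryNode) else self.category(category)
        prev = self.prevalence
        mask = np.array([d in node.member_ids for d in self.disease_ids])
        return float(prev[mask].sum())

    def member_mask(self, category: CategoryNode | str) -> np.ndarray:
        node = category if isinstance(category, CategoryNode) else self.category(category)
        return np.array([d in node.member_ids for d in self.disease_ids])

    def finding(self, finding_id: str) -> FindingModel:
        for f in self.findings:
            if f.finding_id == finding_id:
                return f
        raise KeyError(finding_id)

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "diseases": [
                    {
                        "disease_id": e.disease_id,
                        "label": e.label,
                        "prevalence_pct": e.prevalence_pct,
                        "category_path": "/".join(e.category_path),
                    }
                    for e in self.diseases
                ],
                "findings": {
                    f.finding_id: dict(f.per_disease_prob) for f in self.findings
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, source: Union[str, Path, IO[str]]) -> "GenerativeModel":
        """Load from a JSON file path, stream, or raw JSON text."""
        if isinstance(source, str) and source.lstrip().startswith("{"):
            text, name = source, "<string>"
        else:
            text, name = _open_text(source)
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{name}: invalid JSON: {exc}") from exc
        entries = [
            DiseaseEntry(
                disease_id=d["disease_id"],
                label=d.get("label", d["disease_id"]),
                prevalence_pct=float(d["prevalence_pct"]),
                category_path=tuple(
                    p for p in str(d["category_path"]).split("/") if p
                ),
            )
            for d in obj["diseases"]
        ]
        findings = [
            FindingModel(finding_id=fid, per_disease_prob={k: float(v) for k, v in probs.items()})
            for fid, probs in obj["findings"].items()
        ]
        return cls(diseases=DiseaseTable(entries=entries), findings=findings)


@dataclass
class Cohort:
    """A simulated cross-sectional cohort.

    ``disease_idx`` indexes into ``disease_ids``; ``X`` is the boolean
    (n_patients, n_findings) presence matrix in ``finding_ids`` order.
    """

    disease_ids: tuple[str, ...]
    finding_ids: tuple[str, ...]
    disease_idx: np.ndarray
    X: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.disease_idx), len(self.finding_ids)):
            raise DomainError("finding matrix shape does not match cohort")

    @property
    def n(self) -> int:
        return int(len(self.disease_idx))

    @property
    def patient_disease_ids(self) -> np.ndarray:
        return np.asarray(self.disease_ids, dtype=object)[self.disease_idx]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.X.astype(int), columns=list(self.finding_ids))
        df.insert(0, "disease_id", self.patient_disease_ids)
        return df

    def write_csv(self, sink: Union[str, Path, IO[str]]) -> None:
        _write_text(sink, self.to_dataframe().to_csv(index=False))


def simulate_cohort(model: GenerativeModel, n: int, seed: int) -> Cohort:
    """Draw ``n`` virtual patients: one disease each, findings independent given it."""
    if n < 0:
        raise DomainError(f"cohort size must be non-negative, got {n}")
    rng = np.random.default_rng(seed)
    prev = model.prevalence
    disease_idx = rng.choice(len(prev), size=n, p=prev)
    pm = model.prob_matrix  # (k, f)
    X = rng.random((n, pm.shape[1])) < pm[disease_idx]
    return Cohort(
        disease_ids=model.disease_ids,
        finding_ids=model.finding_ids,
        disease_idx=disease_idx,
        X=X,
        seed=seed,
    )


@dataclass(frozen=True)
class EstimateWithCI:
    """A proportion estimate with its Wilson 95% interval and 2x2 counts."""

    point: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def se(self) -> float:
        """Binomial standard error of the point estimate."""
        return math.sqrt(self.point * (1.0 - self.point) / self.n) if self.n else math.nan


def _proportion(successes: int, total: int) -> EstimateWithCI:
    low, high = proportion_confint(successes, total, alpha=0.05, method="wilson")
    return EstimateWithCI(
        point=successes / total,
        ci_low=float(low),
        ci_high=float(high),
        n_pos=successes,
        n_neg=total - successes,
    )


def estimate_category_accuracy(
    cohort: Cohort, finding_id: str, category: CategoryNode
) -> tuple[EstimateWithCI, EstimateWithCI]:
    """Empirical (sensitivity, specificity) of a finding for a category.

    Sensitivity: fraction finding-positive among category members;
    specificity: fraction finding-negative among non-members.  Wilson 95%
    intervals are attached; an empty stratum raises :class:`StratumEmptyError`.
    """
    try:
        col = cohort.finding_ids.index(finding_id)
    except ValueError:
        raise KeyError(finding_id) from None
    member = np.isin(cohort.patient_disease_ids, list(category.member_ids))
    n_in, n_out = int(member.sum()), int((~member).sum())
    if n_in == 0:
        raise StratumEmptyError(f"no cohort patient belongs to {category.label!r}")
    if n_out == 0:
        raise StratumEmptyError(f"every cohort patient belongs to {category.label!r}")
    pos = cohort.X[:, col]
    sens = _proportion(int(pos[member].sum()), n_in)
    spec = _proportion(int((~pos[~member]).sum()), n_out)
    return sens, spec


def estimate_category_lr(
    cohort: Cohort, finding_id: str, category: CategoryNode
) -> LikelihoodRatioPair:
    """Empirical category-oriented LR pair from cohort 2x2 counts."""
    sens, spec = estimate_category_accuracy(cohort, finding_id, category)
    from .core import DiagnosticAccuracy

    return lr_from_accuracy(DiagnosticAccuracy(sens.point, spec.point))


# ---------------------------------------------------------------------------
# Exact enumeration oracle

def exact_posterior(
    model: GenerativeModel, profile: PatientProfile
) -> dict[str, dict[str, float]]:
    """Exact Bayes posterior over diseases (and every category) given evidence.

    Returns ``{"diseases": {id: P}, "categories": {path: P}}``; unknown
    findings contribute nothing.  Evidence with probability zero under the
    model raises :class:`DegenerateEvidenceError`.
    """
    prev = model.prevalence
    lik = np.ones_like(prev)
    for f in model.findings:
        status = profile.status(f.finding_id)
        if status == "unknown":
            continue
        p = np.array([f.prob(d) for d in model.disease_ids])
        lik *= p if status == "present" else (1.0 - p)
    unnorm = prev * lik
    total = unnorm.sum()
    if total <= 0.0:
        raise DegenerateEvidenceError(
            "observed evidence has probability zero under the model"
        )
    post = unnorm / total
    diseases = {d: float(p) for d, p in zip(model.disease_ids, post)}
    categories = {}
    for path in model.diseases.category_paths():
        node = category_node(model.diseases, path)
        mask = model.member_mask(node)
        categories["/".join(path)] = float(post[mask].sum())
    return {"diseases": diseases, "categories": categories}


def category_accuracy_table(
    model: GenerativeModel, category: CategoryNode | str
) -> AccuracyTable:
    """Analytic category-oriented LR table for every finding of a model."""
    node = category if isinstance(category, CategoryNode) else model.category(category)
    rows = []
    for f in model.findings:
        acc = derive_category_accuracy(model.diseases, f, node)
        pair = lr_from_accuracy(acc)
        rows.append(
            AccuracyRow(
                finding_id=f.finding_id,
                label=f.finding_id,
                lr_pos=pair.lr_pos,
                lr_neg=pair.lr_neg,
                sensitivity=acc.sensitivity,
                specificity=acc.specificity,
            )
        )
    return AccuracyTable(target=node.label, rows=rows)


@dataclass(frozen=True)
class DiscrepancyReport:
    """Sequential (category-LR) vs exact posterior for one profile."""

    category: str
    sequential_posterior: float
    exact_posterior: float

    @property
    def abs_diff(self) -> float:
        return abs(self.sequential_posterior - self.exact_posterior)

    @property
    def log_odds_diff(self) -> float:
        a = prob_to_odds(self.sequential_posterior)
        b = prob_to_odds(self.exact_posterior)
        if a == 0.0 or b == 0.0 or math.isinf(a) or math.isinf(b):
            return math.inf if a != b else 0.0
        return math.log(a) - math.log(b)

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "sequential_posterior": self.sequential_posterior,
            "exact_posterior": self.exact_posterior,
            "abs_diff": self.abs_diff,
            "log_odds_diff": self.log_odds_diff,
        }


def naive_vs_exact(
    model: GenerativeModel,
    profile: PatientProfile,
    category: CategoryNode | str,
) -> DiscrepancyReport:
    """Compare sequential category updating with the enumeration oracle.

    The sequential side uses the model's own analytic category-oriented LRs
    and the category prior on the prevalence simplex, so any discrepancy is
    purely the conditional-independence (naive-Bayes) approximation error at
    the category level.
    """
    node = category if isinstance(category, CategoryNode) else model.category(category)
    table = category_accuracy_table(model, node)
    prior = model.category_prior(node)
    trace = revise_category(prior, profile, table)
    exact = exact_posterior(model, profile)["categories"][node.label]
    return DiscrepancyReport(
        category=node.label,
        sequential_posterior=trace.posterior_prob,
        exact_posterior=exact,
    )


# ---------------------------------------------------------------------------
# Vectorized posteriors over whole cohorts (validation machinery)

_TINY = 1e-300


def sequential_category_posteriors(
    model: GenerativeModel, category: CategoryNode | str, X: np.ndarray
) -> np.ndarray:
    """Sequential (category-LR) posterior for every row of a presence matrix."""
    node = category if isinstance(category, CategoryNode) else model.category(category)
    table = category_accuracy_table(model, node)
    log_pos = np.array([math.log(max(r.lr_pos, _TINY)) for r in table])
    log_neg = np.array([math.log(max(r.lr_neg, _TINY)) for r in table])
    prior = model.category_prior(node)
    X = np.asarray(X, dtype=bool)
    log_odds = math.log(prob_to_odds(prior)) + np.where(X, log_pos, log_neg).sum(axis=1)
    odds = np.exp(log_odds)
    return odds / (1.0 + odds)


def exact_category_posteriors(
    model: GenerativeModel, category: CategoryNode | str, X: np.ndarray
) -> np.ndarray:
    """Enumeration-oracle posterior for every row of a presence matrix."""
    node = category if isinstance(category, CategoryNode) else model.category(category)
    X = np.asarray(X, dtype=bool)
    pm = np.clip(model.prob_matrix, _TINY, 1.0 - _TINY)  # (k, f)
    log_p, log_q = np.log(pm), np.log1p(-pm)
    # (n, k) joint log-likelihood given each disease
    ll = X @ log_p.T + (~X) @ log_q.T + np.log(model.prevalence)
    ll -= ll.max(axis=1, keepdims=True)
    w = np.exp(ll)
    mask = model.member_mask(node)
    return w[:, mask].sum(axis=1) / w.sum(axis=1)


def discrepancy_summary(
    model: GenerativeModel, category: CategoryNode | str, cohort: Cohort
) -> dict[str, float]:
    """Max/mean |sequential - exact| category posterior across a cohort."""
    seq = sequential_category_posteriors(model, category, cohort.X)
    exact = exact_category_posteriors(model, category, cohort.X)
    diff = np.abs(seq - exact)
    return {
        "n_patients": float(cohort.n),
        "max_abs_diff": float(diff.max()) if cohort.n else 0.0,
        "mean_abs_diff": float(diff.mean()) if cohort.n else 0.0,
    }


def calibration_table(
    model: GenerativeModel,
    category: CategoryNode | str,
    cohort: Cohort,
    *,
    bin_width: float = 0.1,
    coverage: float = 0.99,
) -> list[dict[str, float]]:
    """Bin patients by sequential posterior and check empirical calibration.

    For each posterior bin the empirical category frequency is compared with
    the exact binomial central interval (at ``coverage``) around the bin's
    mean predicted posterior.  Returns one record per non-empty bin with an
    ``inside`` flag.
    """
    from scipy.stats import binom

    node = category if isinstance(category, CategoryNode) else model.category(category)
    post = sequential_category_posteriors(model, node, cohort.X)
    member = np.isin(cohort.patient_disease_ids, list(node.member_ids))
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    idx = np.clip(np.digitize(post, edges) - 1, 0, len(edges) - 2)
    records = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n_bin = int(sel.sum())
        if n_bin == 0:
            continue
        p_mean = float(post[sel].mean())
        k_obs = int(member[sel].sum())
        lo, hi = binom.interval(coverage, n_bin, p_mean)
        records.append(
            {
                "bin_low": float(edges[b]),
                "bin_high": float(edges[b + 1]),
                "n": float(n_bin),
                "mean_posterior": p_mean,
                "empirical_frequency": k_obs / n_bin,
                "interval_low": float(lo) / n_bin,
                "interval_high": float(hi) / n_bin,
                "inside": float(lo <= k_obs <= hi),
            }
        )
    return records


# ---------------------------------------------------------------------------
# Demo model

def _accuracy_from_lr_pair(lr_pos: float, lr_neg: float) -> tuple[float, float]:
    """Invert LR(+)/LR(-) to the unique (sensitivity, specificity) pair."""
    if not (lr_neg < 1.0 < lr_pos):
        raise DomainError(
            "inversion needs a discriminating pair with lr_neg < 1 < lr_pos"
        )
    spec = (lr_pos - 1.0) / (lr_pos - lr_neg)
    sens = lr_pos * (1.0 - spec)
    return sens, spec


def demo_abdominal_model(
    *, heterogeneity: float = 0.15, seed: int = 0
) -> GenerativeModel:
    """An abdominal-pain-like generative model for demonstration and testing.

    Per-disease finding probabilities are centred so that, at zero
    heterogeneity, each finding's analytic category-oriented LR for the
    organic category equals the bundled table's value exactly (the published
    LR pair is inverted to a sensitivity/specificity pair, which becomes the
    within-category / outside-category finding probability).  ``heterogeneity``
    adds per-disease log-odds noise (standard deviation, logit scale), making
    the category heterogeneous so the analytic LRs only approximate the
    published values — a demonstration, not a reconstruction, since the
    underlying per-disease accuracies were never published.
    """
    from . import data

    if heterogeneity < 0:
        raise DomainError("heterogeneity must be non-negative")
    diseases = data.load_abdominal_diseases()
    table = data.load_abdominal_findings()
    organic = category_node(diseases, "organic")
    rng = np.random.default_rng(seed)
    findings = []
    for row in table:
        sens, spec = _accuracy_from_lr_pair(row.lr_pos, row.lr_neg)  # type: ignore[arg-type]
        probs = {}
        for e in diseases:
            base = sens if e.disease_id in organic.member_ids else 1.0 - spec
            logit = math.log(base / (1.0 - base)) + heterogeneity * rng.standard_normal()
            probs[e.disease_id] = 1.0 / (1.0 + math.exp(-logit))
        findings.append(FindingModel(finding_id=row.finding_id, per_disease_prob=probs))
    return GenerativeModel(diseases=diseases, findings=findings)
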