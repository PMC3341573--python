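"""Expert scheme trees: branching-point traversal with category revision.

A scheme is a tree of branching points of three kinds:

* **router** — a deterministic question answered from the patient profile's
  attributes (e.g. onset acute vs non-acute); the answer names the child
  branch.
* **reviser** — a probabilistic branching point: a category probability is
  revised with the patient's findings (via the category-oriented LRs of an
  accuracy table) and compared with the node's action threshold; posteriors
  above the threshold take the ``above`` branch, others ``below``.
* **action** — a leaf carrying the terminal clinical action (e.g.
  "symptomatic treatment & follow-up").

The threshold policy is deliberately explicit configuration: published
schemes invoke a "predefined diagnostic threshold" without quantifying it, so
every reviser node carries its own (default 0.10).

A reviser's prior can come from the disease table (``{"source":
"diseases"}``), from the previous reviser's posterior (``{"source":
"carried"}``), or be fixed in the scheme file (``{"source": "fixed",
"probability": p}`` or ``"odds": o``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Callable, Literal, Mapping, Union

from .categories import (  # noqa: F401  (select_lrs re-exported: it is the
    category_prior,  # LR-selection rule this engine applies at revisers)
    revise_category,
    select_lrs,
)
from .core import UpdateTrace
from .errors import ParseError, TraversalError
from .io import AccuracyTable, DiseaseTable, PatientProfile, _open_text

__all__ = [
    "SchemeNode",
    "TraversalStep",
    "TraversalRecord",
    "load_scheme",
    "run_scheme",
    "select_lrs",
]

#: Action threshold used when a reviser node does not declare one.
DEFAULT_THRESHOLD = 0.10

TableResolver = Callable[[str], AccuracyTable]


@dataclass(frozen=True)
class PriorSpec:
    """Where a reviser node's pre-test probability comes from."""

    source: Literal["diseases", "carried", "fixed"]
    probability: float | None = None
    odds: float | None = None


@dataclass
class SchemeNode:
    """One branching point (router or reviser) or leaf action of a scheme."""

    node_id: str
    kind: Literal["router", "reviser", "action"]
    question: str = ""
    # router
    attribute: str = ""
    # reviser
    category: str = ""
    table: AccuracyTable | None = None
    modality: str | None = None
    prior: PriorSpec = field(default_factory=lambda: PriorSpec("diseases"))
    threshold: float = DEFAULT_THRESHOLD
    # leaf
    action: str = ""
    children: dict[str, "SchemeNode"] = field(default_factory=dict)


def _parse_node(
    obj: Mapping, resolve_table: TableResolver, seen_ids: set[str], depth: int
) -> SchemeNode:
    if depth > 100:
        raise ParseError("scheme tree too deep (cycle?)")
    kind = obj.get("type")
    if kind not in ("action", "router", "reviser"):
        raise ParseError(f"unknown node type {kind!r}")
    if kind == "action":
        return SchemeNode(node_id=str(obj.get("id", "")), kind="action",
                          action=str(obj.get("action", "")))
    node_id = str(obj.get("id", ""))
    if not node_id:
        raise ParseError(f"{kind} node without an id")
    if node_id in seen_ids:
        raise ParseError(f"duplicate node id {node_id!r}")
    seen_ids.add(node_id)
    children = {
        str(branch): _parse_node(child, resolve_table, seen_ids, depth + 1)
        for branch, child in obj.get("children", {}).items()
    }
    if not children:
        raise ParseError(f"node {node_id!r} has no children")
    if kind == "router":
        attribute = str(obj.get("field", ""))
        if not attribute:
            raise ParseError(f"router {node_id!r} names no profile field")
        return SchemeNode(
            node_id=node_id, kind="router", question=str(obj.get("question", "")),
            attribute=attribute, children=children,
        )
    if kind == "reviser":
        prior_obj = obj.get("prior", {"source": "diseases"})
        source = prior_obj.get("source")
        if source not in ("diseases", "carried", "fixed"):
            raise ParseError(f"reviser {node_id!r}: unknown prior source {source!r}")
        prior = PriorSpec(
            source=source,
            probability=prior_obj.get("probability"),
            odds=prior_obj.get("odds"),
        )
        if source == "fixed" and (prior.probability is None) == (prior.odds is None):
            raise ParseError(
                f"reviser {node_id!r}: fixed prior needs exactly one of "
                "probability or odds"
            )
        table_ref = obj.get("table")
        if not table_ref:
            raise ParseError(f"reviser {node_id!r} names no accuracy table")
        category = str(obj.get("category", ""))
        if not category:
            raise ParseError(f"reviser {node_id!r} names no category")
        if set(children) != {"above", "below"}:
            raise ParseError(
                f"reviser {node_id!r} must have exactly the branches "
                "'above' and 'below'"
            )
        return SchemeNode(
            node_id=node_id, kind="reviser", question=str(obj.get("question", "")),
            category=category, table=resolve_table(str(table_ref)),
            modality=obj.get("modality"), prior=prior,
            threshold=float(obj.get("threshold", DEFAULT_THRESHOLD)),
            children=children,
        )
    raise ParseError(f"unknown node type {kind!r}")


def _default_resolver(ref: str) -> AccuracyTable:
    """Resolve a table reference: bundled fixture name, else a CSV path."""
    from . import data
    from .io import read_accuracy_table

    try:
        return read_accuracy_table(data.fixture_path(f"{ref}.csv"))
    except FileNotFoundError:
        return read_accuracy_table(ref)


def load_scheme(
    source: Union[str, Path, IO[str]],
    *,
    table_resolver: TableResolver | None = None,
) -> SchemeNode:
    """Parse a scheme-tree JSON file.

    Accuracy-table references inside reviser nodes are resolved eagerly:
    bundled fixture names (e.g. ``"abdominal_findings"``) first, then
    filesystem paths.  Pass ``table_resolver`` to override.
    """
    text, name = _open_text(source)
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{name}: invalid JSON: {exc}") from exc
    return _parse_node(obj, table_resolver or _default_resolver, set(), 0)


@dataclass(frozen=True)
class TraversalStep:
    """What happened at one visited node."""

    node_id: str
    kind: str
    branch: str
    trace: UpdateTrace | None = None  # revisers only
    threshold: float | None = None
    category: str = ""


@dataclass(frozen=True)
class TraversalRecord:
    """Full record of one patient's path through a scheme."""

    steps: tuple[TraversalStep, ...]
    terminal_action: str

    def traces(self) -> list[UpdateTrace]:
        return [s.trace for s in self.steps if s.trace is not None]

    def to_json(self) -> str:
        from .io import trace_to_json

        return json.dumps(
            {
                "terminal_action": self.terminal_action,
                "steps": [
                    {
                        "node_id": s.node_id,
                        "kind": s.kind,
                        "branch": s.branch,
                        "category": s.category,
                        "threshold": s.threshold,
                        "trace": None if s.trace is None else json.loads(trace_to_json(s.trace)),
                    }
                    for s in self.steps
                ],
            },
            indent=2,
        )


def run_scheme(
    scheme: SchemeNode, profile: PatientProfile, diseases: DiseaseTable
) -> TraversalRecord:
    """Run a patient through a scheme tree.

    Routers read the named profile attribute (an unanswered router raises
    :class:`TraversalError` naming the node).  Revisers call
    :func:`revise_category` with the node's accuracy table (optionally
    restricted to one modality) and branch ``above``/``below`` by comparing
    the posterior with the node's threshold.  The record retains every trace.
    """
    steps: list[TraversalStep] = []
    carried_posterior: float | None = None
    node = scheme
    while node.kind != "action":
        if node.kind == "router":
            answer = profile.attributes.get(node.attribute)
            if answer is None:
                raise TraversalError(
                    f"router {node.node_id!r}: profile does not answer "
                    f"attribute {node.attribute!r}"
                )
            if answer not in node.children:
                raise TraversalError(
                    f"router {node.node_id!r}: no branch for answer {answer!r} "
                    f"(branches: {sorted(node.children)})"
                )
            steps.append(TraversalStep(node.node_id, "router", answer))
            node = node.children[answer]
            continue
        # reviser
        assert node.table is not None
        prior_is_odds = False
        if node.prior.source == "diseases":
            prior = category_prior(diseases, node.category)
        elif node.prior.source == "carried":
            if carried_posterior is None:
                raise TraversalError(
                    f"reviser {node.node_id!r}: carried prior requested but no "
                    "earlier reviser was visited"
                )
            prior = carried_posterior
        else:
            if node.prior.probability is not None:
                prior = node.prior.probability
            else:
                prior = node.prior.odds  # type: ignore[assignment]
                prior_is_odds = True
        table = node.table.subset(node.modality)  # type: ignore[arg-type]
        trace = revise_category(prior, profile, table, prior_is_odds=prior_is_odds)
        posterior = trace.posterior_prob
        branch = "above" if posterior > node.threshold else "below"
        steps.append(
            TraversalStep(
                node.node_id, "reviser", branch, trace=trace,
                threshold=node.threshold, category=node.category,
            )
        )
        carried_posterior = posterior
        node = node.children[branch]
    return TraversalRecord(steps=tuple(steps), terminal_action=node.action)
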