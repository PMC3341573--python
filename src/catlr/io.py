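"""Readers/writers for accuracy tables, disease taxonomies, profiles and traces.

File dialects
-------------
* Accuracy tables and disease/prevalence tables are comma-separated UTF-8 with
  a fixed header vocabulary.  Leading ``# key: value`` comment lines carry
  table-level metadata (currently ``target``).
* Patient profiles, scheme trees and update traces are JSON.
* Prevalence is stored in files as percent of cohort (as published tables
  print it) and converted to fractions on access.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import IO, Iterator, Literal, Mapping

import pandas as pd

from .core import (
    DiagnosticAccuracy,
    LikelihoodRatioPair,
    UpdateStep,
    UpdateTrace,
    format_odds,
    format_percent,
    lr_from_accuracy,
)
from .errors import ParseError

__all__ = [
    "AccuracyRow",
    "AccuracyTable",
    "DiseaseEntry",
    "DiseaseTable",
    "PatientProfile",
    "read_accuracy_table",
    "write_accuracy_table",
    "read_disease_table",
    "write_disease_table",
    "read_profile",
    "write_profile",
    "write_trace",
    "trace_to_json",
    "trace_from_json",
]

Status = Literal["present", "absent", "unknown"]
Modality = Literal["history", "exam", "laboratory"]

_STATUSES = ("present", "absent", "unknown")
_MODALITIES = ("history", "exam", "laboratory")

#: Relative tolerance for agreement between a stated LR pair and the LR pair
#: implied by stated sensitivity/specificity on the same row.
LR_CONSISTENCY_RTOL = 0.05

#: Published prevalence columns rarely sum to exactly 100 because each row is
#: rounded; allow this much slack above 100.
PREVALENCE_SLACK_PCT = 0.5


@dataclass
class AccuracyRow:
    """One finding's diagnostic value against the table's target proposition.

    Either the LR pair or the (sensitivity, specificity) pair must be given;
    missing LRs are derived from the accuracy pair at load time.  Findings
    that are statistically dependent share a non-empty ``dependence_group``.
    """

    finding_id: str
    label: str
    lr_pos: float | None = None
    lr_neg: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    dependence_group: str = ""
    modality: Modality = "history"
    note: str = ""

    def validate(self) -> None:
        has_lrs = self.lr_pos is not None and self.lr_neg is not None
        has_acc = self.sensitivity is not None and self.specificity is not None
        if not (has_lrs or has_acc):
            raise ParseError(
                f"row {self.finding_id!r}: needs (lr_pos, lr_neg) or "
                "(sensitivity, specificity)"
            )
        if self.modality not in _MODALITIES:
            raise ParseError(
                f"row {self.finding_id!r}: modality must be one of {_MODALITIES}"
            )
        if has_acc:
            implied = lr_from_accuracy(
                DiagnosticAccuracy(self.sensitivity, self.specificity)  # type: ignore[arg-type]
            )
            if has_lrs:
                for name, stated, exp in (
                    ("lr_pos", self.lr_pos, implied.lr_pos),
                    ("lr_neg", self.lr_neg, implied.lr_neg),
                ):
                    if not _close(stated, exp, LR_CONSISTENCY_RTOL):  # type: ignore[arg-type]
                        raise ParseError(
                            f"row {self.finding_id!r}: stated {name}={stated} is "
                            f"inconsistent with sensitivity/specificity "
                            f"(implies {exp:.4g})"
                        )
            else:
                self.lr_pos = implied.lr_pos
                self.lr_neg = implied.lr_neg
        if self.lr_pos is not None and (math.isnan(self.lr_pos) or self.lr_pos < 0):
            raise ParseError(f"row {self.finding_id!r}: lr_pos must be non-negative")
        if self.lr_neg is not None and (math.isnan(self.lr_neg) or self.lr_neg < 0):
            raise ParseError(f"row {self.finding_id!r}: lr_neg must be non-negative")

    @property
    def lrs(self) -> LikelihoodRatioPair:
        assert self.lr_pos is not None and self.lr_neg is not None
        return LikelihoodRatioPair(self.lr_pos, self.lr_neg)

    def lr_for(self, status: Status) -> float | None:
        """The applicable LR for a finding status (None when unknown)."""
        if status == "present":
            return self.lr_pos
        if status == "absent":
            return self.lr_neg
        return None


def _close(a: float, b: float, rtol: float) -> bool:
    if math.isinf(a) or math.isinf(b):
        return a == b
    return abs(a - b) <= rtol * max(abs(a), abs(b), 1e-12)


@dataclass
class AccuracyTable:
    """A set of findings scored against one target disease or category."""

    target: str
    rows: list[AccuracyRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.finding_id in seen:
                raise ParseError(f"duplicate finding_id {row.finding_id!r}")
            seen.add(row.finding_id)

    def __iter__(self) -> Iterator[AccuracyRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, finding_id: str) -> bool:
        return any(r.finding_id == finding_id for r in self.rows)

    def get(self, finding_id: str) -> AccuracyRow:
        for row in self.rows:
            if row.finding_id == finding_id:
                return row
        raise KeyError(finding_id)

    def subset(self, modality: Modality | None) -> "AccuracyTable":
        """Rows restricted to one modality (None returns the table itself)."""
        if modality is None:
            return self
        return AccuracyTable(
            target=self.target, rows=[r for r in self.rows if r.modality == modality]
        )


@dataclass(frozen=True)
class DiseaseEntry:
    """A disease with its cohort prevalence and category path.

    ``category_path`` is ordered broad-to-narrow, e.g. ``("organic",
    "neoplasm")``; in files it is written ``organic/neoplasm``.
    """

    disease_id: str
    label: str
    prevalence_pct: float
    category_path: tuple[str, ...]

    def __post_init__(self) -> None:
        if math.isnan(self.prevalence_pct) or self.prevalence_pct < 0:
            raise ParseError(
                f"disease {self.disease_id!r}: prevalence must be non-negative"
            )
        if not self.category_path:
            raise ParseError(f"disease {self.disease_id!r}: empty category path")

    @property
    def prevalence(self) -> float:
        """Prevalence as a fraction of the cohort."""
        return self.prevalence_pct / 100.0


@dataclass
class DiseaseTable:
    """Taxonomy of final diagnoses with prevalence fractions."""

    entries: list[DiseaseEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.disease_id in seen:
                raise ParseError(f"duplicate disease_id {e.disease_id!r}")
            seen.add(e.disease_id)
        total = self.total_prevalence_pct
        if total > 100.0 + PREVALENCE_SLACK_PCT:
            raise ParseError(
                f"prevalences sum to {total:.2f}% which exceeds 100% plus "
                f"rounding slack ({PREVALENCE_SLACK_PCT}%)"
            )

    def __iter__(self) -> Iterator[DiseaseEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, disease_id: str) -> DiseaseEntry:
        for e in self.entries:
            if e.disease_id == disease_id:
                return e
        raise KeyError(disease_id)

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(e.disease_id for e in self.entries)

    @property
    def total_prevalence_pct(self) -> float:
        return float(sum(e.prevalence_pct for e in self.entries))

    def category_paths(self) -> list[tuple[str, ...]]:
        """All distinct category prefixes present in the taxonomy, sorted."""
        paths: set[tuple[str, ...]] = set()
        for e in self.entries:
            for k in range(1, len(e.category_path) + 1):
                paths.add(e.category_path[:k])
        return sorted(paths)


@dataclass
class PatientProfile:
    """A patient's observed finding results plus free-form attributes.

    ``results`` maps finding_id to present/absent/unknown; findings not listed
    are treated as unknown.  ``attributes`` holds categorical facts that
    scheme routers branch on (e.g. ``onset: non-acute``).
    """

    results: dict[str, Status] = field(default_factory=dict)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, status in self.results.items():
            if status not in _STATUSES:
                raise ParseError(
                    f"finding {fid!r}: status must be one of {_STATUSES}, "
                    f"got {status!r}"
                )

    def status(self, finding_id: str) -> Status:
        return self.results.get(finding_id, "unknown")


# ---------------------------------------------------------------------------
# CSV reading/writing

def _open_text(source: str | Path | IO[str]) -> tuple[str, str]:
    """Return (text, name) for a path or readable stream."""
    if hasattr(source, "read"):
        return source.read(), getattr(source, "name", "<stream>")  # type: ignore[union-attr]
    path = Path(source)  # type: ignore[arg-type]
    return path.read_text(encoding="utf-8"), str(path)


def _split_metadata(text: str) -> tuple[dict[str, str], str]:
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            content = stripped.lstrip("#").strip()
            if ":" in content:
                key, _, value = content.partition(":")
                meta.setdefault(key.strip(), value.strip())
            continue
        body_lines.append(line)
    return meta, "\n".join(body_lines)


def _opt_float(value: object, what: str, row_name: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ParseError(f"row {row_name!r}: non-numeric {what}: {value!r}") from None


def read_accuracy_table(
    source: str | Path | IO[str], *, target: str | None = None
) -> AccuracyTable:
    """Read a diagnostic-accuracy CSV into a validated :class:`AccuracyTable`.

    The header must contain ``finding_id`` and ``label``; numeric columns
    ``lr_pos``, ``lr_neg``, ``sensitivity``, ``specificity`` are optional per
    row but each row needs one complete pair.  Rows carrying only
    sensitivity/specificity get LRs filled in via ``lr_from_accuracy``.
    """
    text, name = _open_text(source)
    meta, body = _split_metadata(text)
    try:
        df = pd.read_csv(StringIO(body), dtype=str, keep_default_na=False)
    except Exception as exc:  # pandas raises several parse error types
        raise ParseError(f"{name}: could not parse CSV: {exc}") from exc
    missing = {"finding_id", "label"} - set(df.columns)
    if missing:
        raise ParseError(f"{name}: missing mandatory columns {sorted(missing)}")

    rows = []
    for idx, rec in df.iterrows():
        fid = str(rec["finding_id"]).strip()
        if not fid:
            raise ParseError(f"{name}: row {idx + 2}: empty finding_id")
        row = AccuracyRow(
            finding_id=fid,
            label=str(rec["label"]).strip(),
            lr_pos=_opt_float(rec.get("lr_pos"), "lr_pos", fid),
            lr_neg=_opt_float(rec.get("lr_neg"), "lr_neg", fid),
            sensitivity=_opt_float(rec.get("sensitivity"), "sensitivity", fid),
            specificity=_opt_float(rec.get("specificity"), "specificity", fid),
            dependence_group=str(rec.get("dependence_group", "") or "").strip(),
            modality=str(rec.get("modality", "history") or "history").strip(),  # type: ignore[arg-type]
            note=str(rec.get("note", "") or "").strip(),
        )
        row.validate()
        rows.append(row)
    return AccuracyTable(target=target or meta.get("target", ""), rows=rows)


def write_accuracy_table(table: AccuracyTable, sink: str | Path | IO[str]) -> None:
    """Write an accuracy table in the dialect :func:`read_accuracy_table` reads."""
    records = [
        {
            "finding_id": r.finding_id,
            "label": r.label,
            "lr_pos": "" if r.lr_pos is None else repr(r.lr_pos),
            "lr_neg": "" if r.lr_neg is None else repr(r.lr_neg),
            "sensitivity": "" if r.sensitivity is None else repr(r.sensitivity),
            "specificity": "" if r.specificity is None else repr(r.specificity),
            "dependence_group": r.dependence_group,
            "modality": r.modality,
            "note": r.note,
        }
        for r in table.rows
    ]
    df = pd.DataFrame.from_records(
        records,
        columns=[
            "finding_id", "label", "lr_pos", "lr_neg", "sensitivity",
            "specificity", "dependence_group", "modality", "note",
        ],
    )
    text = f"# target: {table.target}\n" + df.to_csv(index=False)
    _write_text(sink, text)


def read_disease_table(source: str | Path | IO[str]) -> DiseaseTable:
    """Read a prevalence/taxonomy CSV into a validated :class:`DiseaseTable`."""
    text, name = _open_text(source)
    _, body = _split_metadata(text)
    try:
        df = pd.read_csv(StringIO(body), dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"{name}: could not parse CSV: {exc}") from exc
    required = {"disease_id", "label", "prevalence_pct", "category_path"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{name}: missing mandatory columns {sorted(missing)}")
    entries = []
    for _, rec in df.iterrows():
        did = str(rec["disease_id"]).strip()
        prev = _opt_float(rec["prevalence_pct"], "prevalence_pct", did)
        if prev is None:
            raise ParseError(f"row {did!r}: missing prevalence_pct")
        path = tuple(
            part.strip() for part in str(rec["category_path"]).split("/") if part.strip()
        )
        entries.append(
            DiseaseEntry(
                disease_id=did,
                label=str(rec["label"]).strip(),
                prevalence_pct=prev,
                category_path=path,
            )
        )
    return DiseaseTable(entries=entries)


def write_disease_table(table: DiseaseTable, sink: str | Path | IO[str]) -> None:
    df = pd.DataFrame.from_records(
        [
            {
                "disease_id": e.disease_id,
                "label": e.label,
                "prevalence_pct": repr(e.prevalence_pct),
                "category_path": "/".join(e.category_path),
            }
            for e in table.entries
        ],
        columns=["disease_id", "label", "prevalence_pct", "category_path"],
    )
    _write_text(sink, df.to_csv(index=False))


# ---------------------------------------------------------------------------
# Profiles (JSON)

def read_profile(source: str | Path | IO[str]) -> PatientProfile:
    """Read a patient profile from JSON: ``{"findings": {...}, "attributes": {...}}``."""
    text, name = _open_text(source)
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{name}: invalid JSON: {exc}") from exc
    if not isinstance(obj, Mapping):
        raise ParseError(f"{name}: profile JSON must be an object")
    findings = obj.get("findings", {})
    attributes = obj.get("attributes", {})
    return PatientProfile(
        results={str(k): str(v) for k, v in findings.items()},  # type: ignore[misc]
        attributes={str(k): str(v) for k, v in attributes.items()},
    )


def write_profile(profile: PatientProfile, sink: str | Path | IO[str]) -> None:
    _write_text(
        sink,
        json.dumps(
            {"attributes": profile.attributes, "findings": profile.results}, indent=2
        )
        + "\n",
    )


# ---------------------------------------------------------------------------
# Trace serialization

def trace_to_json(trace: UpdateTrace) -> str:
    """Serialize an :class:`UpdateTrace` to JSON at full precision."""
    obj = {
        "prior_prob": trace.prior_prob,
        "prior_odds": _json_num(trace.prior_odds),
        "steps": [
            {"label": s.label, "lr": _json_num(s.lr), "odds": _json_num(s.odds)}
            for s in trace.steps
        ],
        "posterior_odds": _json_num(trace.posterior_odds),
        "posterior_prob": trace.posterior_prob,
        "warnings": list(trace.warnings),
    }
    return json.dumps(obj, indent=2)


def trace_from_json(text: str) -> UpdateTrace:
    obj = json.loads(text)
    return UpdateTrace(
        prior_prob=float(obj["prior_prob"]),
        prior_odds=_num_json(obj["prior_odds"]),
        steps=tuple(
            UpdateStep(
                lr=_num_json(s["lr"]), odds=_num_json(s["odds"]), label=s.get("label", "")
            )
            for s in obj["steps"]
        ),
        warnings=tuple(obj.get("warnings", ())),
    )


def _json_num(x: float) -> float | str:
    return "inf" if math.isinf(x) else x


def _num_json(x: object) -> float:
    return math.inf if x == "inf" else float(x)  # type: ignore[arg-type]


def format_trace(trace: UpdateTrace, *, decimals: int = 2) -> str:
    """Human-readable step table for an updating chain.

    Mirrors the layout of published worked examples: prior line, one line per
    applied LR with the running odds, posterior odds and probability.
    """
    lines = [
        f"Pre-test probability = {format_percent(trace.prior_prob)}"
        f"   (odds {format_odds(trace.prior_odds, decimals)})"
    ]
    for step in trace.steps:
        label = f"  [{step.label}]" if step.label else ""
        lines.append(
            f"  x {step.lr:g}{label}"
            f"   -> odds {format_odds(step.odds, decimals)}"
        )
    lines.append(f"Post-test odds = {format_odds(trace.posterior_odds, decimals)}")
    lines.append(f"Post-test probability = {format_percent(trace.posterior_prob)}")
    for w in trace.warnings:
        lines.append(f"note: {w}")
    return "\n".join(lines) + "\n"


def write_trace(
    trace: UpdateTrace,
    sink: str | Path | IO[str],
    *,
    fmt: Literal["text", "json"] = "text",
    decimals: int = 2,
) -> None:
    """Write a trace as a human-readable table (``text``) or JSON (``json``)."""
    if fmt == "json":
        _write_text(sink, trace_to_json(trace) + "\n")
    else:
        _write_text(sink, format_trace(trace, decimals=decimals))


def _write_text(sink: str | Path | IO[str], text: str) -> None:
    if hasattr(sink, "write"):
        sink.write(text)  # type: ignore[union-attr]
    else:
        Path(sink).write_text(text, encoding="utf-8")  # type: ignore[arg-type]
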