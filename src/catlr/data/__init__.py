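"""Bundled fixture tables, profiles and scheme trees.

The fixtures transcribe published worked-example inputs:

* ``uti_findings.csv`` — disease-oriented LRs of symptoms/signs for
  uncomplicated urinary tract infection (vaginal discharge and vaginal
  irritation share a dependence group).
* ``abdominal_findings.csv`` — category-oriented LRs of characteristics,
  symptoms and laboratory tests for the organic category of non-acute
  abdominal pain.
* ``abdominal_diseases.csv`` — final-diagnosis prevalences (percent of
  patients) for a non-acute abdominal pain cohort, with category paths
  ``non-organic``, ``organic`` and ``organic/neoplasm``.
* ``abdominal_scheme.json`` — an example expert scheme for abdominal pain
  (onset router, organic history/laboratory revisers, neoplasm reviser).
* ``case1_profile.json`` / ``case2_profile.json`` — the two worked clinical
  cases as finding profiles.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..io import (
    AccuracyTable,
    DiseaseTable,
    PatientProfile,
    read_accuracy_table,
    read_disease_table,
    read_profile,
)

__all__ = [
    "fixture_path",
    "load_uti_findings",
    "load_abdominal_findings",
    "load_abdominal_diseases",
    "load_abdominal_scheme_json",
    "load_case1_profile",
    "load_case2_profile",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture file."""
    path = Path(str(resources.files(__name__) / name))
    if not path.exists():
        raise FileNotFoundError(f"no bundled fixture named {name!r}")
    return path


def load_uti_findings() -> AccuracyTable:
    """Symptom/sign LRs for uncomplicated urinary tract infection."""
    return read_accuracy_table(fixture_path("uti_findings.csv"))


def load_abdominal_findings() -> AccuracyTable:
    """Category-oriented LRs for organic disease in non-acute abdominal pain."""
    return read_accuracy_table(fixture_path("abdominal_findings.csv"))


def load_abdominal_diseases() -> DiseaseTable:
    """Prevalence/taxonomy of final diagnoses in non-acute abdominal pain."""
    return read_disease_table(fixture_path("abdominal_diseases.csv"))


def load_abdominal_scheme_json() -> str:
    """Raw JSON text of the example abdominal-pain scheme tree."""
    return fixture_path("abdominal_scheme.json").read_text(encoding="utf-8")


def load_case1_profile() -> PatientProfile:
    """Worked UTI case: dysuria+, frequency+, no discharge/irritation, self-diagnosis+."""
    return read_profile(fixture_path("case1_profile.json"))


def load_case2_profile() -> PatientProfile:
    """Worked abdominal case: non-acute onset, discriminatory findings all negative."""
    return read_profile(fixture_path("case2_profile.json"))
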