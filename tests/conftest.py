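"""Shared fixtures: bundled tables/profiles and random generative models."""

from __future__ import annotations

import numpy as np
import pytest

from catlr import data
from catlr.categories import FindingModel
from catlr.io import DiseaseEntry, DiseaseTable
from catlr.simulate import GenerativeModel


@pytest.fixture(scope="session")
def uti_table():
    return data.load_uti_findings()


@pytest.fixture(scope="session")
def abdominal_table():
    return data.load_abdominal_findings()


@pytest.fixture(scope="session")
def diseases():
    return data.load_abdominal_diseases()


@pytest.fixture(scope="session")
def case1_profile():
    return data.load_case1_profile()


@pytest.fixture(scope="session")
def case2_profile():
    return data.load_case2_profile()


def make_random_model(
    n_diseases: int = 6,
    n_findings: int = 3,
    seed: int = 0,
    *,
    categories: tuple[str, ...] = ("alpha", "beta"),
) -> GenerativeModel:
    """A random generative model with diseases split across flat categories."""
    rng = np.random.default_rng(seed)
    prev = rng.dirichlet(np.ones(n_diseases))
    entries = [
        DiseaseEntry(
            disease_id=f"d{i}",
            label=f"disease {i}",
            prevalence_pct=float(p * 100.0),
            category_path=(categories[i % len(categories)],),
        )
        for i, p in enumerate(prev)
    ]
    findings = [
        FindingModel(
            finding_id=f"f{j}",
            per_disease_prob={
                f"d{i}": float(rng.uniform(0.05, 0.95)) for i in range(n_diseases)
            },
        )
        for j in range(n_findings)
    ]
    return GenerativeModel(diseases=DiseaseTable(entries=entries), findings=findings)


def make_homogeneous_model(
    p_in: float = 0.9,
    p_out: float = 0.2,
    n_in: int = 3,
    n_out: int = 3,
    n_findings: int = 3,
    seed: int = 0,
) -> GenerativeModel:
    """Model whose finding probabilities are constant within each category side."""
    rng = np.random.default_rng(seed)
    prev = rng.dirichlet(np.ones(n_in + n_out))
    entries = [
        DiseaseEntry(
            disease_id=f"d{i}",
            label=f"disease {i}",
            prevalence_pct=float(p * 100.0),
            category_path=("inside",) if i < n_in else ("outside",),
        )
        for i, p in enumerate(prev)
    ]
    findings = [
        FindingModel(
            finding_id=f"f{j}",
            per_disease_prob={
                f"d{i}": (p_in if i < n_in else p_out) for i in range(n_in + n_out)
            },
        )
        for j in range(n_findings)
    ]
    return GenerativeModel(diseases=DiseaseTable(entries=entries), findings=findings)
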