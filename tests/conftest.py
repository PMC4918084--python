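import pytest
from hypothesis import HealthCheck, settings

from litsignal import (
    AnnotationCorpus,
    Descriptor,
    Terminology,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cardio_terminology() -> Terminology:
    """Small cardiovascular/nervous-system slice with realistic tree
    numbers: a deep aneurysm chain, a multi-classified abnormality term and
    a shallow demyelinating branch."""
    return Terminology(
        [
            Descriptor("D002318", "Cardiovascular Diseases", {"C14"}),
            Descriptor("D014652", "Vascular Diseases", {"C14.907"}),
            Descriptor("D000783", "Aneurysm", {"C14.907.055"}),
            Descriptor("D017542", "Aneurysm, Ruptured", {"C14.907.055.131"}),
            Descriptor("D000013", "Congenital Abnormalities", {"C16.131"}),
            Descriptor("D018376", "Cardiovascular Abnormalities", {"C14.240", "C16.131.240"}),
            Descriptor("D009422", "Nervous System Diseases", {"C10"}),
            Descriptor("D003711", "Demyelinating Diseases", {"C10.314"}),
        ]
    )


@pytest.fixture(scope="session")
def cardio_ic() -> dict[str, float]:
    """Reference-corpus information content for the cardio fixture terms."""
    return {
        "D002318": 3.53,   # Cardiovascular Diseases
        "D014652": 4.03,   # Vascular Diseases
        "D000783": 7.79,   # Aneurysm
        "D017542": 10.65,  # Aneurysm, Ruptured
        "D000013": 5.55,   # Congenital Abnormalities
        "D018376": 7.14,   # Cardiovascular Abnormalities
        "D009422": 3.40,   # Nervous System Diseases
        "D003711": 8.13,   # Demyelinating Diseases
    }


@pytest.fixture(scope="session")
def parent_child_study():
    """Hand-built 60-article corpus where a specific event term drives a
    drug's signal and its parent term tags along through co-annotation.

    Reference margins: a(child) = 6, a(parent) = 20 (5 qualified + 13
    unqualified parent articles plus the 6 child articles via propagation),
    co-count 6.  Set of interest: the drug's 5 articles, 4 annotated with
    child+parent, 1 with parent only.
    """
    terminology = Terminology(
        [
            Descriptor("P0001", "parent disease", {"C01"}),
            Descriptor("X0001", "child disease", {"C01.001"}),
            Descriptor("DX001", "test drug", frozenset()),
        ]
    )
    records = set()
    soi = [f"s{i}" for i in range(1, 6)]
    for article in soi:
        records.add((article, "DX001", "adverse effects"))
        records.add((article, "P0001", "chemically induced"))
    for article in soi[:4]:
        records.add((article, "X0001", "chemically induced"))
    for article in ("b01", "b02"):  # child background, unqualified
        records.add((article, "X0001", ""))
    for i in range(3, 16):  # parent-only background, unqualified
        records.add((f"b{i:02d}", "P0001", ""))
    universe = {r[0] for r in records} | {f"u{i:02d}" for i in range(40)}
    assert len(universe) == 60
    corpus = AnnotationCorpus(frozenset(records), frozenset(universe))
    return terminology, corpus
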