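import numpy as np
import pytest

from ddx.inference import Differential, Finding
from ddx.knowledge_base import DiseaseEntry, KnowledgeBase, SymptomEntry
from ddx.vignettes import Vignette, VignetteSet


@pytest.fixture
def tiny_kb() -> KnowledgeBase:
    """Two diseases, three symptoms; s1 discriminates strongly toward d1."""
    diseases = [DiseaseEntry("d1", "disease one", 0.5), DiseaseEntry("d2", "disease two", 0.5)]
    symptoms = [
        SymptomEntry("s1", "discriminating sign", "presenting_complaint"),
        SymptomEntry("s2", "supporting sign", "present_illness"),
        SymptomEntry("s3", "shared sign", "medical_history"),
    ]
    weights = np.array(
        [
            [0.9, 0.1],
            [0.7, 0.3],
            [0.4, 0.4],
        ]
    )
    return KnowledgeBase(diseases, symptoms, weights)


def make_differential(*pairs) -> Differential:
    return Differential(tuple((d, int(s)) for d, s in pairs))


def make_vignette(vid, gold_ids, stratum="high", findings=None, sureties=(50, 30, 20)) -> Vignette:
    if findings is None:
        findings = (Finding("s1", "present"),)
    return Vignette(
        id=vid,
        findings=tuple(findings),
        stratum=stratum,
        gold=make_differential(*zip(gold_ids, sureties)),
    )


@pytest.fixture
def small_gold_set() -> VignetteSet:
    """Ten vignettes over four diseases with varied strata."""
    strata = ["high", "high", "high", "moderate", "moderate", "moderate", "low", "low", "low", "low"]
    golds = [
        ("a", "b", "c"),
        ("a", "c", "d"),
        ("b", "a", "c"),
        ("b", "c", "d"),
        ("c", "a", "b"),
        ("c", "b", "d"),
        ("a", "b", "d"),
        ("d", "a", "b"),
        ("a", "c", "b"),
        ("b", "d", "a"),
    ]
    return VignetteSet(
        tuple(
            make_vignette(f"v{i}", gold, stratum=s) for i, (gold, s) in enumerate(zip(golds, strata))
        ),
        label="fixture",
    )
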