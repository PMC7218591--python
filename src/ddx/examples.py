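"""Packaged worked example: a synthetic febrile-illness knowledge base.

The disease list is an invented, illustrative roster of common causes of
acute febrile illness in a South-Asian primary-care setting; the
association weights are synthetic (generated, not clinically curated) and
exist so the engine, evaluation battery, and CLI have a self-contained,
deterministic example to run against.  Nothing here is medical advice or a
validated clinical parameterization.
"""

from __future__ import annotations

from ddx.knowledge_base import KnowledgeBase
from ddx.synthetic import GeneratorConfig, generate_kb

#: Illustrative placeholder roster of 15 febrile illnesses (synthetic study domain).
FEVER_DISEASES = (
    "Malaria",
    "Dengue fever",
    "Typhoid fever",
    "Chikungunya",
    "Scrub typhus",
    "Leptospirosis",
    "Influenza",
    "Viral upper respiratory infection",
    "Community-acquired pneumonia",
    "Urinary tract infection",
    "Pulmonary tuberculosis",
    "Acute viral hepatitis",
    "Amoebic liver abscess",
    "Brucellosis",
    "Infective endocarditis",
)

#: Seed fixing the example KB; any fixed value works, this one is arbitrary.
EXAMPLE_SEED = 2020


def example_knowledge_base() -> KnowledgeBase:
    """Deterministic 15-disease, 60-symptom synthetic example KB."""
    config = GeneratorConfig(seed=EXAMPLE_SEED)
    return generate_kb(config, disease_names=FEVER_DISEASES)
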