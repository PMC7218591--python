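"""Independent reference implementations used only by tests.

These deliberately avoid the package's computation paths: the posterior
oracle multiplies probabilities directly (no logs), and the Welch oracle
spells out the textbook statistic and Welch-Satterthwaite degrees of
freedom instead of calling a packaged test routine.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from ddx.knowledge_base import EPS, DiseaseEntry, KnowledgeBase, SymptomEntry


def brute_force_posterior(kb: KnowledgeBase, findings) -> dict[str, float]:
    """Direct-product Bayes over the closed disease set; returns id -> prob."""
    probs = []
    for j, d in enumerate(kb.diseases):
        p = d.prior
        for f in findings:
            w = kb.weights[kb.symptom_index(f.symptom_id), j]
            w = min(max(w, EPS), 1.0 - EPS)
            p *= w if f.polarity == "present" else (1.0 - w)
        probs.append(p)
    probs = np.asarray(probs)
    probs = probs / probs.sum()
    return {d.id: float(p) for d, p in zip(kb.diseases, probs)}


def welch_upper_tail(a, b) -> tuple[float, float]:
    """Textbook Welch t statistic and upper-tail p value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, float(stats.t.sf(t, df))


def random_kb(rng: np.random.Generator, max_diseases: int = 5, max_symptoms: int = 8) -> KnowledgeBase:
    """Small fully-random KB for oracle cross-checks."""
    nd = int(rng.integers(2, max_diseases + 1))
    ns = int(rng.integers(1, max_symptoms + 1))
    priors = rng.dirichlet(np.ones(nd))
    diseases = [DiseaseEntry(f"d{i}", f"disease {i}", float(p)) for i, p in enumerate(priors)]
    symptoms = [SymptomEntry(f"s{i}", f"symptom {i}", "presenting_complaint") for i in range(ns)]
    weights = rng.uniform(0.0, 1.0, size=(ns, nd))
    return KnowledgeBase(diseases, symptoms, weights)


def random_findings(rng: np.random.Generator, kb: KnowledgeBase, allow_empty: bool = True):
    from ddx.inference import Finding

    low = 0 if allow_empty else 1
    n = int(rng.integers(low, len(kb.symptoms) + 1))
    chosen = rng.choice(len(kb.symptoms), size=n, replace=False)
    return [
        Finding(kb.symptoms[i].id, "present" if rng.random() < 0.5 else "absent")
        for i in chosen
    ]
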