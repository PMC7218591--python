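"""Synthetic knowledge bases, stratified vignette studies, and noisy raters.

The study's curated associations and expert-written vignettes are not
publicly available in machine-readable form, so this module generates
structurally analogous data with *known* ground truth: a febrile-illness
style knowledge base in which every disease owns a few near-pathognomonic
markers, a handful of disease-leaning signs, and a pool of shared
constitutional symptoms; a vignette study balanced over (disease,
specificity stratum) cells; and simulated raters that corrupt the engine's
own differential at configurable error rates.

Stratum policies are threshold-driven (weights ``>= 0.85`` are
pathognomonic, ``>= 0.5`` disease-leaning, shared-pool symptoms have all
weights below 0.5) and every generator is fully deterministic under its
seed, with independent sub-streams per vignette.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ddx.inference import (
    Differential,
    Finding,
    largest_remainder_percentages,
    posterior,
    rank_differentials,
)
from ddx.knowledge_base import DiseaseEntry, KnowledgeBase, SymptomEntry
from ddx.vignettes import STRATA, Demographics, Vignette, VignetteSet

DEFAULT_PATHOGNOMONIC_THRESHOLD = 0.85
DEFAULT_LEANING_THRESHOLD = 0.5


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape of the synthetic study.

    The defaults mirror the emulated study design: 15 diseases x 3
    specificity strata x 2 vignettes per cell = 90 vignettes, over a
    60-symptom vocabulary with 2 pathognomonic markers per disease and a
    quarter of the symptoms in the shared constitutional pool.
    """

    n_diseases: int = 15
    n_symptoms: int = 60
    pathognomonic_per_disease: int = 2
    shared_symptom_fraction: float = 0.25
    vignettes_per_cell: int = 2
    pathognomonic_threshold: float = DEFAULT_PATHOGNOMONIC_THRESHOLD
    leaning_threshold: float = DEFAULT_LEANING_THRESHOLD
    seed: int = 0

    def layout(self) -> tuple[int, int, int]:
        """(n_pathognomonic, n_leaning, n_shared) symptom counts; checks feasibility."""
        if self.n_diseases < 1 or self.n_symptoms < 1 or self.pathognomonic_per_disease < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.shared_symptom_fraction <= 1.0):
            raise ValueError("shared_symptom_fraction must be in [0, 1]")
        if not (0.0 < self.leaning_threshold < self.pathognomonic_threshold < 1.0):
            raise ValueError("thresholds must satisfy 0 < leaning < pathognomonic < 1")
        n_path = self.n_diseases * self.pathognomonic_per_disease
        n_shared = max(1, round(self.shared_symptom_fraction * self.n_symptoms))
        n_leaning = self.n_symptoms - n_path - n_shared
        if n_leaning < self.n_diseases:
            raise ValueError(
                f"infeasible config: {self.n_symptoms} symptoms cannot fit "
                f"{n_path} pathognomonic + {n_shared} shared + at least "
                f"{self.n_diseases} disease-leaning symptoms"
            )
        return n_path, n_leaning, n_shared


@dataclass(frozen=True)
class RaterConfig:
    """A simulated clinician: the engine's answer corrupted at known rates."""

    label: str = "rater-1"
    primary_error_rate: float = 0.3
    differential_error_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for rate in (self.primary_error_rate, self.differential_error_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("error rates must be in [0, 1]")


# ---------------------------------------------------------------------------
# knowledge-base generation
# ---------------------------------------------------------------------------


def generate_kb(
    config: GeneratorConfig, disease_names: Sequence[str] | None = None
) -> KnowledgeBase:
    """Generate a planted-structure knowledge base, deterministic under seed.

    Each disease owns ``pathognomonic_per_disease`` symptoms with weight in
    [0.85, 0.99] for it and near-zero elsewhere, at least one "leaning"
    symptom (owner weight in [0.55, 0.80]), and the shared pool carries
    moderate weights (all below the leaning threshold) for every disease.
    Priors are Dirichlet-drawn and normalized.
    """
    n_path, n_leaning, n_shared = config.layout()
    nd = config.n_diseases
    rng = np.random.default_rng([config.seed, 0])

    if disease_names is None:
        disease_names = [f"Disease {i + 1:02d}" for i in range(nd)]
    if len(disease_names) != nd:
        raise ValueError(f"need {nd} disease names, got {len(disease_names)}")
    width = len(str(nd))
    diseases = [
        DiseaseEntry(f"d{i + 1:0{width}d}", disease_names[i], 0.0) for i in range(nd)
    ]
    priors = rng.dirichlet(np.full(nd, 3.0))
    diseases = [DiseaseEntry(d.id, d.name, float(p)) for d, p in zip(diseases, priors)]

    symptoms: list[SymptomEntry] = []
    weights = rng.uniform(0.0, 0.05, size=(config.n_symptoms, nd))  # faint background

    idx = 0
    for i in range(nd):
        for j in range(config.pathognomonic_per_disease):
            symptoms.append(
                SymptomEntry(
                    f"s{idx + 1:03d}",
                    f"pathognomonic marker {j + 1} of {disease_names[i]}",
                    "present_illness",
                )
            )
            weights[idx, i] = rng.uniform(0.86, 0.99)
            idx += 1
    for j in range(n_leaning):
        owner = j % nd
        symptoms.append(
            SymptomEntry(
                f"s{idx + 1:03d}",
                f"sign leaning toward {disease_names[owner]}",
                "present_illness",
            )
        )
        weights[idx] = rng.uniform(0.0, 0.2, size=nd)
        weights[idx, owner] = rng.uniform(0.55, 0.80)
        idx += 1
    for j in range(n_shared):
        symptoms.append(
            SymptomEntry(
                f"s{idx + 1:03d}", f"shared constitutional symptom {j + 1}", "presenting_complaint"
            )
        )
        weights[idx] = rng.uniform(0.10, 0.45, size=nd)
        idx += 1

    return KnowledgeBase(diseases, symptoms, weights)


# ---------------------------------------------------------------------------
# vignette generation
# ---------------------------------------------------------------------------


def _symptom_roles(
    kb: KnowledgeBase,
    disease_id: str,
    pathognomonic_threshold: float,
    leaning_threshold: float,
) -> tuple[list[int], list[int], list[int]]:
    """Indices of (pathognomonic-for-d, leaning-for-d, shared-pool) symptoms."""
    di = kb.disease_index(disease_id)
    col = kb.weights[:, di]
    row_max = kb.weights.max(axis=1)
    path = [i for i in range(len(kb.symptoms)) if col[i] >= pathognomonic_threshold]
    lean = [
        i
        for i in range(len(kb.symptoms))
        if leaning_threshold <= col[i] < pathognomonic_threshold
    ]
    shared = [i for i in range(len(kb.symptoms)) if row_max[i] < leaning_threshold]
    return path, lean, shared


def _gold_differential(kb: KnowledgeBase, disease_id: str, findings) -> Differential:
    """Primary = generating disease; secondaries = next two by posterior.

    Sureties come from renormalizing the three posterior masses with the
    same largest-remainder rule the engine uses, so synthetic gold is
    internally consistent with the planted generative model.
    """
    post = posterior(kb, findings)
    probs = dict(post.entries)
    secondaries = [d for d, _ in post.entries if d != disease_id][:2]
    chosen = [disease_id] + secondaries
    mass = sum(probs[d] for d in chosen)
    shares = [probs[d] / mass for d in chosen] if mass > 0 else [1 / 3] * 3
    sureties = largest_remainder_percentages(shares)
    return Differential(tuple(zip(chosen, sureties)), k=3)


def generate_vignette(
    kb: KnowledgeBase,
    disease_id: str,
    stratum: str,
    rng: np.random.Generator,
    vignette_id: str | None = None,
    pathognomonic_threshold: float = DEFAULT_PATHOGNOMONIC_THRESHOLD,
    leaning_threshold: float = DEFAULT_LEANING_THRESHOLD,
) -> Vignette:
    """Sample one present-finding vignette for a disease under a stratum policy.

    high: at least one pathognomonic symptom of the disease is present
    (plus leaning and shared symptoms sampled by their weights);
    moderate: pathognomonic symptoms excluded, at least one disease-leaning
    symptom present; low: only shared-pool symptoms.  The gold primary is
    the generating disease.
    """
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}")
    di = kb.disease_index(disease_id)
    col = kb.weights[:, di]
    path, lean, shared = _symptom_roles(
        kb, disease_id, pathognomonic_threshold, leaning_threshold
    )

    def bernoulli(indices: list[int]) -> list[int]:
        return [i for i in indices if rng.random() < col[i]]

    def force_one(pool: list[int]) -> int:
        w = col[pool]
        p = w / w.sum() if w.sum() > 0 else None
        return int(rng.choice(pool, p=p))

    if stratum == "high":
        if not path:
            raise ValueError(f"no pathognomonic symptoms for {disease_id}: high stratum unsatisfiable")
        chosen = bernoulli(path)
        if not any(i in chosen for i in path):
            chosen.append(force_one(path))
        chosen += bernoulli(lean) + bernoulli(shared)
    elif stratum == "moderate":
        if not lean:
            raise ValueError(f"no disease-leaning symptoms for {disease_id}: moderate stratum unsatisfiable")
        chosen = bernoulli(lean)
        if not chosen:
            chosen.append(force_one(lean))
        chosen += bernoulli(shared)
    else:  # low
        if not shared:
            raise ValueError("no shared-pool symptoms: low stratum unsatisfiable")
        chosen = bernoulli(shared)
        if not chosen:
            chosen.append(force_one(shared))

    chosen = sorted(set(chosen))
    findings = tuple(Finding(kb.symptoms[i].id, "present") for i in chosen)

    demographics = Demographics(
        age=float(rng.integers(1, 81)),
        sex=str(rng.choice(["female", "male"])),
        presentation_date=f"2019-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}",
    )
    if vignette_id is None:
        vignette_id = f"{disease_id}_{stratum}"
    return Vignette(
        id=vignette_id,
        findings=findings,
        stratum=stratum,
        gold=_gold_differential(kb, disease_id, findings),
        demographics=demographics,
    )


def generate_study(kb: KnowledgeBase, config: GeneratorConfig) -> VignetteSet:
    """Balanced study: every (disease, stratum) cell gets ``vignettes_per_cell``.

    Each vignette draws from its own RNG sub-stream (seeded by disease,
    stratum and replicate indices), so regeneration is stable and
    order-independent.
    """
    vignettes = []
    for di, disease in enumerate(kb.diseases):
        for si, stratum in enumerate(STRATA):
            for r in range(config.vignettes_per_cell):
                rng = np.random.default_rng([config.seed, 1, di, si, r])
                vignettes.append(
                    generate_vignette(
                        kb,
                        disease.id,
                        stratum,
                        rng,
                        vignette_id=f"v_{disease.id}_{stratum}_{r + 1:03d}",
                        pathognomonic_threshold=config.pathognomonic_threshold,
                        leaning_threshold=config.leaning_threshold,
                    )
                )
    return VignetteSet(tuple(vignettes), label=f"synthetic-study-seed{config.seed}")


# ---------------------------------------------------------------------------
# simulated raters
# ---------------------------------------------------------------------------


def simulate_rater(kb: KnowledgeBase, vs: VignetteSet, rater: RaterConfig):
    """Corrupt the engine's differential per vignette at the rater's error rates.

    With probability ``primary_error_rate`` the primary is replaced by a
    uniformly random other disease; with probability
    ``differential_error_rate`` each secondary slot is replaced by a random
    disease not already in the differential.  Slot sureties are retained
    (they sum to 100 by construction).  Deterministic under the rater seed,
    one sub-stream per vignette.
    """
    from ddx.evaluation import PredictionRecord
    from ddx.inference import diagnose

    records = []
    all_ids = kb.disease_ids
    for j, v in enumerate(vs):
        rng = np.random.default_rng([rater.seed, 2, j])
        oracle = diagnose(kb, v, k=3)
        ids = list(oracle.disease_ids)
        sureties = [s for _, s in oracle.items]

        if rng.random() < rater.primary_error_rate:
            candidates = [d for d in all_ids if d != ids[0]]
            new_primary = str(rng.choice(candidates))
            if new_primary in ids[1:]:
                slot = ids.index(new_primary)
                ids[0], ids[slot] = ids[slot], ids[0]
            else:
                ids[0] = new_primary
        for slot in range(1, len(ids)):
            if rng.random() < rater.differential_error_rate:
                candidates = [d for d in all_ids if d not in ids]
                if candidates:
                    ids[slot] = str(rng.choice(candidates))

        records.append(
            PredictionRecord(
                vignette_id=v.id,
                source=rater.label,
                differential=Differential(tuple(zip(ids, sureties)), k=oracle.k),
            )
        )
    return records


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------


def load_simulation_config(path) -> tuple[GeneratorConfig, list[RaterConfig]]:
    """Read a simulate-run YAML: a ``study`` mapping plus optional ``raters`` list."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    study = GeneratorConfig(**(doc.get("study") or {}))
    raters = [RaterConfig(**rec) for rec in (doc.get("raters") or [])]
    return study, raters


def dump_simulation_config(
    config: GeneratorConfig, raters: Sequence[RaterConfig], path
) -> None:
    doc = {
        "study": {
            "n_diseases": config.n_diseases,
            "n_symptoms": config.n_symptoms,
            "pathognomonic_per_disease": config.pathognomonic_per_disease,
            "shared_symptom_fraction": config.shared_symptom_fraction,
            "vignettes_per_cell": config.vignettes_per_cell,
            "pathognomonic_threshold": config.pathognomonic_threshold,
            "leaning_threshold": config.leaning_threshold,
            "seed": config.seed,
        },
        "raters": [
            {
                "label": r.label,
                "primary_error_rate": r.primary_error_rate,
                "differential_error_rate": r.differential_error_rate,
                "seed": r.seed,
            }
            for r in raters
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
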