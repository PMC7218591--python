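"""Symptom-disease knowledge base: the model's sole parameterization.

A :class:`KnowledgeBase` holds a closed, ordered set of diseases with prior
prevalence weights, an ordered set of coded symptoms, and a dense association
matrix ``w(s, d)`` in ``[0, 1]``.  The weight is interpreted as the
probability of the symptom being present given the disease; absent findings
contribute the complement.  Weights are clamped away from 0 and 1 so no
single finding can annihilate a disease (smoothing).

Serialization is JSON (single document) or a CSV pair
(``entities.csv`` + ``weights.csv``) inside a directory; both round-trip
exactly.  The JSON wire format is documented by the JSON-Schema file in
``ddx/schemas/knowledge_base.schema.json``.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from ddx.errors import ValidationError

#: Smoothing floor/ceiling for likelihoods: clamp w(s,d) to [EPS, 1-EPS].
EPS = 1e-6

#: Tolerance on the disease-prior normalization check.
PRIOR_SUM_TOL = 1e-9

SYMPTOM_CATEGORIES = (
    "presenting_complaint",
    "present_illness",
    "medical_history",
    "family_history",
    "personal_history",
    "demographic",
)


@dataclass(frozen=True)
class DiseaseEntry:
    """One disease in the closed differential universe.

    ``prior`` is the prevalence weight pi_d; priors are normalized to sum to
    one on load (see :func:`load_knowledge_base`).
    """

    id: str
    name: str
    prior: float


@dataclass(frozen=True)
class SymptomEntry:
    """One coded finding type, filed under a history-format category."""

    id: str
    name: str
    category: str


@dataclass(frozen=True)
class Violation:
    """A single validation failure: machine code, JSON-pointer-ish location, text."""

    code: str
    location: str
    message: str


class KnowledgeBase:
    """Closed disease set with priors plus a symptom x disease weight matrix.

    Parameters
    ----------
    diseases, symptoms:
        Ordered entries; order is preserved through serialization and fixes
        the rows/columns of ``weights``.
    weights:
        Dense ``(n_symptoms, n_diseases)`` array with entries in ``[0, 1]``.
    """

    def __init__(
        self,
        diseases: Iterable[DiseaseEntry],
        symptoms: Iterable[SymptomEntry],
        weights: np.ndarray,
    ):
        self.diseases = list(diseases)
        self.symptoms = list(symptoms)
        self.weights = np.asarray(weights, dtype=float)
        if self.weights.shape != (len(self.symptoms), len(self.diseases)):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"({len(self.symptoms)} symptoms, {len(self.diseases)} diseases)"
            )
        self._disease_index = {d.id: i for i, d in enumerate(self.diseases)}
        self._symptom_index = {s.id: i for i, s in enumerate(self.symptoms)}

    # -- accessors ---------------------------------------------------------

    @property
    def disease_ids(self) -> list[str]:
        return [d.id for d in self.diseases]

    @property
    def symptom_ids(self) -> list[str]:
        return [s.id for s in self.symptoms]

    @property
    def priors(self) -> np.ndarray:
        return np.array([d.prior for d in self.diseases], dtype=float)

    def disease_index(self, disease_id: str) -> int:
        try:
            return self._disease_index[disease_id]
        except KeyError:
            raise KeyError(f"undeclared disease id: {disease_id!r}") from None

    def symptom_index(self, symptom_id: str) -> int:
        try:
            return self._symptom_index[symptom_id]
        except KeyError:
            raise KeyError(f"undeclared symptom id: {symptom_id!r}") from None

    def has_symptom(self, symptom_id: str) -> bool:
        return symptom_id in self._symptom_index

    def weight(self, symptom_id: str, disease_id: str) -> float:
        """Raw (unclamped) association weight w(s, d)."""
        return float(
            self.weights[self.symptom_index(symptom_id), self.disease_index(disease_id)]
        )

    # -- equality / construction ------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            self.diseases == other.diseases
            and self.symptoms == other.symptoms
            and self.weights.shape == other.weights.shape
            and bool(np.array_equal(self.weights, other.weights))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"KnowledgeBase({len(self.diseases)} diseases, "
            f"{len(self.symptoms)} symptoms)"
        )

    @classmethod
    def from_weight_mapping(
        cls,
        diseases: Iterable[DiseaseEntry],
        symptoms: Iterable[SymptomEntry],
        weights: Mapping[str, Mapping[str, float]],
    ) -> "KnowledgeBase":
        """Build a dense KB from a sparse ``{symptom_id: {disease_id: w}}`` map.

        Cells absent from the mapping default to weight 0 ("no known
        association"); they are clamped to ``EPS`` only at likelihood time.
        Unknown row/column keys raise :class:`ValidationError`.
        """
        diseases = list(diseases)
        symptoms = list(symptoms)
        d_idx = {d.id: i for i, d in enumerate(diseases)}
        s_idx = {s.id: i for i, s in enumerate(symptoms)}
        mat = np.zeros((len(symptoms), len(diseases)), dtype=float)
        violations: list[Violation] = []
        for sid, row in weights.items():
            if sid not in s_idx:
                violations.append(
                    Violation("unknown_symptom", f"/weights/{sid}", "symptom id not declared")
                )
                continue
            for did, w in row.items():
                if did not in d_idx:
                    violations.append(
                        Violation(
                            "unknown_disease", f"/weights/{sid}/{did}", "disease id not declared"
                        )
                    )
                    continue
                mat[s_idx[sid], d_idx[did]] = float(w)
        if violations:
            raise ValidationError("weight matrix references undeclared ids", violations)
        return cls(diseases, symptoms, mat)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_knowledge_base(
    kb: KnowledgeBase, *, require_normalized_priors: bool = True
) -> list[Violation]:
    """Check every structural invariant; return ordered violation records.

    Violations are returned, never raised, and are deterministically ordered
    by location so error reports are stable.  An empty list means the KB is
    valid.  ``require_normalized_priors`` is relaxed by loaders that
    normalize afterwards.
    """
    violations: list[Violation] = []

    seen: set[str] = set()
    for i, d in enumerate(kb.diseases):
        loc = f"/diseases/{i}"
        if not d.id or any(c.isspace() for c in d.id):
            violations.append(Violation("bad_id", loc, f"disease id {d.id!r} is empty or has whitespace"))
        if d.id in seen:
            violations.append(Violation("duplicate_id", loc, f"duplicate disease id {d.id!r}"))
        seen.add(d.id)
        if not (math.isfinite(d.prior) and d.prior >= 0):
            violations.append(Violation("bad_prior", loc, f"prior {d.prior!r} must be finite and >= 0"))

    seen = set()
    for i, s in enumerate(kb.symptoms):
        loc = f"/symptoms/{i}"
        if not s.id or any(c.isspace() for c in s.id):
            violations.append(Violation("bad_id", loc, f"symptom id {s.id!r} is empty or has whitespace"))
        if s.id in seen:
            violations.append(Violation("duplicate_id", loc, f"duplicate symptom id {s.id!r}"))
        seen.add(s.id)
        if s.category not in SYMPTOM_CATEGORIES:
            violations.append(
                Violation("bad_category", loc, f"category {s.category!r} not in {SYMPTOM_CATEGORIES}")
            )

    bad = np.argwhere(~((kb.weights >= 0.0) & (kb.weights <= 1.0)))
    for si, di in bad:
        sid = kb.symptoms[si].id if si < len(kb.symptoms) else str(si)
        did = kb.diseases[di].id if di < len(kb.diseases) else str(di)
        violations.append(
            Violation(
                "weight_out_of_range",
                f"/weights/{sid}/{did}",
                f"weight {kb.weights[si, di]!r} outside [0, 1]",
            )
        )

    if require_normalized_priors and kb.diseases:
        total = float(kb.priors.sum())
        if abs(total - 1.0) > PRIOR_SUM_TOL:
            violations.append(
                Violation("prior_sum", "/diseases", f"priors sum to {total!r}, expected 1")
            )

    violations.sort(key=lambda v: (v.location, v.code))
    return violations


def _normalize_priors(kb: KnowledgeBase) -> KnowledgeBase:
    """Normalize priors to sum one; uniform fallback when all are zero."""
    priors = kb.priors
    if len(priors) == 0:
        return kb
    if np.any(priors < 0):
        return kb  # left for validation to flag
    total = priors.sum()
    if total <= 0:
        normed = np.full(len(priors), 1.0 / len(priors))
    else:
        normed = priors / total
    diseases = [
        DiseaseEntry(d.id, d.name, float(p)) for d, p in zip(kb.diseases, normed)
    ]
    return KnowledgeBase(diseases, kb.symptoms, kb.weights)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("json", "csv"):
            raise ValueError(f"unknown format {format!r}; expected 'json' or 'csv'")
        return format
    if path.suffix.lower() == ".json":
        return "json"
    return "csv"


def load_knowledge_base(path: str | os.PathLike, format: str | None = None) -> KnowledgeBase:
    """Load and validate a knowledge base from JSON or a CSV-pair directory.

    Priors are normalized to sum one after load (a KB omitting priors gets a
    uniform prior).  Weight cells absent from the file default to 0.  Raises
    :class:`ValidationError` carrying every violation found, with
    JSON-pointer-style locations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"knowledge base not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "json":
        kb = _load_json(path)
    else:
        kb = _load_csv(path)
    kb = _normalize_priors(kb)
    violations = validate_knowledge_base(kb)
    if violations:
        raise ValidationError(f"invalid knowledge base in {path}", violations)
    return kb


def _load_json(path: Path) -> KnowledgeBase:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"malformed JSON in {path}: {exc}") from exc
    violations: list[Violation] = []
    if not isinstance(doc, dict):
        raise ValidationError("top-level JSON value must be an object")
    for key in ("diseases", "symptoms"):
        if key not in doc or not isinstance(doc[key], list):
            violations.append(Violation("schema", f"/{key}", "missing or non-array field"))
    if violations:
        raise ValidationError(f"invalid knowledge base schema in {path}", violations)

    diseases = []
    for i, rec in enumerate(doc["diseases"]):
        if not isinstance(rec, dict) or "id" not in rec:
            violations.append(Violation("schema", f"/diseases/{i}", "entry must be an object with an 'id'"))
            continue
        diseases.append(
            DiseaseEntry(str(rec["id"]), str(rec.get("name", rec["id"])), float(rec.get("prior", 0.0)))
        )
    symptoms = []
    for i, rec in enumerate(doc["symptoms"]):
        if not isinstance(rec, dict) or "id" not in rec:
            violations.append(Violation("schema", f"/symptoms/{i}", "entry must be an object with an 'id'"))
            continue
        symptoms.append(
            SymptomEntry(
                str(rec["id"]),
                str(rec.get("name", rec["id"])),
                str(rec.get("category", "presenting_complaint")),
            )
        )
    if violations:
        raise ValidationError(f"invalid knowledge base schema in {path}", violations)

    weights = doc.get("weights", {})
    if not isinstance(weights, dict):
        raise ValidationError(
            "invalid knowledge base schema",
            [Violation("schema", "/weights", "must be an object symptom_id -> disease_id -> number")],
        )
    return KnowledgeBase.from_weight_mapping(diseases, symptoms, weights)


def _load_csv(path: Path) -> KnowledgeBase:
    """Load the CSV pair ``entities.csv`` + ``weights.csv`` from a directory."""
    if not path.is_dir():
        raise ValidationError(
            f"CSV knowledge base path must be a directory holding "
            f"entities.csv and weights.csv: {path}"
        )
    entities = path / "entities.csv"
    weights_file = path / "weights.csv"
    for f in (entities, weights_file):
        if not f.exists():
            raise FileNotFoundError(f"missing knowledge base component: {f}")

    diseases: list[DiseaseEntry] = []
    symptoms: list[SymptomEntry] = []
    with open(entities, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            kind = (row.get("kind") or "").strip()
            if kind == "disease":
                diseases.append(
                    DiseaseEntry(row["id"], row.get("name", row["id"]), float(row["prior_or_category"]))
                )
            elif kind == "symptom":
                symptoms.append(
                    SymptomEntry(row["id"], row.get("name", row["id"]), row["prior_or_category"])
                )
            else:
                raise ValidationError(
                    f"{entities}:{lineno}: unknown entity kind {kind!r} (expected disease|symptom)"
                )

    weight_map: dict[str, dict[str, float]] = {}
    with open(weights_file, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or header[0] != "symptom_id":
            raise ValidationError(
                f"{weights_file}: first header cell must be 'symptom_id'"
            )
        disease_cols = header[1:]
        for row in reader:
            if not row:
                continue
            sid = row[0]
            weight_map[sid] = {
                did: float(cell) for did, cell in zip(disease_cols, row[1:]) if cell != ""
            }
    return KnowledgeBase.from_weight_mapping(diseases, symptoms, weight_map)


def save_knowledge_base(
    kb: KnowledgeBase, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write ``kb`` so that :func:`load_knowledge_base` reproduces it exactly.

    The KB must validate cleanly first; nothing is written otherwise.
    """
    path = Path(path)
    violations = validate_knowledge_base(kb)
    if violations:
        raise ValidationError("refusing to save invalid knowledge base", violations)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = {
            "diseases": [{"id": d.id, "name": d.name, "prior": d.prior} for d in kb.diseases],
            "symptoms": [{"id": s.id, "name": s.name, "category": s.category} for s in kb.symptoms],
            "weights": {
                s.id: {d.id: float(w) for d, w in zip(kb.diseases, row) if w != 0.0}
                for s, row in zip(kb.symptoms, kb.weights)
            },
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
    else:
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "entities.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["kind", "id", "name", "prior_or_category"])
            for d in kb.diseases:
                writer.writerow(["disease", d.id, d.name, repr(d.prior)])
            for s in kb.symptoms:
                writer.writerow(["symptom", s.id, s.name, s.category])
        with open(path / "weights.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["symptom_id"] + kb.disease_ids)
            for s, row in zip(kb.symptoms, kb.weights):
                writer.writerow([s.id] + [repr(float(w)) for w in row])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def likelihood(kb: KnowledgeBase, finding, disease_id: str) -> float:
    """P(finding | disease) under the probability reading of the weights.

    A present finding contributes ``clamp(w(s,d), EPS, 1-EPS)``; an absent
    one contributes the complement.  The clamp guarantees the result is
    strictly inside (0, 1): no single finding can rule a disease fully in or
    out.
    """
    w = kb.weight(finding.symptom_id, disease_id)
    w = min(max(w, EPS), 1.0 - EPS)
    if finding.polarity == "present":
        return w
    if finding.polarity == "absent":
        return 1.0 - w
    raise ValueError(f"unknown polarity {finding.polarity!r}")


def likelihood_row(kb: KnowledgeBase, finding) -> np.ndarray:
    """Vectorized :func:`likelihood` across all diseases, in KB order."""
    row = kb.weights[kb.symptom_index(finding.symptom_id)]
    row = np.clip(row, EPS, 1.0 - EPS)
    if finding.polarity == "present":
        return row
    if finding.polarity == "absent":
        return 1.0 - row
    raise ValueError(f"unknown polarity {finding.polarity!r}")
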