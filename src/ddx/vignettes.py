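"""Coded clinical vignettes and their gold-standard differentials.

A vignette is a structured patient case: optional demographics, a non-empty
list of coded findings, a specificity stratum (how characteristic the
presentation is of the underlying disease: ``high``, ``moderate`` or
``low``), and a gold differential of exactly three diagnoses (one primary +
two differentials) whose percentage sureties sum to 100.

Vignette sets serialize as JSON lines, one object per line with a fixed key
order, so writes are byte-stable and read/write round-trips exactly.  The
wire format is documented in ``ddx/schemas/vignette.schema.json``.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ddx.errors import ValidationError
from ddx.inference import Differential, Finding
from ddx.knowledge_base import Violation

STRATA = ("high", "moderate", "low")
SEXES = ("female", "male", "other")

#: Gold differentials carry exactly one primary and two differential diagnoses.
GOLD_K = 3


@dataclass(frozen=True)
class Demographics:
    """Patient descriptors recorded in the standard history format.

    All optional; the presentation date is metadata only (no seasonality
    modelling).
    """

    age: float | None = None
    sex: str | None = None
    presentation_date: str | None = None  # ISO-8601

    def __post_init__(self):
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class Vignette:
    id: str
    findings: tuple[Finding, ...]
    stratum: str
    gold: Differential
    demographics: Demographics = field(default_factory=Demographics)

    def __post_init__(self):
        if not self.id:
            raise ValueError("vignette id must be non-empty")
        if not self.findings:
            raise ValueError(f"vignette {self.id!r}: findings must be non-empty")
        if self.stratum not in STRATA:
            raise ValueError(f"vignette {self.id!r}: stratum must be one of {STRATA}")
        if self.gold.k != GOLD_K:
            raise ValueError(f"vignette {self.id!r}: gold differential must have k={GOLD_K}")


@dataclass(frozen=True)
class VignetteSet:
    vignettes: tuple[Vignette, ...]
    label: str = ""

    def __post_init__(self):
        seen: set[str] = set()
        for v in self.vignettes:
            if v.id in seen:
                raise ValueError(f"duplicate vignette id {v.id!r}")
            seen.add(v.id)

    def __len__(self) -> int:
        return len(self.vignettes)

    def __iter__(self):
        return iter(self.vignettes)

    def by_id(self) -> dict[str, Vignette]:
        return {v.id: v for v in self.vignettes}


# ---------------------------------------------------------------------------
# JSON-lines serialization
# ---------------------------------------------------------------------------


def _vignette_to_dict(v: Vignette) -> dict:
    demo: dict = {}
    if v.demographics.age is not None:
        demo["age"] = v.demographics.age
    if v.demographics.sex is not None:
        demo["sex"] = v.demographics.sex
    if v.demographics.presentation_date is not None:
        demo["presentation_date"] = v.demographics.presentation_date
    return {
        "id": v.id,
        "demographics": demo,
        "findings": [{"symptom_id": f.symptom_id, "polarity": f.polarity} for f in v.findings],
        "stratum": v.stratum,
        "gold": v.gold.to_json_dict(),
    }


def _vignette_from_dict(doc: dict, where: str) -> Vignette:
    violations: list[Violation] = []
    for key in ("id", "findings", "stratum", "gold"):
        if key not in doc:
            violations.append(Violation("schema", f"{where}/{key}", "missing required field"))
    if violations:
        raise ValidationError(f"invalid vignette at {where}", violations)

    demo_doc = doc.get("demographics", {}) or {}
    try:
        demographics = Demographics(
            age=demo_doc.get("age"),
            sex=demo_doc.get("sex"),
            presentation_date=demo_doc.get("presentation_date"),
        )
        findings = tuple(
            Finding(rec["symptom_id"], rec["polarity"]) for rec in doc["findings"]
        )
        gold = Differential.from_json_dict(doc["gold"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(
            f"invalid vignette at {where}: {exc}",
            [Violation("schema", where, str(exc))],
        ) from exc

    surety_sum = sum(rec["surety"] for rec in doc["gold"]["items"])
    if surety_sum != 100:  # Differential re-checks; this names the line and sum
        raise ValidationError(
            f"invalid vignette at {where}: gold sureties sum to {surety_sum}, expected 100",
            [Violation("gold_surety_sum", where, f"sum is {surety_sum}")],
        )
    try:
        return Vignette(
            id=doc["id"],
            findings=findings,
            stratum=doc["stratum"],
            gold=gold,
            demographics=demographics,
        )
    except ValueError as exc:
        raise ValidationError(
            f"invalid vignette at {where}: {exc}", [Violation("invariant", where, str(exc))]
        ) from exc


def read_vignettes(path: str | os.PathLike) -> VignetteSet:
    """Read a JSON-lines vignette file, attaching line numbers to errors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vignette file not found: {path}")
    vignettes: list[Vignette] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            where = f"{path.name}:{lineno}"
            try:
                doc = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"malformed JSON at {where}: {exc}") from exc
            vignettes.append(_vignette_from_dict(doc, where))
    if not vignettes:
        warnings.warn(f"vignette file {path} is empty", stacklevel=2)
    try:
        return VignetteSet(tuple(vignettes), label=str(path))
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc


def write_vignettes(vs: VignetteSet, path: str | os.PathLike) -> None:
    """Write a vignette set as JSON lines; byte-stable across rewrites.

    The whole set is serialized before the file is touched, so an invalid
    set never leaves a partial file behind.
    """
    lines = [json.dumps(_vignette_to_dict(v), separators=(", ", ": ")) for v in vs]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line)
            fh.write("\n")


def stratify(vs: VignetteSet) -> dict[str, VignetteSet]:
    """Partition by specificity stratum, preserving order within each part."""
    parts: dict[str, list[Vignette]] = {s: [] for s in STRATA}
    for v in vs:
        parts[v.stratum].append(v)
    return {
        s: VignetteSet(tuple(part), label=f"{vs.label}[{s}]") for s, part in parts.items()
    }


def concat(sets: Iterable[VignetteSet], label: str = "") -> VignetteSet:
    out: list[Vignette] = []
    for vs in sets:
        out.extend(vs)
    return VignetteSet(tuple(out), label=label)
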