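"""Posterior disease ranking: naive-Bayes update and surety differentials.

The engine treats diagnosis as multiclass classification over the closed
disease set of a knowledge base.  Under the single-cause assumption, the
posterior after observing a set of findings is

    P(d | findings)  proportional to  pi_d * prod_f P(f | d)

with conditional independence of findings given the disease.  Accumulation
runs in log space (max-subtraction normalization) so long finding lists
cannot underflow.  A ranked differential carries integer percentage surety
values obtained by largest-remainder (Hamilton) rounding, so they always sum
to exactly 100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ddx.errors import ContradictoryFindingsError
from ddx.knowledge_base import KnowledgeBase, likelihood_row

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Finding:
    """One piece of evidence: a symptom code with polarity.

    Unmentioned symptoms are treated as unobserved, not absent — vignettes
    record elicited findings only.
    """

    symptom_id: str
    polarity: str  # "present" | "absent"

    def __post_init__(self):
        if not self.symptom_id:
            raise ValueError("symptom_id must be non-empty")
        if self.polarity not in ("present", "absent"):
            raise ValueError(f"polarity must be 'present' or 'absent', got {self.polarity!r}")


@dataclass(frozen=True)
class PosteriorDistribution:
    """Full posterior over the KB's disease universe.

    ``entries`` is ordered descending by probability with ties broken by
    disease id ascending; probabilities sum to one.  ``findings_used`` /
    ``findings_skipped`` record how many findings matched the KB's symptom
    vocabulary (unknown codes are skipped, not errors).
    """

    entries: tuple[tuple[str, float], ...]
    findings_used: int
    findings_skipped: int

    def probability(self, disease_id: str) -> float:
        for did, p in self.entries:
            if did == disease_id:
                return p
        raise KeyError(disease_id)


@dataclass(frozen=True)
class Differential:
    """Ranked diagnosis shortlist with integer percentage sureties summing to 100.

    The first item is the primary diagnosis.
    """

    items: tuple[tuple[str, int], ...]
    k: int = field(default=0)

    def __post_init__(self):
        if self.k == 0:
            object.__setattr__(self, "k", len(self.items))
        if len(self.items) != self.k:
            raise ValueError(f"k={self.k} but {len(self.items)} items")
        total = sum(s for _, s in self.items)
        if total != 100:
            raise ValueError(f"surety values must sum to 100, got {total}")
        if any((not isinstance(s, (int, np.integer))) or s < 0 for _, s in self.items):
            raise ValueError("surety values must be non-negative integers")

    @property
    def primary(self) -> str:
        return self.items[0][0]

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.items)

    def to_json_dict(self) -> dict:
        return {
            "items": [
                {"disease_id": d, "rank": i + 1, "surety": int(s)}
                for i, (d, s) in enumerate(self.items)
            ],
            "k": self.k,
        }

    @classmethod
    def from_json_dict(cls, doc: dict) -> "Differential":
        items = sorted(doc["items"], key=lambda rec: rec["rank"])
        return cls(tuple((rec["disease_id"], int(rec["surety"])) for rec in items), int(doc["k"]))


def largest_remainder_percentages(shares: Sequence[float], total: int = 100) -> list[int]:
    """Round non-negative shares (summing to ~1) to integers summing to ``total``.

    Hamilton's method: floor everything, then hand out the remaining units in
    order of largest fractional remainder, earlier index winning ties.
    """
    shares = np.asarray(shares, dtype=float)
    if len(shares) == 0:
        raise ValueError("no shares to round")
    scaled = shares * total
    floors = np.floor(scaled).astype(int)
    remainder = total - int(floors.sum())
    # ties in fractional part broken by rank (stable sort on -fraction)
    order = np.argsort(-(scaled - floors), kind="stable")
    out = floors.copy()
    for idx in order[:remainder]:
        out[idx] += 1
    return [int(v) for v in out]


def posterior(kb: KnowledgeBase, findings: Iterable[Finding]) -> PosteriorDistribution:
    """Posterior over the closed disease set given coded findings.

    Findings whose symptom code is unknown to the KB are skipped (with a
    logged warning) and tallied in the result's provenance.  Duplicate
    findings with the same polarity count once; the same symptom reported
    both present and absent raises :class:`ContradictoryFindingsError`.
    An empty finding list returns the priors.
    """
    findings = list(findings)
    by_symptom: dict[str, str] = {}
    for f in findings:
        prev = by_symptom.get(f.symptom_id)
        if prev is not None and prev != f.polarity:
            raise ContradictoryFindingsError(
                f"symptom {f.symptom_id!r} reported both present and absent"
            )
        by_symptom[f.symptom_id] = f.polarity

    used = 0
    skipped = 0
    with np.errstate(divide="ignore"):  # zero priors legitimately map to -inf
        log_post = np.log(kb.priors)
    # canonical order makes the result exactly invariant to finding permutation
    for sid, polarity in sorted(by_symptom.items()):
        if not kb.has_symptom(sid):
            skipped += 1
            logger.warning("skipping finding with unknown symptom id %r", sid)
            continue
        used += 1
        log_post = log_post + np.log(likelihood_row(kb, Finding(sid, polarity)))

    log_post = log_post - np.max(log_post)
    probs = np.exp(log_post)
    probs = probs / probs.sum()

    order = sorted(range(len(probs)), key=lambda i: (-probs[i], kb.diseases[i].id))
    entries = tuple((kb.diseases[i].id, float(probs[i])) for i in order)
    return PosteriorDistribution(entries, findings_used=used, findings_skipped=skipped)


def rank_differentials(post: PosteriorDistribution, k: int) -> Differential:
    """Top-``k`` differential with renormalized, largest-remainder sureties."""
    n = len(post.entries)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    top = post.entries[:k]
    mass = sum(p for _, p in top)
    if mass <= 0:
        shares = [1.0 / k] * k  # degenerate all-zero mass: uniform
    else:
        shares = [p / mass for _, p in top]
    sureties = largest_remainder_percentages(shares)
    return Differential(tuple((d, s) for (d, _), s in zip(top, sureties)), k)


def diagnose(kb: KnowledgeBase, vignette, k: int = 3) -> Differential:
    """Rank the KB's diseases for one vignette: posterior then top-``k`` sureties.

    ``k`` defaults to 3, matching the one-primary-plus-two-differentials
    reporting convention.
    """
    return rank_differentials(posterior(kb, vignette.findings), k)
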