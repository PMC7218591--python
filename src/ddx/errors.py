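"""Exception types shared across the package."""

from __future__ import annotations


class DdxError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DdxError):
    """An artifact (knowledge base, vignette file, ...) violates its contract.

    Carries the structured violation records so callers (and the CLI) can
    report every problem, not just the first.
    """

    def __init__(self, message: str, violations=()):
        super().__init__(message)
        self.violations = list(violations)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        if not self.violations:
            return base
        lines = [base]
        for v in self.violations:
            lines.append(f"  [{v.code}] {v.location}: {v.message}")
        return "\n".join(lines)


class ContradictoryFindingsError(DdxError):
    """The same symptom was reported both present and absent."""


class CoverageError(DdxError):
    """A prediction source does not cover every vignette under evaluation."""

    def __init__(self, message: str, missing_by_source=None):
        super().__init__(message)
        self.missing_by_source = dict(missing_by_source or {})
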