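"""Receptor-binding protein (RBP) cataloguing.

Phage receptor-binding proteins — tail fibers, tailspikes and related
adhesins — determine which bacterial host a phage can adsorb to.  This module
identifies RBP candidates among annotated phage proteins by matching gene
product annotations against a configurable rule set, routes ``hypothetical``
records to an external-decision side channel, discards records with outlying
sequence lengths (Tukey fences on the length distribution), and removes exact
duplicate sequences.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import ConfigError, InsufficientDataError

__all__ = [
    "AnnotationDecision",
    "AnnotationRuleSet",
    "LengthStats",
    "ProteinRecord",
    "classify_annotation",
    "compute_length_stats",
    "deduplicate",
    "filter_length_outliers",
    "load_default_rules",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, source phage, annotation text and sequence.

    ``host_genus`` is the training label when known; ``None`` for unlabeled
    records and the string ``"OUTGROUP"`` for hosts outside the genera of
    interest.
    """

    id: str
    phage_id: str
    product: str
    sequence: str
    host_genus: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


class AnnotationDecision(enum.Enum):
    RBP = "RBP"
    EXCLUDED = "EXCLUDED"
    HYPOTHETICAL = "HYPOTHETICAL"
    OTHER = "OTHER"


def _compile(patterns: Sequence[str], kind: str) -> list[re.Pattern]:
    compiled = []
    for pat in patterns:
        try:
            compiled.append(re.compile(pat, re.IGNORECASE))
        except re.error as exc:
            raise ConfigError(f"invalid {kind} pattern {pat!r}: {exc}") from exc
    return compiled


@dataclass
class AnnotationRuleSet:
    """Case-insensitive regex patterns deciding RBP candidacy.

    Inclusion patterns nominate a record as an RBP; exclusion patterns veto
    records whose annotation is RBP-adjacent but not an RBP itself (the veto
    applies only to inclusion matches); hypothetical patterns route
    unannotated records to an external RBP detector.
    """

    inclusion_patterns: list[str]
    exclusion_patterns: list[str]
    hypothetical_patterns: list[str]
    _inclusion: list[re.Pattern] = field(init=False, repr=False)
    _exclusion: list[re.Pattern] = field(init=False, repr=False)
    _hypothetical: list[re.Pattern] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._inclusion = _compile(self.inclusion_patterns, "inclusion")
        self._exclusion = _compile(self.exclusion_patterns, "exclusion")
        self._hypothetical = _compile(self.hypothetical_patterns, "hypothetical")

    @classmethod
    def from_yaml(cls, path) -> "AnnotationRuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"rule file {path}: expected a mapping")
        unknown = set(raw) - {"inclusion", "exclusion", "hypothetical"}
        if unknown:
            raise ConfigError(f"rule file {path}: unknown keys {sorted(unknown)}")
        for key in ("inclusion", "exclusion", "hypothetical"):
            if not raw.get(key):
                raise ConfigError(f"rule file {path}: section {key!r} missing or empty")
        return cls(
            inclusion_patterns=list(raw["inclusion"]),
            exclusion_patterns=list(raw["exclusion"]),
            hypothetical_patterns=list(raw["hypothetical"]),
        )


def load_default_rules() -> AnnotationRuleSet:
    """Load the annotation rule set shipped with the package."""
    with resources.as_file(resources.files("phistruct.data") / "rules.yaml") as p:
        return AnnotationRuleSet.from_yaml(p)


def classify_annotation(product: str, rules: AnnotationRuleSet) -> AnnotationDecision:
    """Classify a free-text product annotation.

    Exclusion wins over inclusion; HYPOTHETICAL is returned only when no
    inclusion pattern matched. Pure function of (product, rules).
    """
    included = any(p.search(product) for p in rules._inclusion)
    if included:
        if any(p.search(product) for p in rules._exclusion):
            return AnnotationDecision.EXCLUDED
        return AnnotationDecision.RBP
    if any(p.search(product) for p in rules._hypothetical):
        return AnnotationDecision.HYPOTHETICAL
    return AnnotationDecision.OTHER


@dataclass(frozen=True)
class LengthStats:
    """Tukey-fence summary of a length distribution.

    Quartiles use linear interpolation between order statistics (the "type 7"
    convention); the fences are ``q1 - 1.5*iqr`` and ``q3 + 1.5*iqr``.
    """

    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + 1.5 * self.iqr


def compute_length_stats(lengths: Iterable[int]) -> LengthStats:
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size < 4:
        raise InsufficientDataError(
            f"need at least 4 lengths for quartile fences, got {arr.size}"
        )
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    return LengthStats(q1=float(q1), q3=float(q3))


def filter_length_outliers(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], list[ProteinRecord], LengthStats]:
    """Drop records whose length falls outside the Tukey fences.

    Endpoints are inclusive: a record exactly on a fence is kept. Order is
    preserved in both output lists.
    """
    if not records:
        raise InsufficientDataError("no records to filter")
    stats = compute_length_stats(len(r) for r in records)
    kept, removed = [], []
    for rec in records:
        (kept if stats.lower <= len(rec) <= stats.upper else removed).append(rec)
    return kept, removed, stats


def deduplicate(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Remove exact-sequence duplicates, keeping the first occurrence.

    Near-duplicate collapsing is the job of identity clustering (simsplit);
    this is the cheap exact pass.
    """
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(rec)
    return out
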