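"""Abstraction levels: harmonizing terms of uneven specificity.

An *abstraction level* is the subset of terms whose information content lies
in a half-open range ``[ic_min, ic_max)``.  Terms inside the range represent
themselves; terms more specific than the range (IC >= ic_max) are aggregated
— independently along each of their tree-number paths — into the nearest
(deepest) ancestor whose IC falls in range, with the union taken across
paths; terms more general than the range, or specific terms with no in-range
ancestor on any path, are excluded.  Because IC is monotone non-increasing
toward the root, the first in-range ancestor met while walking up a path is
the nearest one.

The fixed-tree-level alternative maps every term to its level-k tree-number
prefixes instead, which is the classical "pick the 2nd MeSH level" strategy.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ValidationError
from .terminology import Terminology, tree_level

__all__ = [
    "AbstractionLevel",
    "CoverageReport",
    "build_abstraction_level",
    "build_tree_level",
    "apply_level",
    "write_level",
]


@dataclass(frozen=True)
class AbstractionLevel:
    """A term → representative-set mapping.

    ``mapping`` sends every considered original term to the set of
    representatives standing in for it (empty set = excluded).  Exactly one
    of the IC range or ``level`` is set, depending on how the level was
    built.
    """

    mapping: dict[str, frozenset[str]]
    representatives: frozenset[str]
    ic_min: float | None = None
    ic_max: float | None = None
    level: int | None = None

    def map_term(self, term: str) -> frozenset[str]:
        """Representatives of `term`; empty when excluded or unknown."""
        return self.mapping.get(term, frozenset())

    @property
    def excluded(self) -> frozenset[str]:
        return frozenset(t for t, reps in self.mapping.items() if not reps)


@dataclass(frozen=True)
class CoverageReport:
    """Which original terms survived the rewrite and which were dropped."""

    covered: frozenset[str]
    excluded: frozenset[str]

    @property
    def n_covered(self) -> int:
        return len(self.covered)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def build_abstraction_level(
    terminology: Terminology,
    ic: Mapping[str, float],
    ic_min: float,
    ic_max: float,
) -> AbstractionLevel:
    """Construct the IC-range abstraction level ``[ic_min, ic_max)``.

    Terms without an IC value (never annotated in the reference set) are
    excluded: their specificity is unknown, so they cannot be placed.
    """
    if ic_min >= ic_max:
        raise ValidationError(f"ic_min ({ic_min}) must be < ic_max ({ic_max})")

    def in_range(value: float) -> bool:
        return ic_min <= value < ic_max

    mapping: dict[str, frozenset[str]] = {}
    terms = {d.descriptor_id for d in terminology} | set(ic)
    for term in terms:
        value = ic.get(term)
        if value is None or value < ic_min:
            mapping[term] = frozenset()
            continue
        if in_range(value):
            mapping[term] = frozenset({term})
            continue
        # too specific: aggregate per tree-number path to the nearest
        # (deepest) in-range ancestor, union across paths
        descriptor = terminology.get(term)
        reps: set[str] = set()
        if descriptor is not None:
            for tn in descriptor.tree_numbers:
                for anc in terminology.ancestor_chain(tn):
                    anc_ic = ic.get(anc)
                    if anc_ic is not None and in_range(anc_ic):
                        reps.add(anc)
                        break
        mapping[term] = frozenset(reps)

    representatives = frozenset(t for t, v in ic.items() if in_range(v))
    return AbstractionLevel(
        mapping=mapping, representatives=representatives, ic_min=ic_min, ic_max=ic_max
    )


def build_tree_level(terminology: Terminology, level: int) -> AbstractionLevel:
    """Map every term to its level-`level` tree-number prefix ancestors
    (itself if already at that level); terms whose tree numbers are all
    shallower than `level` are excluded."""
    if level < 1:
        raise ValidationError(f"tree level must be >= 1, got {level}")
    mapping: dict[str, frozenset[str]] = {}
    representatives: set[str] = set()
    for descriptor in terminology:
        reps: set[str] = set()
        for tn in descriptor.tree_numbers:
            if tree_level(tn) < level:
                continue
            prefix = ".".join(tn.split(".")[:level])
            rep = terminology.resolve_tree_number(prefix)
            if rep is not None:
                reps.add(rep)
        mapping[descriptor.descriptor_id] = frozenset(reps)
        representatives |= reps
    return AbstractionLevel(
        mapping=mapping, representatives=frozenset(representatives), level=level
    )


def apply_level(
    events: Iterable[tuple[str, str]],
    level: AbstractionLevel,
) -> tuple[dict[str, frozenset[str]], CoverageReport]:
    """Rewrite (article, term) events onto representatives.

    Returns the per-representative article sets — an article contributes at
    most once per representative, however many of its original terms map
    there — and a coverage report of covered vs. excluded original terms.
    """
    rep_articles: dict[str, set[str]] = defaultdict(set)
    covered: set[str] = set()
    excluded: set[str] = set()
    for article, term in events:
        reps = level.map_term(term)
        if reps:
            covered.add(term)
            for rep in reps:
                rep_articles[rep].add(article)
        else:
            excluded.add(term)
    report = CoverageReport(frozenset(covered), frozenset(excluded))
    return {r: frozenset(a) for r, a in rep_articles.items()}, report


def write_level(level: AbstractionLevel, path: str | Path) -> None:
    """Export TSV: ``original_id<TAB>representative_ids(;)<TAB>status`` with
    status one of self / aggregated / excluded."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("# original_id\trepresentative_ids\tstatus\n")
        for term in sorted(level.mapping):
            reps = level.mapping[term]
            if not reps:
                status = "excluded"
            elif reps == frozenset({term}):
                status = "self"
            else:
                status = "aggregated"
            handle.write(f"{term}\t{';'.join(sorted(reps))}\t{status}\n")
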