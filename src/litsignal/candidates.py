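"""Candidate drug–event extraction and the per-drug set of interest.

Within each article, candidate adverse-drug-event pairs are the cross
product of the descriptors qualified as drugs ("adverse effects") and those
qualified as event manifestations ("chemically induced").  Drugs are
identified by their unique ingredient through the drug map; ATC codes serve
only to group ingredients into 4th-level classes (one ingredient may carry
several ATC codes, e.g. a systemic and a topical one).

The *set of interest* for a subject (an ingredient, or an ATC4 class
pooling its member ingredients) is the set of articles pairing the subject
with any qualified event, together with per-representative event counts
after abstraction-level rewriting.  All qualified events on a supporting
article contribute to the subject's profile, since enrichment is computed
over the annotation profile of the article set, not over single pairs.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .abstraction import AbstractionLevel, CoverageReport, apply_level
from .corpus import AnnotationCorpus
from .errors import ParseError, UnknownSubjectError

log = logging.getLogger(__name__)

DEFAULT_DRUG_QUALIFIERS = ("adverse effects", "ae")
DEFAULT_EVENT_QUALIFIERS = ("chemically induced", "ci")


@dataclass(frozen=True)
class CandidatePair:
    """One supporting article linking a drug to a candidate adverse event."""

    drug: str
    event: str
    article_id: str


class DrugMap:
    """MeSH drug ID ↔ ingredient ↔ ATC5 code mapping.

    ATC4 classes are pure 5-character prefixes of ATC5 codes.
    """

    def __init__(self, rows: Iterable[tuple[str, str, str]]) -> None:
        self.mesh_to_ingredient: dict[str, str] = {}
        self.ingredient_atc5: dict[str, set[str]] = defaultdict(set)
        for mesh_id, ingredient, atc5 in rows:
            self.mesh_to_ingredient[mesh_id] = ingredient
            if atc5:
                self.ingredient_atc5[ingredient].add(atc5)
            else:
                self.ingredient_atc5.setdefault(ingredient, set())
        self.ingredient_atc5 = dict(self.ingredient_atc5)

    @property
    def ingredients(self) -> frozenset[str]:
        return frozenset(self.ingredient_atc5)

    @property
    def atc4_classes(self) -> frozenset[str]:
        return frozenset(
            code[:5] for codes in self.ingredient_atc5.values() for code in codes
        )

    def classes_of(self, ingredient: str) -> frozenset[str]:
        """Distinct ATC4 prefixes of the ingredient's ATC5 codes."""
        try:
            codes = self.ingredient_atc5[ingredient]
        except KeyError:
            raise UnknownSubjectError(ingredient) from None
        return frozenset(code[:5] for code in codes)

    def members_of(self, atc4_class: str) -> frozenset[str]:
        """Ingredients carrying at least one ATC5 code in the class."""
        return frozenset(
            ing
            for ing, codes in self.ingredient_atc5.items()
            if any(code[:5] == atc4_class for code in codes)
        )


def drug_to_classes(ingredient: str, drug_map: DrugMap) -> frozenset[str]:
    """ATC4 classes of an ingredient (lookup error when unknown)."""
    return drug_map.classes_of(ingredient)


def load_drug_map(path: str | Path) -> DrugMap:
    """Read the drug-map TSV: ``mesh_drug_id<TAB>ingredient_id<TAB>atc5_code``."""
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected mesh_drug_id, ingredient_id, atc5_code")
            rows.append((fields[0], fields[1], fields[2]))
    return DrugMap(rows)


def write_drug_map(drug_map: DrugMap, path: str | Path) -> None:
    path = Path(path)
    inverse = sorted(drug_map.mesh_to_ingredient.items())
    with path.open("w", encoding="utf-8") as handle:
        handle.write("# mesh_drug_id\tingredient_id\tatc5_code\n")
        for mesh_id, ingredient in inverse:
            codes = sorted(drug_map.ingredient_atc5.get(ingredient, ())) or [""]
            for code in codes:
                handle.write(f"{mesh_id}\t{ingredient}\t{code}\n")


# -- extraction ----------------------------------------------------------------


def extract_candidate_pairs(
    corpus: AnnotationCorpus,
    drug_map: DrugMap | None = None,
    drug_qualifiers: Iterable[str] = DEFAULT_DRUG_QUALIFIERS,
    event_qualifiers: Iterable[str] = DEFAULT_EVENT_QUALIFIERS,
) -> frozenset[CandidatePair]:
    """Per-article cross product of qualified drugs × qualified events.

    When a drug map is supplied, drugs are restricted to mapped MeSH IDs and
    reported as ingredients; otherwise the raw descriptor ID is the subject.
    Qualifier strings are matched case-insensitively against alias lists.
    """
    drugs_by_article: dict[str, set[str]] = defaultdict(set)
    events_by_article: dict[str, set[str]] = defaultdict(set)
    for article, descriptor in corpus.qualified(drug_qualifiers):
        if drug_map is not None:
            ingredient = drug_map.mesh_to_ingredient.get(descriptor)
            if ingredient is None:
                continue
            drugs_by_article[article].add(ingredient)
        else:
            drugs_by_article[article].add(descriptor)
    for article, descriptor in corpus.qualified(event_qualifiers):
        events_by_article[article].add(descriptor)

    pairs: set[CandidatePair] = set()
    for article, drugs in drugs_by_article.items():
        for drug in drugs:
            for event in events_by_article.get(article, ()):
                pairs.add(CandidatePair(drug, event, article))
    return frozenset(pairs)


def write_candidate_pairs(pairs: Iterable[CandidatePair], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("# drug\tevent\tarticle_id\n")
        for pair in sorted(pairs, key=lambda p: (p.drug, p.event, p.article_id)):
            handle.write(f"{pair.drug}\t{pair.event}\t{pair.article_id}\n")


def load_candidate_pairs(path: str | Path) -> frozenset[CandidatePair]:
    path = Path(path)
    pairs: set[CandidatePair] = set()
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected drug, event, article_id")
            pairs.add(CandidatePair(fields[0], fields[1], fields[2]))
    return frozenset(pairs)


# -- set of interest -----------------------------------------------------------


@dataclass(frozen=True)
class SetOfInterest:
    """Articles supporting a subject plus its event profile at a level.

    ``rep_articles[x]`` is the set of supporting articles annotated with a
    qualified event mapping to representative ``x``; its size is the
    observed count ``m`` for the enrichment test, and ``s`` is the number of
    supporting articles.
    """

    subject: str
    articles: frozenset[str]
    rep_articles: dict[str, frozenset[str]]
    coverage: CoverageReport

    @property
    def s(self) -> int:
        return len(self.articles)

    @property
    def event_counts(self) -> dict[str, int]:
        return {rep: len(arts) for rep, arts in self.rep_articles.items()}


def build_set_of_interest(
    subject: str,
    pairs: Iterable[CandidatePair],
    corpus: AnnotationCorpus,
    level: AbstractionLevel,
    drug_map: DrugMap | None = None,
    event_qualifiers: Iterable[str] = DEFAULT_EVENT_QUALIFIERS,
) -> SetOfInterest:
    """Assemble the set of interest for an ingredient or an ATC4 class.

    A class subject pools the articles of all its member ingredients.  A
    subject with zero supporting articles yields an empty set of interest,
    which downstream reads as "no signal".
    """
    if drug_map is not None and subject in drug_map.atc4_classes:
        members = drug_map.members_of(subject)
    else:
        members = frozenset({subject})
    articles = frozenset(p.article_id for p in pairs if p.drug in members)
    events = (
        (article, descriptor)
        for article, descriptor in corpus.qualified(event_qualifiers)
        if article in articles
    )
    rep_articles, coverage = apply_level(events, level)
    return SetOfInterest(
        subject=subject, articles=articles, rep_articles=rep_articles, coverage=coverage
    )
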