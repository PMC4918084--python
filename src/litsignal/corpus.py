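"""Reference annotation statistics: aggregated article sets, term
probabilities, information content and pairwise co-frequencies.

The reference corpus plays the role MEDLINE plays for drug-safety literature
mining: every article is indexed with descriptor/qualifier pairs, and a
term's background frequency is the number of distinct articles annotated
with the term *or any of its descendants*, obtained by propagating each
article ID to all ancestors along the tree-number hierarchy.  Information
content is ``IC(t) = -log2 p(t)`` with ``p(t) = |a(t)| / n`` over the
aggregated sets, so general terms get low IC and specific ones high IC.
Pairwise co-frequencies ``|a(x) ∩ a(y)|`` quantify known dependencies
between terms (hierarchical or co-morbid) and feed the conditional
enrichment correction.

Qualifiers are deliberately ignored here: background frequencies are
computed over all indexing, not qualified subsets.
"""

from __future__ import annotations

import json
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import ParseError, ValidationError
from .terminology import Terminology

log = logging.getLogger(__name__)

STATS_FORMAT_VERSION = 1


@dataclass(frozen=True)
class AnnotationCorpus:
    """Deduplicated (article, descriptor, qualifier) triples plus the
    article universe (which may include unannotated articles)."""

    records: frozenset[tuple[str, str, str]]
    article_universe: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", frozenset(self.records))
        seen = {r[0] for r in self.records}
        object.__setattr__(
            self, "article_universe", frozenset(self.article_universe) | seen
        )

    @property
    def n_articles(self) -> int:
        return len(self.article_universe)

    def qualified(self, qualifiers: Iterable[str]) -> Iterator[tuple[str, str]]:
        """Yield (article_id, descriptor_id) for records whose qualifier
        matches one of `qualifiers` case-insensitively."""
        wanted = {q.casefold() for q in qualifiers}
        for article, descriptor, qualifier in self.records:
            if qualifier.casefold() in wanted:
                yield article, descriptor

    def annotations(self) -> Iterator[tuple[str, str]]:
        """Yield all (article_id, descriptor_id) pairs, qualifiers dropped."""
        for article, descriptor, _ in self.records:
            yield article, descriptor


def load_annotations(path: str | Path) -> AnnotationCorpus:
    """Read the annotation TSV: ``article_id<TAB>descriptor_id<TAB>qualifier``.

    The qualifier column may be empty.  A row with an empty descriptor field
    registers the article in the universe without adding an annotation,
    which lets corpora with unannotated articles round-trip through the
    format.
    """
    path = Path(path)
    records: set[tuple[str, str, str]] = set()
    universe: set[str] = set()
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                fields.append("")
            if len(fields) < 3 or not fields[0]:
                raise ParseError(f"{path}:{lineno}: expected article_id, descriptor_id, qualifier")
            article, descriptor, qualifier = fields[0], fields[1], fields[2]
            universe.add(article)
            if descriptor:
                records.add((article, descriptor, qualifier))
    return AnnotationCorpus(frozenset(records), frozenset(universe))


def write_annotations(corpus: AnnotationCorpus, path: str | Path) -> None:
    path = Path(path)
    annotated = {r[0] for r in corpus.records}
    with path.open("w", encoding="utf-8") as handle:
        handle.write("# article_id\tdescriptor_id\tqualifier\n")
        for article, descriptor, qualifier in sorted(corpus.records):
            handle.write(f"{article}\t{descriptor}\t{qualifier}\n")
        for article in sorted(corpus.article_universe - annotated):
            handle.write(f"{article}\t\t\n")


# -- aggregation and statistics ----------------------------------------------


def aggregate_article_sets(
    corpus: AnnotationCorpus, terminology: Terminology
) -> dict[str, frozenset[str]]:
    """Ancestor-propagated article sets ``a(t)``.

    Whenever an article is indexed with a term, its ID is added to the
    article set of every ancestor of that term, so ``a(t)`` covers the term
    and all its descendants.  Descriptors absent from the terminology pass
    through as orphan leaves with their raw sets (and a warning).
    """
    raw: dict[str, set[str]] = defaultdict(set)
    for article, descriptor in corpus.annotations():
        raw[descriptor].add(article)

    aggregated: dict[str, set[str]] = defaultdict(set)
    orphans = 0
    for descriptor, articles in raw.items():
        aggregated[descriptor] |= articles
        if descriptor in terminology:
            for anc in terminology.ancestors(descriptor):
                aggregated[anc] |= articles
        else:
            orphans += 1
    if orphans:
        log.warning(
            "%d annotated descriptor(s) absent from the terminology; "
            "retained as leaf orphans with zero ancestors", orphans
        )
    return {t: frozenset(a) for t, a in aggregated.items()}


def information_content(term_counts: Mapping[str, int], n_total: int) -> dict[str, float]:
    """``IC(t) = -log2(|a(t)| / n)`` for every term with a positive count;
    terms never annotated carry no IC (absent from the map)."""
    if n_total <= 0:
        raise ValidationError("reference set is empty: total article count is 0")
    return {
        t: -math.log2(c / n_total) for t, c in term_counts.items() if c > 0
    }


def cofrequency_table(
    term_articles: Mapping[str, frozenset[str]],
) -> dict[tuple[str, str], int]:
    """Sparse symmetric co-frequency table over aggregated article sets.

    Stores ``|a(x) ∩ a(y)|`` for every unordered pair with a non-empty
    intersection, keyed by the lexicographically sorted pair; absent pairs
    mean zero.  Built through an article→terms inverted index so only
    co-occurring pairs are ever touched.
    """
    by_article: dict[str, list[str]] = defaultdict(list)
    for term, articles in term_articles.items():
        for article in articles:
            by_article[article].append(term)
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for terms in by_article.values():
        for x, y in combinations(sorted(terms), 2):
            counts[(x, y)] += 1
    return dict(counts)


@dataclass
class ReferenceStats:
    """Aggregated reference statistics, the "build once, analyze many"
    artifact behind every enrichment run.

    `term_articles` is present only when the stats were built in-memory from
    a corpus; stats loaded from a serialized directory carry counts and
    co-frequencies only, which is all signal detection needs.
    """

    n: int
    term_counts: dict[str, int]
    cofreq: dict[tuple[str, str], int] = field(default_factory=dict)
    term_articles: dict[str, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("reference set must contain at least one article")

    def count(self, term: str) -> int:
        return self.term_counts.get(term, 0)

    def cofreq_count(self, x: str, y: str) -> int:
        if x == y:
            return self.count(x)
        key = (x, y) if x < y else (y, x)
        return self.cofreq.get(key, 0)

    @property
    def probability(self) -> dict[str, float]:
        return {t: c / self.n for t, c in self.term_counts.items() if c > 0}

    @property
    def ic(self) -> dict[str, float]:
        return information_content(self.term_counts, self.n)


def build_reference_stats(
    corpus: AnnotationCorpus,
    terminology: Terminology,
    with_cofreq: bool = True,
) -> ReferenceStats:
    """Aggregate a corpus into :class:`ReferenceStats`.

    The reference size ``n`` is the size of the article universe.
    """
    term_articles = aggregate_article_sets(corpus, terminology)
    n = corpus.n_articles
    if n == 0:
        raise ValidationError("cannot build reference stats from an empty corpus")
    counts = {t: len(a) for t, a in term_articles.items()}
    cofreq = cofrequency_table(term_articles) if with_cofreq else {}
    log.info(
        "reference stats: %d articles, %d annotated terms, %d stored co-frequency pairs",
        n, len(counts), len(cofreq),
    )
    return ReferenceStats(n=n, term_counts=counts, cofreq=cofreq, term_articles=term_articles)


# -- serialization -------------------------------------------------------------


def save_stats(stats: ReferenceStats, directory: str | Path) -> None:
    """Persist counts to a directory of TSVs plus a meta.json header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "term_counts.tsv").open("w", encoding="utf-8") as handle:
        handle.write("# term\tcount\n")
        for term in sorted(stats.term_counts):
            handle.write(f"{term}\t{stats.term_counts[term]}\n")
    with (directory / "pair_counts.tsv").open("w", encoding="utf-8") as handle:
        handle.write("# term_x\tterm_y\tcount\n")
        for (x, y) in sorted(stats.cofreq):
            handle.write(f"{x}\t{y}\t{stats.cofreq[(x, y)]}\n")
    meta = {
        "format_version": STATS_FORMAT_VERSION,
        "n_articles": stats.n,
        "n_terms": len(stats.term_counts),
        "n_pairs": len(stats.cofreq),
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")


def load_stats(directory: str | Path) -> ReferenceStats:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
    if meta.get("format_version") != STATS_FORMAT_VERSION:
        raise ValidationError(
            f"stats directory {directory} has format_version "
            f"{meta.get('format_version')!r}; expected {STATS_FORMAT_VERSION}"
        )
    counts: dict[str, int] = {}
    with (directory / "term_counts.tsv").open(encoding="utf-8") as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            term, count = line.rstrip("\n").split("\t")
            counts[term] = int(count)
    cofreq: dict[tuple[str, str], int] = {}
    with (directory / "pair_counts.tsv").open(encoding="utf-8") as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            x, y, count = line.rstrip("\n").split("\t")
            cofreq[(x, y)] = int(count)
    return ReferenceStats(n=int(meta["n_articles"]), term_counts=counts, cofreq=cofreq)
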