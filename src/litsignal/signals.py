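"""Enrichment and disproportionality signal statistics.

Two detectors share one result shape:

* **Enrichment (GEA).**  Step 1 scores each representative event term x with
  the inclusive hypergeometric upper tail ``P(X >= m)`` for
  ``X ~ Hypergeometric(n, a, s)`` — the chance of seeing m or more of the
  subject's s supporting articles annotated with x when a of the n
  reference articles are.  Step 2 corrects for dependencies among enriched
  terms: for every other enriched term y that co-occurs with x in the
  reference set, a conditional p-value asks how surprising the joint counts
  are given y (population a_y, successes a_xy, draws o), and the adjusted
  p-value is the maximum of the raw p and all pairwise conditional
  p-values.  A term that is only enriched because a co-occurring partner
  drags it along (a redundant ancestor, a multi-classified sibling) thereby
  loses significance.

* **PRR.**  The proportional reporting ratio over the 2x2 contingency table
  of drug-mention × event-mention article counts within the candidate
  universe, with the usual 0.5 zero-cell correction and a log-scale Wald
  95% confidence interval.  For a drug class, the "drug" margin pools
  articles mentioning any member ingredient against articles mentioning any
  other drug.

Tail sums are computed in exact integer arithmetic (binomial coefficients
over Python big integers, one final correctly-rounded division), never as
``1 - CDF``, so extreme tails keep full relative accuracy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

from .abstraction import AbstractionLevel, apply_level
from .candidates import (
    DEFAULT_EVENT_QUALIFIERS,
    CandidatePair,
    DrugMap,
    SetOfInterest,
    build_set_of_interest,
)
from .corpus import AnnotationCorpus, ReferenceStats
from .errors import ValidationError
from .terminology import Terminology

log = logging.getLogger(__name__)

#: GEA p-value thresholds and PRR thresholds swept in reports.
DEFAULT_P_THRESHOLDS = (0.1, 0.05, 0.005)
DEFAULT_PRR_THRESHOLDS = (1.0, 1.5, 5.0)
#: First-stage eligibility threshold: the loosest reporting threshold.
DEFAULT_ALPHA1 = 0.1


def hypergeom_upper_tail(n: int, a: int, s: int, m: int) -> float:
    """Inclusive upper tail ``P(X >= m)``, ``X ~ Hypergeometric(n, a, s)``.

    `n` population size, `a` marked items, `s` draws, `m` observed marked
    draws.  Returns 1.0 when m == 0.
    """
    for name, value in (("n", n), ("a", a), ("s", s), ("m", m)):
        if value < 0:
            raise ValidationError(f"{name} must be non-negative, got {value}")
    if a > n or s > n:
        raise ValidationError(f"a ({a}) and s ({s}) must not exceed n ({n})")
    if m > min(a, s):
        raise ValidationError(f"m ({m}) exceeds min(a, s) = {min(a, s)}")
    if m == 0:
        return 1.0
    numerator = sum(
        math.comb(a, k) * math.comb(n - a, s - k) for k in range(m, min(a, s) + 1)
    )
    return float(Fraction(numerator, math.comb(n, s)))


def conditional_p(a_y: int, a_xy: int, o: int, m_xy: int) -> float:
    """Conditional enrichment p-value of term x given co-occurring term y.

    ``P(X >= m_xy)`` for ``X ~ Hypergeometric(a_y, a_xy, o)``: among the a_y
    reference articles annotated with y, a_xy also carry x; o articles of
    the set of interest carry y; how surprising is it that m_xy of those
    carry x as well?  Structurally the same test as
    :func:`hypergeom_upper_tail` with the y-annotated articles as the
    population.
    """
    if a_y <= 0:
        raise ValidationError("conditioning term has zero reference count")
    if a_xy < 1:
        raise ValidationError("conditioning requires a reference co-count >= 1")
    return hypergeom_upper_tail(n=a_y, a=a_xy, s=o, m=m_xy)


def adjusted_pvalues(
    raw_p: Mapping[str, float],
    stats: ReferenceStats,
    soi: SetOfInterest,
) -> dict[str, float]:
    """Max-rule pairwise conditional adjustment over the enriched terms.

    `raw_p` holds the step-1 p-values of the enriched terms only.  For each
    term x, the adjusted p is the maximum of its raw p and its conditional
    p against every other enriched term y with a positive reference
    co-count; a term with no eligible partner keeps its raw p.
    """
    adjusted: dict[str, float] = {}
    for x, p_x in raw_p.items():
        articles_x = soi.rep_articles.get(x, frozenset())
        worst = p_x
        for y in raw_p:
            if y == x:
                continue
            a_xy = stats.cofreq_count(x, y)
            if a_xy < 1:
                continue
            articles_y = soi.rep_articles.get(y, frozenset())
            o = len(articles_y)
            m_xy = len(articles_x & articles_y)
            worst = max(worst, conditional_p(stats.count(y), a_xy, o, m_xy))
        adjusted[x] = worst
    return adjusted


# -- PRR -----------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 article counts: a = drug & event, b = drug only, c = event only,
    d = neither."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")


def prr(table: ContingencyTable) -> tuple[float, float, float]:
    """Proportional reporting ratio with 95% CI.

    ``PRR = (a/(a+b)) / (c/(c+d))``.  If any cell is zero, 0.5 is first
    added to all four cells.  The CI is the log-scale Wald interval
    ``exp(ln PRR ± 1.96·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)))`` on the
    (possibly corrected) cells.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    value = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    log_prr = math.log(value)
    return value, math.exp(log_prr - 1.96 * se), math.exp(log_prr + 1.96 * se)


# -- end-to-end detection ------------------------------------------------------


@dataclass(frozen=True)
class SignalResult:
    """One scored (subject, event-term) association.

    Count semantics are shared across methods: m = supporting articles of
    the subject annotated with the term, s = supporting articles of the
    subject, a = term's article count in the scoring universe, n = universe
    size.  For PRR the universe is the candidate-article set and the Table-
    style cells follow as (m, s−m, a−m, n−s−a+m); for enrichment the
    universe is the reference corpus.
    """

    subject: str
    term: str
    m: int
    s: int
    a: int
    n: int
    raw_p: float | None = None
    adjusted_p: float | None = None
    prr: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def score(self) -> float:
        """Comparable score: −log10(adjusted p) for enrichment, PRR value
        for disproportionality."""
        if self.adjusted_p is not None:
            return -math.log10(max(self.adjusted_p, 1e-300))
        assert self.prr is not None
        return self.prr


def detect_signals(
    subject: str,
    pairs: Iterable[CandidatePair],
    corpus: AnnotationCorpus,
    stats: ReferenceStats,
    level: AbstractionLevel,
    method: str = "gea",
    drug_map: DrugMap | None = None,
    alpha1: float = DEFAULT_ALPHA1,
    event_qualifiers: Iterable[str] = DEFAULT_EVENT_QUALIFIERS,
) -> list[SignalResult]:
    """Score all representative event terms of a subject's set of interest.

    ``method="gea"`` runs the two-step conditional enrichment test against
    the reference stats and sorts ascending by adjusted p (ties by term
    ID); ``method="prr"`` builds per-term contingency tables over the
    candidate-article universe and sorts descending by PRR.  An empty set
    of interest yields an empty list ("no signal").
    """
    pairs = frozenset(pairs)
    soi = build_set_of_interest(
        subject, pairs, corpus, level, drug_map=drug_map, event_qualifiers=event_qualifiers
    )
    if soi.s == 0:
        return []

    if method == "gea":
        results = _detect_gea(soi, stats, alpha1)
    elif method == "prr":
        results = _detect_prr(soi, pairs, corpus, level, event_qualifiers)
    else:
        raise ValidationError(f"unknown method {method!r}; expected 'gea' or 'prr'")
    return results


def _detect_gea(
    soi: SetOfInterest, stats: ReferenceStats, alpha1: float
) -> list[SignalResult]:
    raw: dict[str, float] = {}
    for term, articles in soi.rep_articles.items():
        m = len(articles)
        a = stats.count(term)
        raw[term] = hypergeom_upper_tail(n=stats.n, a=a, s=soi.s, m=m)
    enriched = {t: p for t, p in raw.items() if p < alpha1}
    adjusted = adjusted_pvalues(enriched, stats, soi)
    results = [
        SignalResult(
            subject=soi.subject,
            term=term,
            m=len(soi.rep_articles[term]),
            s=soi.s,
            a=stats.count(term),
            n=stats.n,
            raw_p=p,
            adjusted_p=adjusted.get(term, p),
        )
        for term, p in raw.items()
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.term))
    return results


def _detect_prr(
    soi: SetOfInterest,
    pairs: frozenset[CandidatePair],
    corpus: AnnotationCorpus,
    level: AbstractionLevel,
    event_qualifiers: Iterable[str],
) -> list[SignalResult]:
    # candidate-article universe: every article supporting any drug
    universe = frozenset(p.article_id for p in pairs)
    events = (
        (article, descriptor)
        for article, descriptor in corpus.qualified(event_qualifiers)
        if article in universe
    )
    event_articles, _ = apply_level(events, level)
    drug_articles = soi.articles & universe
    s = len(drug_articles)
    n = len(universe)
    results = []
    for term, articles in soi.rep_articles.items():
        term_universe = event_articles.get(term, frozenset()) & universe
        m = len(articles & drug_articles)
        if m == 0:
            continue
        a = len(term_universe)
        table = ContingencyTable(
            a=m, b=s - m, c=a - m, d=n - s - (a - m)
        )
        value, lo, hi = prr(table)
        results.append(
            SignalResult(
                subject=soi.subject, term=term, m=m, s=s, a=a, n=n,
                prr=value, ci_low=lo, ci_high=hi,
            )
        )
    results.sort(key=lambda r: (-r.prr, r.term))
    return results


# -- reporting -----------------------------------------------------------------


def signal_flags(
    result: SignalResult, thresholds: Iterable[float] | None = None
) -> dict[float, bool]:
    """Strict threshold flags: ``p < t`` for enrichment, ``PRR > t`` for
    disproportionality."""
    if result.adjusted_p is not None:
        thresholds = tuple(thresholds or DEFAULT_P_THRESHOLDS)
        return {t: result.adjusted_p < t for t in thresholds}
    thresholds = tuple(thresholds or DEFAULT_PRR_THRESHOLDS)
    assert result.prr is not None
    return {t: result.prr > t for t in thresholds}


def write_results(
    results: Iterable[SignalResult],
    path: str | Path,
    terminology: Terminology | None = None,
    thresholds: Iterable[float] | None = None,
) -> None:
    """Write the results TSV with per-threshold signal flags."""
    results = list(results)
    if thresholds is None:
        is_gea = any(r.adjusted_p is not None for r in results)
        thresholds = DEFAULT_P_THRESHOLDS if is_gea or not results else DEFAULT_PRR_THRESHOLDS
    thresholds = tuple(thresholds)
    path = Path(path)

    def fmt(value: float | None) -> str:
        return "" if value is None else repr(value)

    with path.open("w", encoding="utf-8") as handle:
        flag_cols = "\t".join(f"signal_at_{t:g}" for t in thresholds)
        handle.write(
            "subject\tterm_id\tterm_name\tm\ts\ta\tn\traw_p\tadjusted_p\t"
            f"prr\tci_low\tci_high\t{flag_cols}\n"
        )
        for r in results:
            name = ""
            if terminology is not None:
                descriptor = terminology.get(r.term)
                if descriptor is not None:
                    name = descriptor.name
            flags = signal_flags(r, thresholds)
            flag_str = "\t".join("1" if flags[t] else "0" for t in thresholds)
            handle.write(
                f"{r.subject}\t{r.term}\t{name}\t{r.m}\t{r.s}\t{r.a}\t{r.n}\t"
                f"{fmt(r.raw_p)}\t{fmt(r.adjusted_p)}\t{fmt(r.prr)}\t"
                f"{fmt(r.ci_low)}\t{fmt(r.ci_high)}\t{flag_str}\n"
            )
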