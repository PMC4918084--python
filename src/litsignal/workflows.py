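"""End-to-end study workflows shared by the evaluation scripts and tests.

Each function runs the full pipeline — reference statistics, abstraction
level, candidate extraction, signal detection, gold alignment — on a
synthetic study, so measured recovery rates exercise every stage rather
than the test statistic in isolation.
"""

from __future__ import annotations

from dataclasses import replace

from .abstraction import build_abstraction_level
from .candidates import extract_candidate_pairs
from .corpus import build_reference_stats
from .evaluation import ConfusionMatrix, confusion_at_threshold, map_outcome_to_level
from .signals import detect_signals
from .synthetic import (
    PlantedAssociation,
    SimulationConfig,
    SyntheticStudy,
    disease_leaves,
    drug_id,
    generate_study,
    generate_terminology,
)

#: Wide-open IC range: every annotated term represents itself, so planted
#: leaf events are scored directly.
IDENTITY_IC_RANGE = (0.0, 100.0)


def score_gold_pairs(
    study: SyntheticStudy,
    method: str = "gea",
    ic_range: tuple[float, float] = IDENTITY_IC_RANGE,
) -> dict[tuple[str, str], float]:
    """Run detection for every gold subject; return the statistic per gold
    (subject, outcome) pair (adjusted p for enrichment, PRR otherwise).
    Pairs without any scored association are absent."""
    stats = build_reference_stats(study.corpus, study.terminology)
    level = build_abstraction_level(study.terminology, stats.ic, *ic_range)
    pairs = extract_candidate_pairs(study.corpus, study.drug_map)
    per_term: dict[tuple[str, str], float] = {}
    for subject in sorted({case.subject for case in study.gold}):
        for result in detect_signals(
            subject, pairs, study.corpus, stats, level,
            method=method, drug_map=study.drug_map,
        ):
            value = result.adjusted_p if method == "gea" else result.prr
            per_term[(subject, result.term)] = value

    best = min if method == "gea" else max
    scores: dict[tuple[str, str], float] = {}
    for case in study.gold:
        values = [
            per_term[(case.subject, rep)]
            for rep in map_outcome_to_level(case.outcome, level)
            if (case.subject, rep) in per_term
        ]
        if values:
            scores[(case.subject, case.outcome)] = best(values)
    return scores


def planted_study_config(seed: int, n_planted: int = 5) -> SimulationConfig:
    """Default study conditions with `n_planted` strong associations: one
    per drug, relative risk 10, 25 dedicated supporting articles each."""
    base = SimulationConfig(seed=seed)
    leaves = disease_leaves(generate_terminology(base))
    planted = tuple(
        PlantedAssociation(drug_id(i), leaves[(4 * i + 1) % len(leaves)],
                           multiplier=10.0, n_supporting=25)
        for i in range(n_planted)
    )
    return replace(base, planted=planted)


def recovery_confusion(seed: int, threshold: float = 0.005) -> ConfusionMatrix:
    """Plant associations, run the enrichment pipeline end to end, and
    score the synthetic gold standard at the given adjusted-p threshold."""
    study = generate_study(planted_study_config(seed))
    scores = score_gold_pairs(study, method="gea")
    return confusion_at_threshold(scores, study.gold, threshold, "less")


def null_raw_significance(seed: int, alpha: float = 0.05) -> tuple[int, int]:
    """On a null corpus (nothing planted), count raw enrichment p-values
    below `alpha` across all (drug, leaf representative) tests.

    Returns (n_significant, n_tests); leaf terms a subject's articles never
    mention enter the denominator with p = 1.
    """
    study = generate_study(SimulationConfig(seed=seed))
    stats = build_reference_stats(study.corpus, study.terminology)
    level = build_abstraction_level(study.terminology, stats.ic, *IDENTITY_IC_RANGE)
    pairs = extract_candidate_pairs(study.corpus, study.drug_map)
    leaves = [t for t in disease_leaves(study.terminology) if t in level.representatives]
    n_significant = n_tests = 0
    for subject in sorted(study.drug_map.ingredients):
        results = detect_signals(
            subject, pairs, study.corpus, stats, level, drug_map=study.drug_map
        )
        if not results:  # no supporting article: no test performed
            continue
        raw = {r.term: r.raw_p for r in results}
        for leaf in leaves:
            n_tests += 1
            n_significant += raw.get(leaf, 1.0) < alpha
    return n_significant, n_tests
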