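"""Synthetic terminologies, corpora, drug maps and gold standards.

The generator emulates the study conditions of literature-based
pharmacovigilance at desk scale: a MEDLINE-like reference corpus whose
articles are indexed with disease descriptors from a multi-level tree
(annotations drawn at leaves only, so internal-node counts arise purely
through ancestor propagation, as they do with real indexing) and with
supplementary-concept drug records carrying the "adverse effects"
qualifier.  Planted drug–event associations inflate the co-annotation rate
of one drug with one disease leaf by a relative-risk multiplier and/or emit
a fixed number of dedicated co-annotated supporting articles; everything
else is independent background, so unplanted pairs form exact null
hypotheses for the enrichment test.

A single integer seed fully determines all output; each artifact section
(terminology / corpus / gold) draws from its own derived stream so that
components regenerate independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .candidates import DrugMap, write_drug_map
from .corpus import AnnotationCorpus, write_annotations
from .errors import ValidationError
from .evaluation import GoldCase, write_gold
from .terminology import Descriptor, Terminology, write_terminology

DRUG_QUALIFIER = "adverse effects"
EVENT_QUALIFIER = "chemically induced"


@dataclass(frozen=True)
class PlantedAssociation:
    """A ground-truth drug–event association.

    `multiplier` scales the event's annotation probability inside the
    drug's articles relative to background; `n_supporting` adds that many
    dedicated articles co-annotated with the qualified pair.
    """

    drug: str
    event: str
    multiplier: float = 10.0
    n_supporting: int = 25

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValidationError("multiplier must be >= 1")
        if self.n_supporting < 0:
            raise ValidationError("n_supporting must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a 2000-article reference corpus over a depth-3,
    branching-3 disease tree (39 terms, 27 leaves) and 10 drugs, each drug
    appearing in ~2% of articles and each disease leaf annotating 15% of
    articles (~4 disease terms per article, a typical index-term density
    for a corpus retrieved for its adverse-event content; it also keeps the
    chance of an article carrying no event term near zero, so selecting a
    drug's event-carrying articles barely biases per-term counts).
    """

    seed: int = 0
    n_articles: int = 2000
    depth: int = 3
    branching: int = 3
    multi_parent_fraction: float = 0.0
    n_drugs: int = 10
    drug_article_rate: float = 0.02
    background_rate: float = 0.15
    qualifier_rate: float = 1.0
    n_decoy_negatives: int = 20
    planted: tuple[PlantedAssociation, ...] = ()

    def __post_init__(self) -> None:
        for name in ("multi_parent_fraction", "drug_article_rate",
                     "background_rate", "qualifier_rate"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        if self.depth < 1 or self.branching < 1:
            raise ValidationError("depth and branching must be >= 1")
        object.__setattr__(self, "planted", tuple(self.planted))


def drug_id(index: int) -> str:
    """Deterministic supplementary-concept-style drug descriptor ID."""
    return f"C9{index:05d}"


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# -- terminology ---------------------------------------------------------------


def generate_terminology(cfg: SimulationConfig) -> Terminology:
    """A complete `branching`-ary disease tree of the configured depth
    (``branching + branching² + …`` terms), optionally with a fraction of
    multi-parent terms realized as duplicated tree numbers, plus `n_drugs`
    drug descriptors with zero tree numbers."""
    rng = _rng(cfg, 0)
    terminology = Terminology()
    counter = 0
    by_depth: dict[int, list[tuple[str, str]]] = {}  # depth -> [(id, primary tn)]
    frontier = [f"C{i + 1:02d}" for i in range(cfg.branching)]
    tns_by_id: dict[str, set[str]] = {}
    for depth in range(1, cfg.depth + 1):
        level_nodes = []
        next_frontier = []
        for tn in frontier:
            counter += 1
            did = f"D{counter:06d}"
            tns_by_id[did] = {tn}
            level_nodes.append((did, tn))
            if depth < cfg.depth:
                next_frontier.extend(f"{tn}.{j + 1:03d}" for j in range(cfg.branching))
        by_depth[depth] = level_nodes
        frontier = next_frontier

    # multi-classification: adopt a second parent at the same depth
    adoption = 0
    for depth in range(2, cfg.depth + 1):
        parents = by_depth[depth - 1]
        if len(parents) < 2:
            continue
        for did, tn in by_depth[depth]:
            if rng.random() >= cfg.multi_parent_fraction:
                continue
            own_parent = tn.rsplit(".", 1)[0]
            candidates = [p_tn for _, p_tn in parents if p_tn != own_parent]
            if not candidates:
                continue
            adoption += 1
            extra_parent = candidates[rng.integers(len(candidates))]
            tns_by_id[did].add(f"{extra_parent}.9{adoption:02d}")

    for depth in range(1, cfg.depth + 1):
        for did, tn in by_depth[depth]:
            terminology.add(Descriptor(did, f"Disease {tn}", frozenset(tns_by_id[did])))
    for i in range(cfg.n_drugs):
        terminology.add(Descriptor(drug_id(i), f"drug{i}", frozenset()))
    return terminology


def disease_leaves(terminology: Terminology) -> list[str]:
    """Disease terms (tree-numbered descriptors) with no children."""
    index = terminology.tree_index
    prefixes = {tn.rsplit(".", 1)[0] for tn in index if "." in tn}
    leaves = []
    for descriptor in terminology:
        if descriptor.tree_numbers and not any(
            tn in prefixes for tn in descriptor.tree_numbers
        ):
            leaves.append(descriptor.descriptor_id)
    return sorted(leaves)


# -- corpus --------------------------------------------------------------------


def generate_corpus(
    cfg: SimulationConfig, terminology: Terminology
) -> tuple[AnnotationCorpus, tuple[PlantedAssociation, ...]]:
    """Draw the annotation corpus and return it with the ground truth.

    Every article draws each drug independently at `drug_article_rate` and
    each disease leaf independently at `background_rate`; inside a planted
    drug's articles the planted event's rate is multiplied by the planted
    multiplier (capped at 1).  Planted pairs additionally emit their
    `n_supporting` dedicated co-annotated articles.  Qualifiers are
    attached per annotation at `qualifier_rate`.
    """
    rng = _rng(cfg, 1)
    leaves = disease_leaves(terminology)
    leaf_index = {leaf: i for i, leaf in enumerate(leaves)}
    drugs = [drug_id(i) for i in range(cfg.n_drugs)]
    drug_index = {d: i for i, d in enumerate(drugs)}
    n = cfg.n_articles

    drug_mat = rng.random((n, len(drugs))) < cfg.drug_article_rate
    event_mat = rng.random((n, len(leaves))) < cfg.background_rate
    for planted in cfg.planted:
        if planted.drug not in drug_index or planted.event not in leaf_index:
            raise ValidationError(
                f"planted pair ({planted.drug}, {planted.event}) references "
                "unknown drug or non-leaf event"
            )
        if planted.multiplier > 1:
            rows = np.flatnonzero(drug_mat[:, drug_index[planted.drug]])
            boosted = min(1.0, planted.multiplier * cfg.background_rate)
            event_mat[rows, leaf_index[planted.event]] = rng.random(len(rows)) < boosted

    records: set[tuple[str, str, str]] = set()
    articles = [f"A{i:06d}" for i in range(n)]

    def qualifier(base: str) -> str:
        return base if rng.random() < cfg.qualifier_rate else ""

    for row, col in zip(*np.nonzero(drug_mat)):
        records.add((articles[row], drugs[col], qualifier(DRUG_QUALIFIER)))
    for row, col in zip(*np.nonzero(event_mat)):
        records.add((articles[row], leaves[col], qualifier(EVENT_QUALIFIER)))

    universe = set(articles)
    for pair_idx, planted in enumerate(cfg.planted):
        for k in range(planted.n_supporting):
            art = f"S{pair_idx:02d}{k:04d}"
            universe.add(art)
            records.add((art, planted.drug, DRUG_QUALIFIER))
            records.add((art, planted.event, EVENT_QUALIFIER))

    corpus = AnnotationCorpus(frozenset(records), frozenset(universe))
    return corpus, cfg.planted


# -- drug map and gold ---------------------------------------------------------


def generate_drug_map(cfg: SimulationConfig) -> DrugMap:
    """Ingredient per drug, three ingredients per systemic ATC4 class, and
    every fifth drug additionally filed under a shared topical class."""
    rows = []
    for i in range(cfg.n_drugs):
        ingredient = f"ING{i:03d}"
        rows.append((drug_id(i), ingredient, f"A{i // 3:02d}AA{i % 3 + 1:02d}"))
        if i % 5 == 0:
            rows.append((drug_id(i), ingredient, f"S01AA{i // 5 + 1:02d}"))
    return DrugMap(rows)


def generate_gold(
    ground_truth: Sequence[PlantedAssociation],
    n_decoy_negatives: int,
    cfg: SimulationConfig,
    drug_map: DrugMap,
    terminology: Terminology,
) -> list[GoldCase]:
    """Positives are the planted pairs (subjects as ingredients); negatives
    are sampled unplanted ingredient–leaf combinations."""
    rng = _rng(cfg, 2)
    positives = {
        (drug_map.mesh_to_ingredient[p.drug], p.event) for p in ground_truth
    }
    leaves = disease_leaves(terminology)
    candidates = sorted(
        (ing, event)
        for ing in sorted(drug_map.ingredients)
        for event in leaves
        if (ing, event) not in positives
    )
    if n_decoy_negatives > len(candidates):
        raise ValidationError(
            f"requested {n_decoy_negatives} decoys but only {len(candidates)} "
            "unplanted combinations exist"
        )
    chosen = rng.choice(len(candidates), size=n_decoy_negatives, replace=False)
    gold = [GoldCase(s, o, True) for s, o in sorted(positives)]
    gold.extend(GoldCase(*candidates[i], False) for i in sorted(chosen))
    return gold


# -- one-call convenience ------------------------------------------------------


@dataclass(frozen=True)
class SyntheticStudy:
    config: SimulationConfig
    terminology: Terminology
    corpus: AnnotationCorpus
    drug_map: DrugMap
    gold: tuple[GoldCase, ...]
    ground_truth: tuple[PlantedAssociation, ...]


def generate_study(cfg: SimulationConfig) -> SyntheticStudy:
    terminology = generate_terminology(cfg)
    corpus, ground_truth = generate_corpus(cfg, terminology)
    drug_map = generate_drug_map(cfg)
    gold = generate_gold(ground_truth, cfg.n_decoy_negatives, cfg, drug_map, terminology)
    return SyntheticStudy(
        config=cfg,
        terminology=terminology,
        corpus=corpus,
        drug_map=drug_map,
        gold=tuple(gold),
        ground_truth=ground_truth,
    )


def write_study(study: SyntheticStudy, directory: str | Path) -> None:
    """Emit the four TSV artifacts consumed by the rest of the package."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_terminology(study.terminology, directory / "terminology.tsv")
    write_annotations(study.corpus, directory / "annotations.tsv")
    write_drug_map(study.drug_map, directory / "drug_map.tsv")
    write_gold(study.gold, directory / "gold.tsv")
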