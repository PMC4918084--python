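# Methods

## Model and procedure

`litsignal` treats literature-based ADE detection as over-representation
analysis of annotation profiles. The objects involved:

* **Terminology.** Descriptors carry one or more dot-delimited tree
  numbers; the tree numbers, not explicit parent links, define the
  hierarchy (a term's ancestors are the owners of the proper prefixes of
  its tree numbers, unioned over its tree numbers). Multi-classified
  descriptors make the structure a DAG, which is the root cause of the
  dependency problem the conditional test addresses. Supplementary-concept
  records (drugs) may have zero tree numbers; they pair with events but
  never aggregate. Descriptors annotated in a corpus but missing from the
  terminology are kept as orphan leaves with zero ancestors and a logged
  warning — silently dropping data would be worse.

* **Reference statistics.** For every term, the aggregated article set
  a(t) is the union of the raw article sets of the term and its
  descendants, built by propagating each article ID to all tree-number
  ancestors. n is the size of the article universe (which may contain
  unannotated articles; the annotation TSV dialect lets a row with an
  empty descriptor field declare such an article so corpora round-trip).
  p(t) = |a(t)|/n, IC(t) = −log₂ p(t); terms never annotated carry no IC.
  Co-frequencies |a(x) ∩ a(y)| are stored sparsely for unordered pairs
  with a positive intersection. Qualifiers are ignored on the reference
  side: background frequencies describe all indexing, not qualified
  subsets. Counts are of unique articles — an article indexed with two
  descendants of t contributes once to |a(t)|.

* **Abstraction level.** Given an IC range [IC_min, IC_max) (half-open:
  the upper bound is aggregated, the lower bound kept), a term in range
  represents itself; a term with IC ≥ IC_max maps independently along each
  tree-number path to the *nearest* (deepest) in-range ancestor, union
  across paths — because IC is monotone non-increasing toward the root,
  the first in-range ancestor met walking up is the nearest. Terms below
  the range, or above it with no in-range ancestor, are excluded, and
  excluded originals are reported in a coverage account. Representatives
  from different paths are all kept; the conditional correction handles
  the correlation this induces. Reference-side counts for a level reuse
  the ancestor-propagated counts directly, since a(representative) already
  covers all descendants. The fixed-tree-level variant maps each term to
  its level-k tree-number prefixes instead.

* **Candidates and the set of interest.** Within each article, candidate
  pairs are the cross product of descriptors qualified as drugs
  ("adverse effects") and as event manifestations ("chemically induced");
  qualifier strings match case-insensitively against configurable alias
  lists, since the qualifiers are semantic roles rather than literal
  strings. Subjects are unique ingredients; ATC5 codes serve only to group
  ingredients into ATC4 classes (prefix operation), and a class subject
  pools its members' articles. The set of interest of a subject is the set
  of articles pairing it with any qualified event; its event profile
  counts, per representative, the distinct articles carrying *any*
  qualified event mapping there — all qualified events on a supporting
  article contribute, because enrichment is computed over the annotation
  profile of the article set, not over a single extracted pair. This
  article-profile reading is an interpretation choice; the alternative
  (only the paired event) is strictly narrower and would discard profile
  information the test needs.

* **Enrichment test.** Step 1: raw p = P(X ≥ m), X ~ Hypergeom(n, a, s),
  inclusive tail, p = 1 when m = 0. Step 2: among terms with raw
  p < α₁ (default 0.1, the loosest reporting threshold), each pair (x, y)
  with reference co-count a_xy ≥ 1 gets a conditional p-value
  P(X ≥ m_xy), X ~ Hypergeom(a_y, a_xy, o), where o and m_xy are counts of
  y and of x∧y inside the set of interest; adjusted p(x) is the maximum of
  raw p(x) and all its conditional p-values (including raw p in the max
  guarantees adjusted ≥ raw). The conditional population is the reference
  margin (a_y, a_xy) with draws from the set of interest; the alternative
  reading — population = the set of interest itself — is isolated behind
  the single `conditional_p` function so it could be swapped. Conditioning
  ranges over step-1-enriched terms only. No multiple-testing correction
  is applied by default; thresholds are strict (p < t, PRR > t).

* **PRR baseline.** PRR = (a/(a+b)) / (c/(c+d)) over article counts in
  the candidate universe (articles supporting at least one drug); for a
  class, a and b count articles mentioning any member drug, c and d
  articles mentioning any other drug. If any cell is zero, 0.5 is added to
  all four cells. The 95 % CI is the standard log-scale Wald interval
  exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))).

* **Evaluation.** Gold subjects are ingredients or ATC4 classes; lifting
  drug-level labels to classes propagates each drug's label to all its
  classes, and a class receiving conflicting labels for an outcome becomes
  a positive control and leaves the negatives. Gold outcomes are rewritten
  onto the active level's representatives (an excluded outcome is a
  configuration error — that level cannot express the outcome). Confusion
  counting treats a pair with no score as a non-signal, since the absence
  of any supporting article cannot produce a signal. ROC AUC is rank-based
  with ties counted ½; scoreless subjects rank below every scored subject,
  tied among themselves. Score orientation: −log₁₀(adjusted p) for
  enrichment, the PRR value for disproportionality, so AUCs are comparable
  across methods. Reported metrics round half-up to two decimals; F1 is
  the harmonic mean of *unrounded* precision and recall.

## Numerical choices

* Hypergeometric tails are exact: big-integer binomial-coefficient sums
  with one correctly rounded rational-to-float division at the end. This
  avoids the catastrophic cancellation of `1 − CDF` at extreme tails and
  is fast at the population sizes the package targets (tests agree with
  `scipy.stats.hypergeom.sf` to 10 significant digits and with a full
  pmf-enumeration oracle to 1e−12).
* Ties in result ranking break by term ID (ascending adjusted p for
  enrichment, descending PRR for the baseline), making every output file
  byte-reproducible.
* Degenerate inputs: an empty set of interest yields an empty result list
  ("no signal"); an empty reference corpus is a validation error; metrics
  with a zero denominator are reported as absent rather than 0.

## Synthetic data: what it emulates, and what it does not

The generator emulates a MEDLINE-like study at desk scale. Defaults (the
conditions under which all shipped experiments run): 2000 reference
articles; a complete depth-3/branching-3 disease tree (39 terms, 27
leaves) with IDs and tree numbers assigned deterministically; 10 drugs as
zero-tree-number supplementary concepts; each drug appears in 2 % of
articles with the "adverse effects" qualifier; each disease leaf annotates
15 % of articles with the "chemically induced" qualifier. Annotations are
drawn at leaves only, so internal-node counts arise purely through
ancestor propagation, as with real indexing. The leaf rate gives ~4
disease terms per article — a realistic index-term density for a corpus
retrieved for its adverse-event content — and keeps the probability of an
article carrying no event term near zero (0.85²⁷ ≈ 0.01). The latter
matters statistically: the set of interest is defined by co-mention, so
selecting a drug's event-carrying articles conditions on "≥ 1 event
term"; with sparse event vocabularies that selection inflates every
per-term count, whereas at this density the bias factor is ≈ 1.01 and the
per-term null is hypergeometric to excellent approximation.

Planted associations multiply the event's rate inside the drug's articles
(capped at probability 1) and/or append dedicated co-annotated supporting
articles. The planted-recovery experiment uses five planted pairs per
study at relative risk 10 with 25 supporting articles each, thresholds
at adjusted p < 0.005, pooled over three seeds; the null experiment uses
the same conditions with nothing planted. One seeded stream per artifact
section (terminology / corpus / gold) keeps components independently
regenerable; a single integer seed fully determines all files.

What the generator does **not** emulate: publication types and dates,
abstract text, indexing-depth variation across journals, correlated
co-morbidity structure between disease branches, and reporting-rate
differences across outcomes. Passing tests on synthetic corpora therefore
demonstrate the statistical machinery (calibration, recovery, dependency
suppression) — not performance on real literature, where candidate
extraction quality and terminology coverage dominate.

## Problem sizes

Shipped experiments are sized for quick, repeatable runs: 2000-article
corpora, ≤ 40-term vocabularies, three seeds per stochastic claim; the
whole test suite and the acceptance script each complete in well under a
minute on one CPU. The reference-statistics builder is quadratic in
per-article annotation count (co-frequency pairs) and is serialized to a
TSV directory for "build once, analyze many" use at larger scales.

## Known limitations

* Enrichment against a broad reference corpus tends to flag generic
  drug-safety terms (they genuinely are over-represented in ADE-related
  article sets); a domain-focused reference would temper this.
* The conditional correction is pairwise and max-based; it suppresses
  redundancy but does not form a joint model over enriched terms.
* Evaluation is retrospective; nothing here addresses prospective,
  time-indexed signal detection.
* The terminology layer deliberately handles descriptor records and tree
  numbers only — no qualifier hierarchies, entry terms or synonyms.
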