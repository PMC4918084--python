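# litsignal

Literature-based adverse-drug-event (ADE) signal detection via
**generalized enrichment analysis** over MeSH-style article annotations.

Drug-safety signals are usually mined from spontaneous-report databases
with disproportionality statistics. The published biomedical literature is
a complementary source: MEDLINE-style indexing attaches controlled
descriptor/qualifier pairs to every article, so an article indexed with
*ofloxacin/adverse effects* and *tendinopathy/chemically induced* is a
candidate report of an ADE. `litsignal` implements that analysis end to
end for pharmacovigilance researchers and curators of ADE repositories:

1. **Reference statistics.** From a large annotation corpus, each term's
   article set a(t) is ancestor-propagated along the terminology's
   dot-delimited tree numbers. Term probability is p(t) = |a(t)|/n and
   information content IC(t) = −log₂ p(t); pairwise co-frequencies
   |a(x) ∩ a(y)| quantify known term dependencies.
2. **Abstraction levels.** Adverse-event terms of uneven specificity are
   harmonized onto a set of representatives with IC in a chosen half-open
   range [IC_min, IC_max): in-range terms keep themselves, over-specific
   terms aggregate to the nearest in-range ancestor along each tree-number
   path, and the rest are excluded. A fixed-tree-level alternative (the
   classical "2nd MeSH level") is also provided.
3. **Signals.** For a drug (or ATC4 drug class) with set of interest S of
   size s, each representative event term x with a reference count a out
   of n and observed count m is scored with the inclusive hypergeometric
   upper tail P(X ≥ m), X ~ Hypergeom(n, a, s). A second, *conditional*
   pass corrects for dependencies among the enriched terms: for each pair
   (x, y) with reference co-count a_xy, the conditional p-value
   P(X ≥ m_xy), X ~ Hypergeom(a_y, a_xy, o), asks whether x's joint
   occurrence with y in S is surprising given y; the adjusted p-value of x
   is the maximum over its raw p and all pairwise conditional p-values, so
   a term that merely tags along with a co-occurring partner (a redundant
   ancestor, a multi-classified sibling) loses significance. A
   proportional reporting ratio baseline, PRR = (a/(a+b)) / (c/(c+d)) over
   the 2×2 drug-mention × event-mention contingency table with 0.5
   zero-cell correction and log-scale Wald 95 % CI, is included for
   comparison.
4. **Evaluation.** Signals are aligned with an OMOP-style gold standard of
   positive/negative drug–outcome controls (with drug-class lifting and
   the class-conflict rule), producing confusion matrices,
   precision/recall/F1 at threshold sweeps, and tie-aware ROC AUC in which
   drugs without literature support rank worst.

A fully seeded synthetic module generates terminologies, corpora with
planted drug–event associations, drug maps and gold standards, so the
whole pipeline is testable without downloading any corpus.

## Worked example

Simulate a small study with one planted association (drug `C900000` ↦
ingredient `ING000`, event `D000013`, relative risk 10, 25 dedicated
supporting articles), build reference statistics, and score the drug:

```bash
cat > sim.yaml <<'YAML'
n_articles: 600
n_drugs: 6
planted:
  - {drug: C900000, event: D000013, multiplier: 10.0, n_supporting: 25}
YAML
litsignal simulate --seed 11 --sim-config sim.yaml --out data
litsignal build-ref --terminology data/terminology.tsv \
    --annotations data/annotations.tsv --out stats
litsignal detect --terminology data/terminology.tsv \
    --annotations data/annotations.tsv --stats stats \
    --drug-map data/drug_map.tsv --ic-min 0 --ic-max 100 \
    --subject ING000 --out signals.tsv
```

The log reports `reference stats: 625 articles, 45 annotated terms, 953
stored co-frequency pairs` (600 background articles plus the 25 supporting
ones), and the top of `signals.tsv` reads:

```
subject  term_id  m   s   a    n    raw_p                  adjusted_p
ING000   D000013  42  42  125  625  7.306248450385325e-33  7.306248450385325e-33
ING000   D000038  4   42  86   625  0.8570319939382718     0.8570319939382718
```

All 42 of the drug's supporting articles mention the planted event
(m = s = 42) against a background of 125/625 reference articles, an
overlap with an adjusted p-value of ~7·10⁻³³ — a strong signal — while
the next term is entirely unremarkable (p ≈ 0.86). Scoring every drug
(`detect` without `--subject`) and evaluating against the simulated gold
standard:

```bash
litsignal detect ... --out all.tsv
litsignal evaluate --results all.tsv --gold data/gold.tsv \
    --terminology data/terminology.tsv --stats stats \
    --ic-min 0 --ic-max 100 --out report.json
```

yields, at adjusted p < 0.005, the pooled confusion `tp=1, fp=0, tn=20,
fn=0` (the planted pair against 20 decoy negatives), precision = recall =
F1 = 1.0 and AUC = 1.0.

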