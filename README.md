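# dietbarcode

Diet metabarcoding for elusive herbivores, from degraded plant barcode
fragments. The package implements the analysis chain used to
reconstruct a large tropical herbivore's diet from dung: chloroplast
barcode fragments (e.g. the *trnH*-*psbA* intergenic spacer) recovered
from dung fibres are matched against a regional reference database,
resolved to species, genus or family with calibrated mismatch
thresholds, the leftover unidentifiable sequences are grouped into
minimum putative species, and incidence-based richness estimation
(sample rarefaction + Chao2) quantifies how complete the recovered
diet list is. A synthetic-data module generates reference databases,
degraded query fragments and incidence matrices with the statistical
structure the downstream stages assume, so the whole chain is testable
without any sequence downloads.

Intended users: molecular ecologists analysing diet metabarcoding data
at Sanger scale, and anyone needing a transparent, scriptable
implementation of threshold-based barcode assignment with incidence
richness estimation.

## The method

**Mismatch statistic.** A query fragment is aligned to each reference
sequence by Smith–Waterman local alignment (match +1, mismatch −1, gap
open −2, gap extend −1; both strands, lower score kept). The distance
is

```
mismatch = (gap openings + mismatched columns) / alignment length
```

where a gap opening is the start of a maximal gap run in either row.
Hits covering less than half the query are discarded.

**Rank assignment.** Best-hit mismatch strictly under 0.3 % ⇒ same
species, under 2.0 % ⇒ same genus, under 4 % ⇒ same family; otherwise
unassigned. All hits inside the winning band vote; if they disagree at
that rank, the call is demoted to their lowest common rank
(an LCA-style consensus), yielding the *minimum* set of candidate taxa.

**Minimum richness of the unidentified.** Sequences that stay
unassigned are clustered by single linkage: two fragments link when
they differ by at most 5 % over at least 95 % of the shorter
fragment's length; connected components are minimum putative species.

**Richness estimation.** From a samples × taxa incidence matrix,
sample-based rarefaction (500 random sample orderings by default)
gives the accumulation curve mean ± SD, and total richness is
estimated by Chao2,

```
S_chao2 = S_obs + ((m−1)/m) · Q1² / (2·Q2)
```

(bias-corrected form `S_obs + ((m−1)/m)·Q1(Q1−1)/(2(Q2+1))` when
Q2 = 0), with the Chao (1987) log-normal 95 % CI. Q1 and Q2 are the
numbers of taxa seen in exactly one and exactly two samples.

## Worked example

```python
from dietbarcode import (
    SimulationConfig, Degradation, generate_reference, generate_queries,
    BarcodeTaxonomyClassifier, tally_assignments, qc_filter,
    DivergenceClusterer, chao2, generate_incidence,
)

cfg = SimulationConfig(
    n_families=3, genera_per_family=2, species_per_genus=2,
    seed=42, frac_novel=0.2,
    degradation=Degradation(substitution_rate=0.001, indel_rate=0.0005,
                            truncation_range=(100, 400)),
)
db = generate_reference(cfg)                      # 12-species reference
queries = generate_queries(db, cfg, 30)           # degraded dung fragments
kept, discarded = qc_filter(queries)              # >120 bp rule
print(f"{len(kept)} of {len(queries)} fragments passed the >120 bp filter")

clf = BarcodeTaxonomyClassifier().fit(db)
calls = clf.predict(kept)
print(tally_assignments(calls))

unassigned = [q for q, a in zip(kept, calls) if not a.is_assigned]
clusterer = DivergenceClusterer().fit(unassigned)
print(f"{clusterer.n_clusters_} divergence clusters among "
      f"{len(unassigned)} unassigned fragments")

inc = generate_incidence(19, 25, 0.15, seed=42)   # 19 dung piles
est = chao2(inc)
print(f"S_obs={est.S_obs}, Q1={est.Q1}, Q2={est.Q2}, "
      f"Chao2={est.S_chao2:.1f} (95% CI {est.ci_low:.1f}-{est.ci_high:.1f})")
```

prints

```
27 of 30 fragments passed the >120 bp filter
{'queries_per_rank': {'species': 14, 'genus': 8, 'family': 0, 'unassigned': 5},
 'distinct_taxa': {'species': 7, 'genus': 6, 'family': 3}}
5 divergence clusters among 5 unassigned fragments
S_obs=25, Q1=5, Q2=2, Chao2=30.9 (95% CI 25.9-63.2)
```

Three fragments failed the length filter; of the 27 retained, 14 were
resolved to species and 8 only to genus (damage pushed them past the
0.3 % species threshold); the 5 unassigned fragments — a fifth of the
queries were simulated from taxa absent from the reference — formed 5
divergence clusters, i.e. at least 5 additional species. The Chao2
estimate says the 25 taxa observed across 19 dung piles are drawn from
roughly 31 (the 5 uniques and 2 duplicates signal undetected taxa).

The same stages are available from the shell:

```sh
dietbarcode simulate --config sim.yaml --out data/
dietbarcode match --queries data/queries.fasta --ref data/reference.fasta \
    --tax data/taxonomy.tsv --out hits.tsv
dietbarcode assign --hits hits.tsv --ref data/reference.fasta \
    --tax data/taxonomy.tsv --out assignments.tsv
dietbarcode cluster --queries unassigned.fasta --out clusters.tsv
dietbarcode richness --incidence data/incidence.tsv \
    --curve-out curve.tsv --estimate-out estimate.json
dietbarcode run --config run.yaml        # full pipeline + manifest
```

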