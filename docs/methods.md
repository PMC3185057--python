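# Methods

## Problem setting

Dung of a free-ranging herbivore contains plant fibres whose DNA is
partially degraded. Short chloroplast barcode fragments (*trnH*-*psbA*
scale, ~500 bp full length) amplified from those fibres are compared
to a regional reference database in which every sequence carries a
species / genus / family lineage. The analysis must (i) decide, per
fragment, the finest rank the sequence evidence supports, (ii) put a
floor on the number of species among fragments that match nothing,
and (iii) estimate how much of the diet remains unobserved given the
incidence of taxa across sampling units (dung piles or feeding
sites).

## Alignment and the mismatch statistic

Queries are aligned to references with Smith–Waterman local alignment
(match +1, mismatch −1, gap open −2, gap extend −1), via Biopython's
`PairwiseAligner`. BLAST-style heuristic seeding buys nothing at
desk scale, and the statistic below is defined on the resulting
alignment, not on any aligner internals. The distance is

    mismatch = (n_gap_openings + n_mismatches) / alignment_length

computed by an explicit walk over the aligned columns: a gap opening
is the start of a maximal run of gap characters in either row; a
column is a mismatch when both rows hold a base and the bases differ,
or when either base is an ambiguity code (N never matches anything,
including another N — the conservative reading). The alignment length
counts all columns of the locally aligned region, including gap
columns; terminal unaligned overhangs are excluded.

Fragment orientation is unknown, so both strands are aligned and the
orientation with the lower mismatch score is kept (ties favour
forward). A hit must cover ≥ 50 % of the query; shorter local matches
are treated as "no hit" so that trivial word matches cannot supply a
deceptively small denominator. The coverage floor is applied per
strand *before* choosing the orientation — otherwise a spurious
8-bp reverse-strand exact match (mismatch 0) would outrank the true
forward alignment and then be discarded, losing the query entirely.
When several tracebacks are optimal, the aligner's first is used,
which keeps runs reproducible.

## Rank assignment

Thresholds: best-hit mismatch < 0.003 ⇒ species, < 0.020 ⇒ genus,
< 0.040 ⇒ family, else unassigned. All inequalities are strict, so a
score exactly at a threshold falls in the coarser band. These are
calibration constants of the barcode locus and database, exposed as
parameters (`AssignmentThresholds`, or `--thresholds` on the CLI).

Conflict handling was genuinely open: equal or near-equal best hits
can disagree about the taxon. The rule implemented is that every hit
whose score lies inside the winning band votes; if the voters
disagree at the band's rank, the call is demoted to their lowest
common rank, and to unassigned when even the families conflict. This
consensus produces the *minimum* number of candidate taxa and
naturally yields calls resolvable "only to a family". Distinct-taxon
tallies count each taxon once regardless of how many queries hit it,
and a species-level call contributes its genus and family to the
coarser tallies; each `Assignment` therefore carries its resolved
lineage so tallies need no database lookup.

Quality control: fragments must be strictly longer than 120 bases
(`qc_filter`; an `inclusive` switch admits exactly 120 when a user's
convention differs).

## Clustering the unidentified

Unassigned fragments are grouped by single linkage: fragments link
when their pairwise mismatch score is ≤ 0.05 over an alignment
covering ≥ 0.95 of the *shorter* fragment (the common default for
fragments of unequal length, and the conservative choice); "differing
by more than 5 %" therefore splits, exactly 5 % still links. Pairs
failing the coverage requirement contribute no edge — they are
neither linked nor forced apart. Components are computed with
`scipy.sparse.csgraph.connected_components` on the link graph; the
test suite checks the partition against an independent breadth-first
search. Input order cannot affect the partition (sequences are
processed in id order). The number of clusters is the minimum
cumulated species richness of the unidentified material.

## Richness estimation

Input is a binary samples × taxa incidence matrix. Rarefaction
averages the number of distinct taxa in the first t samples over R
random permutations of the sample order (sampling without
replacement; R = 500 by default). The SD reported per point is the
sample SD (ddof = 1) across the R orderings; at t = m all orderings
contain every sample, so the mean equals S_obs and the SD is exactly
0. The exact expectation (sample-based rarefaction closed form)

    E[S(t)] = S_obs − Σ_i C(m − m_i, t) / C(m, t)

is implemented separately (`expected_rarefaction`) and serves as the
oracle for the randomized curve, not as its implementation.

Chao2: classic form S_obs + ((m−1)/m)·Q1²/(2Q2) when Q2 > 0,
bias-corrected S_obs + ((m−1)/m)·Q1(Q1−1)/(2(Q2+1)) when Q2 = 0 — the
automatic switch follows the EstimateS 8.2 convention, and both forms
plus the (m−1)/m small-sample factor are switchable. The 95 % CI uses
the log-normal approximation on T = S_chao2 − S_obs (Chao 1987) with
the classic/bias-corrected variance forms. The estimate and SE were
verified against `vegan::specpool` on a fixed matrix (agreement to
5 decimals; the values are frozen in the test suite). Two properties
matter in practice: S_chao2 ≥ S_obs always, and the CI models the
*undetected* count — its lower bound necessarily exceeds S_obs, so
when sampling has already found everything the interval trivially
excludes the truth by a hair. Coverage is therefore property-tested
conditional on undetected species existing, where simulation shows
~87–93 % coverage (the shortfall reflects the estimator's well-known
negative bias as a lower-bound estimator).

## Synthetic data

The generator builds the study system the downstream stages assume,
not a general sequence-evolution simulator.

**Reference.** Band targets are single divergence values:
`species_band` (default 0.002) is the divergence a degraded query may
accumulate against its source, `genus_band` (0.015) the divergence
between congeneric species, `family_band` (0.035) between
confamilial genera, and `novel_divergence` (0.07) beyond the family
threshold. Rather than mutating down the taxonomy at band-controlled
rates and rejecting violating pairs, each family, genus and species
branch mutates a *disjoint* set of positions (sizes chosen so twice
the path sums hit the band targets); pairwise Hamming divergences are
then sums of private mutation counts and land in their bands exactly,
by construction — the stronger guarantee makes the calibration
property deterministic rather than asymptotic. Positions within 10
bases of the ends are never mutated so local alignment cannot trim a
band-defining difference. `audit_divergences` re-measures every pair
through the alignment module as verification. Configurations whose
mutation budget exceeds the sequence length are rejected as
infeasible.

**Queries.** A fragment is a uniform random window of its source
(length uniform over `truncation_range`, default 100–400 bases so a
realistic fraction fails the 120 bp filter), with per-base binomial
substitutions (default 10⁻³), single-base indels extended
geometrically with p = 0.5 (default rate 5·10⁻⁴), and a random
strand. Novel-taxon queries derive from a reference sequence mutated
at `novel_divergence` so their nearest relative lies beyond the
family threshold; their truth label is "novel". Truth labels and dung
pile ids travel in FASTA headers as `|key=value|` tokens.

What the generator does *not* emulate: PCR bias, chimeras,
heterogeneous substitution processes (transition/transversion bias,
rate variation along the locus), shared indel polymorphism between
relatives, and contamination. Passing tests therefore demonstrate the
pipeline's logic under calibrated divergence structure, not
performance on real chromatogram-derived data.

**Incidence.** Cells are independent Bernoulli draws with scalar or
per-taxon detection probability — adequate for exercising Q1/Q2-based
estimators, but without the spatial or temporal correlation of real
dung-pile data.

## Pipeline

`run_all` chains simulate (or load) → QC → match → assign → cluster →
richness and writes every stage output plus a JSON manifest
(parameters, seed, per-stage counts, success-rate arithmetic,
assignment tallies, richness summary, and truth-label evaluation when
headers carry labels). Only fragments the assignment stage left
unassigned are clustered, mirroring the idea that clustering puts a
floor under the *unidentified* material; `cluster_all` overrides.
The dung-pile × taxon incidence matrix fed to the richness stage
combines assigned taxa with cluster labels of unassigned fragments.
All randomness flows from the single run seed; outputs are written
with fixed orderings and line endings, so same-seed runs are
byte-identical. In the manifest's count mapping, every generated
query counts as amplified (the simulator does not model PCR failure)
and "sequenced" means passing the length QC.

## Numerical and scale choices

Alignment of a 480 bp pair costs ~15 ms, so default problem sizes
keep full runs interactive: the bundled study system uses 8–20
reference species and tens of queries, which exercises every code
path (multi-band divergences, novel taxa, QC failures, conflict
demotion) at a few seconds per stage. Recovery checks use a
20-species reference (5 families × 2 genera × 2 species) with
within-species-band degradation — substitution rate 3·10⁻⁴, no
indels, fragments of 420–500 bases — under which a single
substitution stays below the 0.3 % species threshold and ≥95 %
species recovery is the expected behaviour; with degradation disabled
recovery must be exact. Monte-Carlo checks compare randomized
rarefaction to its closed form within 3 standard errors.

## Known limitations

- Thresholds are locus- and database-specific calibration constants;
  defaults are not transferable to other barcodes.
- The assignment consensus is one defensible conflict rule among
  several; alternatives (e.g. best-hit-only, bootstrap support) are
  out of scope.
- Chao2 is a lower-bound estimator; under strong detection
  heterogeneity it underestimates, and its CI under-covers
  accordingly.
- Single-linkage clustering chains: two fragments > 5 % apart share a
  cluster when intermediates connect them, so cluster counts are
  floors, not species counts.
- No abundance information is used anywhere; all richness statistics
  are incidence-based.
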