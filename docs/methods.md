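# Methods

This note documents the models and conventions `equihap` implements,
the defaults it ships, and what the synthetic-data validation does and
does not demonstrate about real survey data.

## Coordinates, variant calls and distances

All positions use 1-based NPS numbering on the horse mtDNA reference;
the analysis window is inclusive on both ends (default 15,494–15,740,
247 bp). Which reference sequence defines the numbering is
configuration (`window.reference_fasta`), not an assumption of the
code.

A sequence is reduced to a set of canonical variant labels against the
window reference: a bare position for a transition, a base suffix for a
transversion (classified by purine/pyrimidine classes), `d` for a
deletion, `pos+BASES` for an insertion after the given position
(multi-base insertions are one call). IUPAC ambiguity codes compatible
with the reference emit no call — the conservative choice for
heteroplasmic or uncertain reads — and `N` marks the position as
missing rather than variant. Back mutations need no special handling in
profile space: they simply cancel.

The distance between two profiles is the size of the symmetric
difference of their label sets ("number of mismatches"), with each
indel call counting exactly one mismatch, and any position unreadable
in either profile excluded from the comparison. This masking rule is
what makes short, incomplete ancient fragments comparable at all; its
cost is that very incomplete fragments have downward-biased distances.

## Haplogroup motifs and (near-)matching

The motif of haplogroup *h* is the set of window variants carried by
every training member of *h* (members unreadable at the position do not
veto) and by no member of any other haplogroup. Exclusivity is a hard
definition, not a statistical criterion: one shared carrier removes the
variant from both motifs. Haplogroups whose private variation lies
outside the window come back with empty motifs, are flagged, and can
never be assigned from the fragment — the situation the backbone
haplogroups A, B, C, G, K and J are in for a 247 bp window. A rename
map (default: E/F/G→EFG, J/K→KJ, O/P→OP) lets the engine work with a
hierarchical nomenclature without hard-coding it.

Assignment scores each non-empty motif by the fraction of its sites
present in the query, where the denominator counts only motif sites the
query was observed at. Scoring over covered sites is the standard
practice of mitochondrial haplogroup callers and is what lets a
fragment missing two of three motif sites still match on the third. An
exact score of 1 is an `exact_motif` call; otherwise the best
haplogroup must reach `min_fraction` (default 0.5) and lead the
runner-up by `min_margin` (default 1e-9, i.e. any strict tie fails);
everything else is UNCLASSIFIED. Two simultaneous exact matches are
logged as a conflict and returned UNCLASSIFIED, since they indicate a
defective motif set. The 0.5 default is an artifact decision — no
published threshold exists for "near" matching — and both knobs are
exposed in the CLI and pipeline config.

## Haplotype networks

Unique haplotypes (keyed by their sorted label string) are joined by a
minimum spanning tree under the same Hamming distance, computed by
Kruskal's algorithm with edges ordered by (distance, smaller node id,
larger node id) and node ids assigned by sorted canonical key. Minimum
spanning trees are rarely unique; the fixed tie-break makes the output
bit-reproducible, and the tests verify optimality of the total weight
against exhaustive enumeration of all spanning trees (Prüfer
sequences) on small instances and against an independent library MST
on larger ones. Equally-minimal alternative edges are not emitted; only
the tree is.

Cohort summaries follow the field's definitions: a haplotype is unique
to a cohort when all its carriers fall inside it; F% is
100 · n_unique / n_haplotypes per (haplogroup, cohort); dominant
haplotypes are those at or above a carrier-count threshold (default
40). "Candidate ancestral" haplotypes are ranked by degree within the
haplogroup's induced subtree, then carrier count, then key. This is an
explicit operational convention — frequency-weighted centrality in the
network — chosen because no formal ancestrality criterion exists for
these networks; the rank-1 node is reported as a candidate, never
asserted as ancestral.

## Population-genetic statistics

Diversity uses Nei's unbiased haplotype diversity
h = n/(n−1)(1−Σp²) and nucleotide diversity π = mean pairwise
distance / window length.

AMOVA follows the classical hierarchical sums-of-squares decomposition
on pairwise distances, with the "number of differences" metric (no
substitution-model correction) so that network, Φ statistics and
diversity all share one distance. Variance components are estimated by
equating mean squares to their expectations with the usual unequal-n
coefficients; negative components are reported as computed and clipped
to zero only in the display percentages (both are retained in the JSON
output). Permutation tests use the unit appropriate to each statistic:
whole populations across groups for Φ_CT, individuals across
populations within groups for Φ_SC, individuals across all populations
for Φ_ST; P is the proportion of permuted statistics at least as large
as the observed one. The default is 10,100 permutations with the seed
recorded in every result; `components=` restricts permutation to the
statistics actually needed. Note that for identical polymorphic
samples the unbiased among-component is negative, not zero — the
estimator trades a clean zero for unbiasedness.

Gene flow uses the haploid maternal island model
Φ_ST = 1/(2Nm+1), i.e. Nm = (1−Φ_ST)/(2Φ_ST), diverging to infinity
for non-positive Φ_ST. Published Nm matrices may rest on other
conventions (e.g. diploid 4Nm); comparisons across studies should
check the formula first.

Cohort association uses the Pearson χ² statistic on the 2×2 table
(cohort × in/out of haplogroup), df = 1, without continuity
correction; an expected cell below 1 sets a `low_expected` flag instead
of suppressing the result. A haplogroup absent from both cohorts has
identical proportions by construction and returns statistic 0, P = 1.

## Frequency tables and PCA

Frequency tables hold percentages per population row with sample
sizes; rows must sum to 100 within ±0.5 to absorb 1-decimal printing,
and UNCLASSIFIED calls live in a side column outside the haplogroup
matrix. The packaged world table covers 59 populations and the 10
haplogroups analysable inside the window (D, I, EFG, H, L, M, N, OP,
Q, R).

`run_pca` eigendecomposes the correlation (default) or covariance
matrix. The `cases` argument sets the orientation. For the world
survey the analysis convention is `cases="haplogroups"`: haplogroups
are the observations and populations the variables. This is the
orientation under which per-haplogroup "contributions" are regression-
method factor scores, and it is the one that reproduces the published
variance shares of the world table (PC1 44.54%, PC2 18.88%, first two
components 63.42% cumulative, first three 73.12%) to printed
precision; the population-cases orientation does not. Factor scores
use the regression method (standardized principal-component scores,
Z·V·Λ^−1/2); loading signs are fixed so each component's
largest-magnitude entry is positive; constant variables are dropped
with a warning under correlation standardization. Region-subdivided
analyses pool rows (sample-size-weighted) per partition level before
the PCA.

## Synthetic data generator

The generator defines the validation conditions. Defaults: ten
haplogroups named after the analysable backbone (D…R), three-site
motifs, within-haplogroup derived-mutation rate λ = 0.5 per sample,
transition:transversion draw 10:1, and two populations per cohort
whose haplogroup-frequency vectors are the pooled published northern
and southern East-Asia profiles — so the planted structure matches the
contrast the cohort statistics are meant to detect. Founder motif
positions are drawn without replacement across haplogroups, making
exclusivity true by construction; each sample adds its derived
mutations at positions no founder uses (infinite sites within the
window, collisions between samples possible), producing star
genealogies around each founder rather than full coalescent trees —
sufficient for motif, network and AMOVA testing, and a documented
simplification. `dropout_rate` is the per-site, per-sample probability
that a motif site reads as `N` (missing), emulating fragment
incompleteness rather than reversion to the reference. All randomness
derives from one master seed through named substreams (reference,
founders, samples).

What passing synthetic tests shows: the implementation recovers
planted motifs exactly on complete data, classifies at 100% accuracy
without noise and ≥95% at 20% per-site dropout, builds weight-optimal
networks, and has a correctly calibrated Φ_CT permutation test
(3–7% rejections at α = 0.05 under an exchangeable null; the
calibration uses 12 populations of 6, because with few populations the
group-permutation space is so small that the test's discreteness, not
its validity, dominates the rejection rate). What it does not show:
robustness to recurrent mutation at shared sites, to reference bias,
to ancient-DNA damage (deamination), or to motifs eroded by real
backbone paraphyly — real-data caveats the classifier's flags
(UNCLASSIFIED modes, conflict warnings, empty-motif warnings) are
designed to surface rather than hide.

## Problem sizes and numerical choices

The test suite runs the world-table PCA at full size (59 × 10); MST
oracle equivalence on 200 random instances of up to 8 haplotypes
(exhaustive enumeration beyond 8 nodes grows as n^(n−2) and adds
nothing); classification recovery on 500 samples (50 per haplogroup);
and AMOVA calibration on 1,000 simulated datasets of 72 individuals
with 199 permutations each. Floating-point tolerances: variance
percentages sum to 100 within 1e−9; Φ statistics are reported to full
double precision and compared with 1e−12 slack in permutation
rankings to make ties deterministic.

## Known limitations

* Insertions cannot be represented in fixed-length window sequences;
  they are supported as profile labels (e.g. `15495+C`) but not
  round-tripped through FASTA.
* The Hamming metric treats a transition and a transversion at the
  same site as two mismatches (label symmetric difference); per-site
  capping would change tied network topologies in rare cases.
* Motif inference assumes the training labels are correct and the
  backbone is cladistic within the window; it cannot detect label
  errors, only exclusivity violations.
* The AMOVA's frequency-only mode (`metric="haplotype_incidence"`)
  simply binarizes the distance matrix; it shares the Φ estimator
  machinery rather than re-deriving classical F-statistics from
  haplotype frequencies directly.
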