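# Methods

## Scope and model

`markersieve` evaluates concatenation markers for deep phylogenomic
placement problems.  It does not infer maximum-likelihood trees: the
site-heterogeneous inference step (e.g. C60 + PMSF mixtures with
UFBoot/SH-aLRT supports) is external.  The package prepares its inputs
(occupancy-filtered supermatrices, partition files, down-sampled taxon
sets) and consumes its outputs (newick gene trees whose internal labels
may carry dual `UFBoot/SH-aLRT` support strings, parsed by splitting on
`/`; a bare number is stored as UFBoot; missing components stay missing,
never 0, because 0 is a meaningful support value).

## Monophyly and congruence ranking

A lineage is monophyletic on an unrooted tree iff some edge bipartition
isolates exactly the lineage members present as leaves.  Lineages with
fewer than `min_present = 2` members present are excluded from the
denominator rather than counted as successes — a singleton is vacuously
monophyletic and would inflate scores of sparse markers.  A lineage
covering the entire leaf set is treated as (vacuously) monophyletic.
The score is the plain fraction of evaluable lineages recovered.  More
elaborate rankings (support-weighted, split-depth-penalized) exist in
the literature but are not restated in our sources; the fraction is the
auditable core, and per-lineage verdicts are retained on the score
object so weighted variants can be layered on.

Selection takes the top `round(fraction x n)` (half-up) of the
(score desc, n_evaluable desc, id asc) ordering; an explicit `k`
override exists because published set sizes (e.g. 60 of 248 at "25%")
need not equal the exact quarter.  The deterministic tie rule makes
output independent of input order, and guarantees the top-25% selection
is a prefix of the top-50% selection.

## Placement tendency

Per marker tree: root at the outgroup when outgroup leaves are present
(the pendant edge of the lexicographically first outgroup leaf — any
outgroup leaf gives the same focal sister as long as the focal clade is
inside the ingroup), else at the midpoint.  If the focal clade is absent
(< 2 leaves) or not monophyletic the marker is UNRESOLVED — conservative
and auditable, rather than a majority-vote placement.  Otherwise the
sister subtree's leaves are tallied by clade-series membership
(outgroup leaves ignored; leaves of clades in neither series count in
the denominator as "other").  WITH_A / WITH_B require a strict majority
(> 0.5 by default, configurable); an exact 50/50 mix is UNRESOLVED.
Venn regions over 2–4 marker selections partition the union by exact
membership signature; per-region WITH_B percentages are rounded to one
decimal, half-up, matching the precision the statistic is usually
quoted at.

## Supermatrix construction

"Present in at least a fraction *t* of the taxa" is read per column:
present = not `-` and not `?` (`X` is a residue of unknown identity and
counts as present); the threshold count is `ceil(t x n_taxa)` with
default t = 0.6.  Genomes lacking a marker get all-gap rows before
filtering (standard supermatrix practice) and hence count as absent.
Internal coordinates are 0-based half-open; partition files are written
1-based inclusive (`marker = start-end`), the common RAxML/IQ-TREE
dialect — the partition-file format is this package's choice, as no
particular dialect is mandated by the workflow it implements.  Columns
are never re-ordered, so concatenation is order-stable.  Alignment
trimming/masking is out of scope; inputs are assumed pre-trimmed.

Down-sampling of over-represented clades picks, per clade with a quota,
the subset greedily maximizing summed pairwise patristic distance on a
guide tree (seeded with the farthest pair; all ties break on the
lexicographically smallest id).  Focal and outgroup genomes always
bypass quotas.  Greedy max-dispersion is a 1/2-approximation, which is
ample for representative sampling.

## ESP profiles and UPGMA

Hit tables (genome, family, copy count) binarize to presence/absence;
duplicate rows merge.  The default profile distance is Jaccard (robust
to profile-size differences; 0 when both profiles are empty), with
Hamming as the alternative — no particular metric is canonical for this
analysis, so it is configurable and recorded.  UPGMA is implemented
directly to pin down determinism: merge the closest pair (ties: the
smallest cluster-index pair in creation order), height = distance / 2 so
cophenetic distances reproduce the linkage values, size-weighted average
update.  Tests cross-check the cophenetic matrix against SciPy's average
linkage and an independent brute-force recomputation.

## Synthetic data generator

The generator emulates the study design the pipeline targets: a rooted
species tree `(outgroup, (A-series, (focal, B-series)))` — an outgroup,
a TACK-like ladder of clades, an Asgard-like ladder, and a small focal
clade — with lognormal branch lengths (median ≈ 0.14 substitutions/site).
Defaults: 4 clades per series, 4 taxa per clade, 3 outgroup genomes,
focal size 2 (mirroring the two focal genomes typically available for a
newly proposed lineage), 200 markers.  Per marker, the gene tree is a
branch-length-jittered copy (multiplicative lognormal, sigma 0.2);
with probability `hgt_rate` (default 0.25) the focal clade is pruned and
regrafted onto a random edge inside the A or B series — excluding the
one regraft position that would recreate the original attachment, so a
recorded event always changes the topology; with probability
`contaminant_rate` (default 0.05) one non-focal ingroup leaf is moved to
a random edge more than three nodes away.  Contaminants are drawn from
the ingroup so outgroup rooting stays available; outgroup contamination
is outside the modeled scope.  Both event types preserve leaf counts,
keeping taxon sets comparable across markers, and every event is
recorded in a truth table (`clean` ⇔ no event ⇔ bipartition-identical to
the species tree).

Alignments evolve under an equal-exchangeability 20-state model
(probability a site differs after time *t*: (19/20)(1 − e^(−20t/19))),
root sequence uniform, no rate heterogeneity or indels.  Real archaeal
data are strongly site-heterogeneous; the simulation only needs enough
signal for recovery tests, so passing tests demonstrate the machinery's
correctness on idealized discordance, not robustness to compositional
bias, long-branch attraction or alignment error.  There is no
incomplete-lineage-sorting model: discordance arises solely from the
explicit graft/contaminant events.

ESP hit tables are generated with core families in every genome, a rich
family set shared by the B-series plus the focal clade (the Asgard-like
ESP complement) and a smaller A-series set, with symmetric presence/
absence flip noise (default 5%).

A deterministic synthetic stand-in reproduces the structure of the
published pooled-marker table (seven source sets pooling to 248
nonredundant markers, 12 from the asCOG namespace; four ranked
selections of sizes 28/56/60/120 sharing a 19-marker four-way core,
with 3 and 6 asCOGs in the two larger selections); it exercises the
pooling/subsetting machinery end to end and is labelled synthetic where
it is defined.

## Determinism and numerical choices

All randomness flows from `numpy.random.default_rng` seeded from the
config; identical (config, seed) gives byte-identical trees, alignments,
truth tables and pipeline outputs.  Derived per-alignment seeds are
drawn below 2³¹.  Ultrametricity is asserted to 1e-9.  Percentages use
decimal half-up rounding (never float banker's rounding).  Problem
sizes in the test suite — 200-marker recovery runs, exhaustive
monophyly checks over all 11,463 unrooted topologies with 4–8 leaves
(all member subsets through 6 leaves, seeded samples at 7–8), 6x6 UPGMA
oracles — were chosen to exercise each property thoroughly while keeping
the whole suite fast on a single CPU.

## Known limitations

- The congruence score ignores branch supports and split depth.
- Tendency classification is sister-composition only; "nested within a
  series" registers as WITH_A/WITH_B only via the sister tally, and a
  focal clade rendered paraphyletic by a contaminant is UNRESOLVED even
  when its placement is visually obvious.
- The occupancy filter treats `X` as present; workflows that treat
  ambiguity as missing should recode before concatenation.
- UPGMA assumes a constant-rate (ultrametric) signal; it is a profile
  summary, not a phylogeny.
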