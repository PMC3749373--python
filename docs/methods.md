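# Methods

This note documents the models, parameter choices and numerical conventions
behind `legumeks`, in the order the pipeline runs them.

## Scope and data model

The package analyses *gene families*: small sets of coding sequences, one or
a few per species, related by speciation and duplication. Inputs are
per-species CDS FASTA collections plus an optional gene-position table
(species, chromosome, 1-based gene-order index, derivable from GFF3 by
ranking gene features per seqid on start coordinate). All divergence is
measured in substitutions per site; synonymous divergence Ks serves as the
relative clock throughout.

## Homology search

The search is a seed-gated local alignment. A query/subject pair is
considered only if the two sequences share an exact 11-mer (the classic
BLASTN word size); sharing no such word means no reportable hit. Scoring is
BLASTN-like — match +2, mismatch −3, a gap of length g costs 5 + 2g — and
the alignment itself is a full affine-gap Smith–Waterman computed by
Biopython's pairwise aligner, so at desk scale the engine is exact rather
than heuristic. E-values use the Karlin–Altschul formula
`E = K·m·n·exp(−λS)` with defaults λ = 0.625, K = 0.41, m the query length
and n the summed CDS length of the subject's species; bit scores are
`(λS − ln K)/ln 2`.

Two engineering choices keep all-vs-all search affordable without changing
what passes the homology filter: each unordered pair is aligned once (the
scoring is symmetric; coordinates are swapped for the reverse direction),
and a fast edit-distance bound (edlib, infix mode) pre-screens pairs whose
divergence exceeds 0.4 — random coding sequences sit near 0.5 while
homologs that could reach the 70 %-identity filter sit well below 0.3. The
pre-screen can be disabled in `SearchConfig`.

Hit filtering keeps identity ≥ 70 % and E ≤ 1e−50; both boundaries are
inclusive. Orthologs are confirmed by bidirectional best hits (best = max
bit score, ties by lower E, higher identity, then subject id). Families are
connected components of the filtered hit graph seeded at anchor genes —
a deliberate simplification of Markov clustering that is appropriate when
families are anchored single genes; components containing several anchors
merge into one family. Families spanning fewer than 4 of the 6 species are
discarded.

## Codon-aware alignment and complete deletion

Ks/Ka estimation requires codon-respecting columns, so alignment happens in
amino-acid space (BLOSUM62, gap open 10, extend 0.5) and is back-translated;
every gap run is a multiple of three and reading frames survive. Trailing
stop codons are trimmed; internal stops are errors that name the codon
index. The multiple aligner is progressive: a guide order from pairwise
4-mer distances, profiles merged leaf-to-root by aligning their consensus
translations (majority codon per column; all-gap columns become X). For
substitution-only histories — which is what the simulator produces — this
reduces to exact stacking; with indels it yields standard progressive
behaviour without iterative refinement.

Complete deletion removes whole codon columns in which any row carries a gap
or an ambiguous nucleotide (IUPAC codes count as gaps). Removing whole
codons rather than single nucleotide columns keeps site counting
codon-consistent. Every downstream distance, rate, tree and bootstrap uses
only the surviving columns; an alignment with no surviving codon column is
an error rather than a silent fallback.

## Distances and Nei–Gojobori rates

The plain nucleotide p-distance and its Jukes–Cantor correction
`d = −(3/4)·ln(1 − (4/3)p)` are both reported, because "substitutions per
site" is model-ambiguous; trees use d by default.

Synonymous/nonsynonymous counting follows Nei–Gojobori (1986):

* **Sites.** Per codon position, the synonymous fraction is the share of
  the three single-nucleotide alternatives that preserve the amino acid,
  with stop-codon alternatives removed from numerator and denominator; S is
  the sum over positions and N = 3·codons − S, so per-codon counts always
  total 3.
* **Differences.** Codons differing at k ≤ 3 positions are connected by k!
  single-step paths; sd and nd are averaged over the paths that avoid stop
  codons. If every path is blocked, the k direct differences count as
  nonsynonymous — a conservative convention for an unresolvable corner.
* **Rates.** ps = Σsd / S̄ and pn = Σnd / N̄ with S̄, N̄ the means of the two
  sequences' site counts, each corrected with the Jukes–Cantor transform.
  A log argument ≤ 0 marks saturation: the rate is undefined and flagged,
  never infinite, and undefined values are skipped by medians, histograms
  and Ka/Ks summaries. Ka/Ks is undefined when Ks = 0.

By default pairs with fewer than 10 compared codons are rejected
(`min_codons`, relaxable) because proportions on a handful of codons are
dominated by sampling noise.

## Neighbor joining, bootstrap, clusters

NJ follows the standard Q-criterion agglomeration; among tied Q values the
smallest active index pair joins, making the algorithm deterministic for a
given input order (with exactly tied distances, any deterministic NJ is
necessarily input-order dependent). Negative branch-length estimates are
clamped to zero. The final three lineages join at a trifurcating root via
the three-point formulas, so additive matrices are recovered exactly — a
property the tests exercise on hundreds of random additive trees.

Bootstrap resampling draws codon columns (not nucleotides) with
replacement, rebuilds the distance matrix and tree, and scores each internal
split of the original tree by the percentage of replicates containing it.
Saturated Jukes–Cantor distances in replicates are capped at 5.0
substitutions/site so a replicate is never lost to a single saturated pair.

The one-vs-two-cluster reading of a family tree is formalized as: candidate
split = longest internal edge (ties: higher support, then lexicographically
smallest tip set); accepted when its support reaches `min_support`
(default 50 — the threshold is a package choice, configurable) and either
both sides have ≥ 2 tips or the split separates a same-species pair.
Newick output stores supports as internal node labels and lengths with six
decimals, which bounds round-trip precision at ~1e-6 per branch.

## Relation classification and tandem detection

With a two-cluster partition: same species + same cluster → inparalog, any
pair split across clusters → outparalog, different species + same cluster →
ortholog. With a single cluster, same-species pairs are outparalogs when
Ks > 0.40 and inparalogs otherwise; 0.40 sits between the speciation-peak
scale (~0.4) and the typical outparalog average (~0.5) and is configurable.
Undefined Ks defers to cluster evidence; a pair with neither is an error.
Tandem arrangement is approximated by gene order alone: same species, same
chromosome, order-index gap ≤ 1. Full synteny-block detection is out of
scope; positions missing from the table yield a warning and a False flag.

## Ks landscape

Per species pair, defined Ks values (tandem pairs excluded) are binned at
width 0.1 up to 2.0; values beyond the range go to an overflow count so
proportions plus overflow always total 1. A peak is a plateau of equal bins
strictly above both neighbours (boundaries count as open sides), reported at
its lowest-Ks bin; a plateau spanning the whole histogram is not a peak, and
peaks below 10 % proportion are ignored. Typing windows: center ≤ 0.15 →
recent WGD; ≤ 0.50 → speciation (widened downward because speciation peaks
between cool- and warm-season legumes can sit near 0.25); ≤ 0.80 → ancient
duplication; beyond → unassigned. All windows are configuration fields; a
1e-9 tolerance absorbs float noise in bin midpoints. Recent-WGD evidence is
read from within-species (paralog) distributions only: the shortest
cross-species ortholog divergences can straddle the recent-WGD window
boundary, but a cross-species distribution is not evidence for a genome
duplication in either species.

Species-pair summaries use the ortholog-Ks median (tandem excluded; for
within-species pairs, the non-tandem paralog median). The closest species
pair is the one attaining the per-family minimum ortholog Ks most often
(ties: lower median); the farthest attains the maximum most often (ties:
higher median); within-species comparisons are excluded from this report.
Selection pressure is summarized as per-gene mean Ka/Ks with categories
strong-negative (< 0.3), negative (< 1), positive (> 1); the global mean
averages per-gene means so each family counts once.

## The simulator

The generator emulates the six-legume study design; it is the ground truth
behind every recovery test.

* **Species tree.** Fixed topology
  `((Gm,(Cc,Pv)),(Lj,(Mt,Ca)))` with branch lengths in dS units,
  least-squares fitted so tip-to-tip distances reproduce observed ortholog
  Ks medians between the real genomes (Gm–Cc 0.212, Gm–Pv 0.212, Gm–Lj
  0.331, Gm–Ca 0.336, Gm–Mt 0.398, Mt–Ca 0.282, Mt–Pv 0.400, Mt–Cc 0.405);
  unprinted pairs (e.g. Cc–Pv ≈ 0.20) are interpolated from the topology.
  These lengths are calibration defaults, not assertions about any dataset.
* **Events.** Default: one ancient duplication at dS 0.65 applied before the
  first speciation (its copies descend the whole tree; cross-copy pairs are
  outparalogs), one whole-genome duplication on the Gm terminal branch at
  dS 0.1, one tandem duplication on the Mt branch at dS 0.05 with the copy
  placed at the adjacent gene-order index. Each duplicate-derived gene is
  lost with probability 0.3, mimicking post-duplication gene deletion.
* **Sequence evolution.** A branch of length t applies `round(t·S)`
  synonymous and `round(ω·t·N)` nonsynonymous single-nucleotide
  substitutions (S, N = NG86 site counts at branch start), placed uniformly
  over the currently eligible (codon, position, nucleotide) choices; changes
  creating stops are never eligible, repeated hits at a site are allowed —
  exactly the multiple-hit process the Jukes–Cantor correction undoes.
  Rounding causes a small-length bias; at the default 300 codons it is
  below 0.01 dS. ω is constant per family (default 0.2, matching strong
  purifying selection on essential genes).
* **Truth.** Relations come from the gene-tree node type at each pair's
  most recent common ancestor (speciation → ortholog; pre-speciation
  duplication → outparalog; terminal-branch duplication → inparalog), true
  dS from the path length between tips, true dN = ω·dS. Genomic placement
  puts ancient and WGD copies on different chromosomes and tandem copies at
  adjacent order indices, with ≥ 4-index gaps between unrelated genes.
* **Determinism.** One seed per spec; family i uses the stream seeded by
  (seed, i), so datasets are byte-identical across reruns and families are
  independent of each other's sampling.
* **Non-goals.** No indels, no among-site rate variation, no codon-usage
  bias, no segmental duplications. Consequently passing recovery tests
  shows the estimators and classifiers are correct under the stated model;
  it does not certify behaviour on real data with alignment uncertainty,
  rate heterogeneity or partial gene models.

## Problem sizes and defaults

The shipped study conditions are 20 families of 300 codons across six
species — comparable to a focused gene-set study (~250 genes, ~1 500
pairs). Bootstrap defaults to 1000 replicates; the acceptance script uses
200, which is ample for the split supports it checks. Estimator-recovery
checks use 20 seeds (single-branch) or 20 families (pipeline level);
neighbor-joining exactness uses 200 random additive matrices of 4–12 taxa.

## External reproduction

The two within-genome worked cases that motivated the classification rules
— a soybean inparalog pair with Ks ≈ 0.04 and an outparalog pair with
Ks ≈ 0.685 — can be reproduced by fetching the G. max v1.1 CDS release,
writing the two sequences per case to FASTA and running
`legumeks align`/`rates`; genome downloads are deliberately outside the
package and its tests.

## Known limitations

* Connected-component clustering can chain distinct families through a
  promiscuous intermediate; Markov-clustering refinement is a stretch goal.
* The consensus-profile progressive aligner has no iterative refinement;
  deep families with many indels would benefit from an external aligner
  (the pipeline accepts pre-aligned FASTA).
* NG86 with Jukes–Cantor correction underestimates Ks under strong
  transition/transversion bias; model-based estimators are config hooks,
  not implemented.
* Tandem detection is adjacency-only and depends on the provided gene
  order; it cannot distinguish the rare case of two independent genes
  sitting next to each other from a tandem pair — both signals (adjacency
  and relation label) are exposed so users can adjudicate.
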