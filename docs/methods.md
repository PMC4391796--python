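# Methods

`barcodegap` implements distance-based species delimitation for DNA-barcode
surveys: a mitochondrial barcode (COI-like) delimits molecular operational
taxonomic units (MOTUs) by genetic distance, a slower nuclear marker
(ITS2-like) cross-validates the boundaries, and the two are reconciled
specimen by specimen. This note records the models, the numerical choices,
and what the synthetic data do and do not show.

## Distances

Pairwise distances use the Kimura two-parameter (K2P) model, which corrects
the observed proportions of transitions (P) and transversions (Q) for
multiple substitutions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Distances are proportions internally and percentages only in reports.
Columns where either sequence has a gap, an N, or an IUPAC ambiguity code
are dropped per pair (*pairwise deletion*, the default — it wastes no data
on partial barcode fragments); *complete deletion* (drop such columns
globally) is available for sensitivity analysis since distance software
defaults differ on this point. When a log argument is non-positive the pair
is *saturated*: it is recorded as undefined, excluded from clustering edges,
and never imputed. The whole matrix is computed by one-hot matrix products
(16 n×L×n products), so a few hundred sequences take milliseconds.

## Threshold delimitation

A lineage at threshold t is a connected component of the graph with an edge
wherever d < t (strict inequality: ties at exactly t count as separated).
Single linkage is used deliberately: it is the only linkage whose output
guarantees that distinct lineages are separated by at least t, which is the
semantic of "lineages separated by more than X% divergence". The price is
chaining — an intra-lineage maximum can exceed t — and the per-lineage
statistics report observed ranges honestly rather than clipping them.

Conventions carried through all reports:

* haplotype collapsing for display joins sequences closer than 1% (single
  linkage again); the representative is the lexicographically lowest id and
  leaf labels carry an "Nind" member-count suffix. All sequences stay in
  the distance matrix; collapsing is display-only.
* singleton lineages report the sentinel `NC` ("not calculated") instead
  of an intra-lineage range.
* the "inter-lineage variability" of a lineage is its distance to the
  nearest other lineage. The nearest lineage is located by minimum pairwise
  distance; the reported statistic is either that minimum (`min_nearest`,
  default) or the mean of all pairs to that lineage (`mean_nearest`). Both
  are emitted because published variability tables rarely state their
  aggregator.
* a finer threshold t2 can be scanned inside each lineage
  (`sublineage_scan`); a lineage is reported when it separates at t2, with
  the maximum between-sublineage distance.

Default thresholds: 10% for the mitochondrial marker (the standard
congeneric cut-off for these taxa), 5% for the sublineage scan, 3% for the
nuclear marker, 1% for display collapsing.

## Automatic barcode-gap discovery

The barcode gap is the discontinuity between intraspecific and
interspecific distances in the ranked pairwise-distance distribution. The
published descriptions of the gap-discovery method pin down its inputs
(a log-spaced grid of prior maximum intraspecific divergences, default
0.001–0.1 in 10 steps, and a relative gap width X, here 1.0) but not its
internals, so the detector here is a documented reconstruction:

1. **Prior-derived start.** For prior P, the largest distance ≤ P marks the
   highest rank still presumed intraspecific; gaps are scanned from that
   rank on (from the first rank if every distance exceeds P). At least
   three preceding ranks of evidence are required.
2. **Significance.** A rank interval (d_i, d_{i+1}) is a gap when its width
   exceeds X times the local mean rank spacing, estimated over the
   preceding max(10, 5% of pairs) ranks.
3. **Partition.** Sequences are split into connected components with edges
   d ≤ gap-low, so the partition equals the threshold partition at any t
   inside the gap.
4. **Recursion.** Each group is re-scanned until no gap splits it. Inside a
   group the effective prior is capped at the group's mean pairwise
   distance — after a split, distances the parent pass treated as
   intraspecific must become eligible gap locations, otherwise nested
   divergence scales could never be resolved. A recursive split claims a
   coarser scale nested inside a group, so it must clear a stricter bar:
   a full window of preceding ranks and a width exceeding X times the
   gap's own lower edge. A "gap" that does not actually disconnect the
   graph is not a split.

Group counts fall as the prior grows (the familiar staircase; very small
priors oversplit by design). One partition is chosen by stability: the
contiguous run of priors with an identical recursive group count spanning
the widest prior interval (each grid point owns the linear interval between
the geometric midpoints to its neighbours), earliest run on ties. The
per-prior table, both initial and recursive counts, and the distance
histogram are always emitted so the staircase can be inspected.

## Neighbor-joining trees and bootstrap

NJ follows the standard agglomeration with selection criterion
Q(i,j) = (n−2)d(i,j) − r_i − r_j. Ties are broken deterministically toward
the pair whose clusters contain the lexicographically lowest leaf ids, so
a given matrix always yields the same tree. Negative branch lengths are
clamped to zero and counted; on additive matrices the clamp count is zero
and NJ provably reproduces the generating tree, which the tests assert
exactly. Bootstrap support resamples alignment columns with replacement
from a single seeded stream in fixed replicate order (reproducibility is
preferred over parallelism); support is the percentage of successful
replicates containing the same leaf bipartition, replicates with saturated
matrices are skipped and counted. Newick output prints support only above
a display floor (default 80%).

## Median-joining haplotype networks

Before network construction the alignment is recoded so that every
mutational event weighs one step: each variable column is a substitution
character; each distinct maximal gap run (any length ≥ 1) is one binary
indel character — *simple indel coding*, which realises "a 5-bp deletion is
one event, not five"; annotated structural rearrangements (e.g. a known
inversion, which cannot be auto-detected from an alignment) are one binary
character each, their columns excluded from substitution coding. A residue
column under another sequence's gap scores as missing and is skipped
pairwise.

The network is the classic median-joining construction: the union of all
minimum spanning trees of the haplotype Hamming graph (the minimum spanning
network at tolerance ε, default 0), iteratively augmented with median
vectors — per-character majority consensus of triplets adjacent in the
current network. A candidate median must pass the local triplet test
(connecting the triplet through it is cheaper than the triplet's spanning
connection) and is accepted only if it strictly lowers the minimum spanning
weight of the whole node set; acceptance is therefore monotone (the
recorded spanning-cost history is non-increasing, asserted by tests) and
the loop terminates. Median vectors of degree ≤ 2 lying on no geodesic
between observed haplotypes are pruned as obsolete. Clone sequences enter
as individual nodes with the specimen as a node attribute, since
intra-individual copy polymorphism is precisely what the network is meant
to expose. The exact median search is exponential in principle and intended
for clade-scale inputs (tens of haplotypes, as in published network
figures), not whole-survey alignments.

## Two-marker concordance

Cross-marker comparison is specimen-mediated (sequence-level identity is
undefined across loci). Discrepancies are typed: *merge* (one lineage of
marker B spans several of marker A), *split* (the inverse), and *tangled*
(divergent copies from the same specimen fall in different lineages —
multi-copy nuclear behaviour; such specimens are flagged, never
force-assigned, and excluded from the merge/split accounting). The
diversity summary counts morphotaxon labels against genetic lineages per
higher group: identified species count, as do group labels carried by
immatures ("with/without hair setae" style bins); unlabelled immatures
contribute to lineage counts only. A morphotaxon spanning ≥ 2 lineages is
reported as a cryptic complex. Published totals of this kind depend on
unstated counting rules for immature groups; the rule above is this
package's fixed, documented choice.

## Synthetic data

The generator targets *distance structure*, not population-genetic process
(no coalescent, recombination, or selection — a stated non-goal). K
lineage ancestors radiate from a random root so that between-lineage
pairwise K2P distances land in `inter_divergence` (default 0.12–0.25);
members sit `intra_divergence` (default 0–0.02) from their ancestor, giving
within-lineage pairs up to ~4%; a barcode gap exists by construction and
the constructor refuses configurations that destroy it unless asked.
Substitutions are placed by expected-count inversion: for a target K2P
distance the transition/transversion counts are solved in closed form
(transition fraction κ/(κ+2), κ = 4 by default) and placed on random
distinct sites, so realized distances track targets up to binomial noise
plus the slight upward convexity of the correction when branches
concatenate. The second marker evolves at 0.25× the rate, carries
lineage-level multi-base indel blocks (Poisson 0.5 per lineage, 2–8 bp)
realised as shared gap columns, and is sequenced as 1–4 clones per specimen
with per-site copy noise 0.002 — emulating a multi-copy nuclear marker.
Everything derives from one seeded generator: identical configs give
byte-identical FASTA.

Planting knobs create the interesting failure modes with known truth:
sublineages a chosen divergence apart inside a lineage (cryptic structure
between two thresholds), lineage pairs just above a threshold, pairs with
identical slow-marker ancestors (marker discordance), and foreign clones
in one specimen (copy polymorphism). `survey_config` combines them into a
realistic survey: 41 lineages over 185 specimens with a long-tailed size
profile (1–44), four sublineages diverging ~6–10%, one pair ~10.4% apart,
one slow-marker merge and one tangle, plus shared morphotaxon labels
(two immature groups of three lineages, cryptic complexes of 4, 5 and 2)
and one unlabelled lineage.

What passing tests show — and do not. Recovery of planted truth by both
the 10% threshold and gap discovery (asserted over 20 seeds) demonstrates
internal consistency under a clean, planted gap; it says nothing about
taxa whose real distance distributions overlap, about alignment error
(inputs are aligned by construction), or about saturation at deep
divergences. The generator's star-shaped lineages also lack real
phylogenetic substructure, which is why the recursive gap scan is tested
separately on constructed nested-scale matrices.

## Problem sizes and numerics

The test suite and the acceptance script run at survey scale (185×600 nt
and ~490×400 nt alignments, 100 bootstrap replicates, networks on
clade-sized subsets) and complete in well under a minute; these sizes are
the package's intended desk scale. Degenerate inputs are defined rather
than accidental: < 2 sequences refuse a matrix, ≤ 2 sequences yield a
trivial gap partition with a warning, a single haplotype yields a
single-node network with a warning, empty FASTA writes warn. Distances are
float64 throughout; K2P agreement with a brute-force column walk is
asserted to 1e-12 and NJ additivity to 1e-9.

## Known limitations

* The gap-discovery internals are a reconstruction from the method's
  published inputs; on clean-gap and nested-scale instances any reasonable
  estimator agrees (that is the tested contract), but exact per-prior
  agreement with the original program on noisy real data is not claimed —
  in particular the recursive partition is conservative by design where
  the original is known to oversplit.
* Maximum-likelihood tree inference, model selection, alignment, and
  reference-database identity assignment are out of scope; trees here are
  illustrative NJ, and alignment is an input contract.
* Published diversity totals that depend on how immature specimens were
  binned can differ by ±1–2 from this package's fixed counting rule.
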