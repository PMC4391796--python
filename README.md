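# barcodegap

Distance-based species delimitation for DNA-barcode surveys of
morphologically difficult invertebrates (the motivating case: aquatic
oligochaetes used as sediment-quality bioindicators, where most field
specimens are immature and unidentifiable). Given aligned sequences of a
mitochondrial barcode (COI) and optionally a slower nuclear marker (ITS2),
the package delimits molecular operational taxonomic units (MOTUs),
validates them with automatic barcode-gap discovery, draws
neighbor-joining trees with bootstrap and median-joining haplotype
networks, and reconciles the two markers and the morphology specimen by
specimen.

## The method

Pairwise distances use the Kimura two-parameter model, correcting the
observed transition (P) and transversion (Q) proportions for multiple
hits:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Lineages at threshold *t* are single-linkage components of the graph with
edges d < t, the only clustering rule that guarantees output lineages are
separated by at least *t* (defaults: 10% for COI, 3% for ITS2, with a 5%
within-lineage scan and 1% display collapsing). The barcode gap — the
discontinuity between intra- and interspecific distances — is also found
automatically: over a log-spaced grid of prior intraspecific divergences,
the first rank interval of the sorted distances that is wide relative to
the local slope (relative gap width X = 1.0) cuts the data into groups,
recursively within groups, and the partition stable over the widest prior
range is chosen. Haplotype networks recode every mutational event at equal
weight (each multi-base indel block or annotated inversion is a single
step) and join all minimum spanning trees through cost-reducing median
vectors. All of it is seeded and deterministic.

A synthetic-data generator produces two-marker datasets with known truth
(lineages with a planted barcode gap, transition bias, a slow marker with
indel blocks and clone polymorphism), so the whole pipeline is testable
without any field data.

## Worked example

Generate a survey-shaped dataset (41 planted lineages, 185 specimens,
lineage sizes 1–44, four cryptic sublineages diverging 6–10%) and delimit:

```
$ python analysis/01_simulate_survey.py --seed 1
$ python analysis/02_delimit_coi.py --seed 1
41 lineages at the 10% threshold
  L10: 2 sublineages at 5%, max divergence 9.29%
  L17: 2 sublineages at 5%, max divergence 9.10%
  L33: 2 sublineages at 5%, max divergence 6.84%
  L40: 2 sublineages at 5%, max divergence 7.40%
```

The 10% threshold recovers all 41 planted lineages; the 5% scan exposes
exactly the four planted sublineages that the coarser threshold absorbs,
with their between-sublineage divergences. Gap discovery confirms the
delimitation without being told any threshold — at the largest default
prior its initial pass finds the same 41 groups:

```
$ python analysis/03_barcode_gap.py
   prior  gap_low  gap_high  n_groups_initial  n_groups_recursive
   ...
0.059948 0.059249  0.060985                44                  45
0.100000 0.092911  0.110304                41                  43
```

(Small priors oversplit by design; the staircase of counts is the
diagnostic output.) The ITS2 networks separate the lineage pair that sits
only ~10.4% apart in COI by 12 mutational steps, while the planted
marker-discordant pair collapses onto identical ITS2:

```
$ python analysis/04_its2_network.py
merge_pair: 9 nodes (0 medians); SIM14-SIM15 separated by 0 steps
tangle_pair: 30 nodes (0 medians); SIM16-SIM17 separated by 21 steps
close_pair: 8 nodes (1 medians); SIM39-SIM40 separated by 12 steps
$ python analysis/05_concordance.py
185 shared specimens, 3 raw discrepancies:
  tangled: COI A17 vs ITS2 B15/B16 (specimens iso086)
  merge: COI A14/A15 vs ITS2 B14 (specimens iso081, ...)
  merge: COI A39/A40 vs ITS2 B38 (specimens iso181, ...)
```

The same steps are available as a CLI on any externally aligned FASTA:
`barcodegap simulate|delimit|abgd|network|compare --help`.

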