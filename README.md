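# polykaryo

Comparative-genomics toolkit for studying how a polyploid crucifer genome
descends from the eight-chromosome ancestral crucifer karyotype (ACK).
It was built around the analyses needed for a diploid/tetraploid species
pair such as flixweed (*Descurainia sophia*): tracing ancestral genomic
blocks through chromosome fusions and rearrangements, asking whether the
tetraploid's two subgenomes show fractionation or expression dominance,
dating the polyploidy event from synonymous divergence, and screening
UDP-glycosyltransferase (UGT) candidates whose expression tracks
quercetin-glucoside accumulation.

## What it computes

- **Synteny.** Homolog pairs with collinear flanking support become
  syntenic orthologs; consecutive pairs separated by fewer than 50
  intervening genes *or* by at most 300 kb (in both genomes) are chained
  into syntenic fragments.
- **Genomic-block projection.** Fragments against an ancestor proxy whose
  genes carry block labels (A–X, 22 blocks on ACK1–ACK8) yield block
  projections on the descendant; from these come per-block copy numbers,
  block-adjacency (association) conservation, and chromosome-level events
  — intact inheritance vs fusion, with a rearrangement flag.
- **Subgenomes.** Homoeologous chromosome pairs by maximum-weight matching
  on self-synteny; the denser chromosome of each pair forms subgenome A.
  Gene retention per subgenome is profiled against the ancestor, and
  homoeolog expression dominance is counted at fold thresholds 1–8 with a
  binomial sign test.
- **Ks dating.** Nei–Gojobori (1986) codon counting with equal-weight
  pathway averaging (stop-codon pathways excluded) and the Jukes–Cantor
  correction `Ks = −(3/4)·ln(1 − (4/3)·ps)`; whole-genome duplications
  appear as peaks in the Gaussian-KDE of the paralog Ks distribution.
- **Candidate screen.** A 44-residue PSPG-box scan anchored on the five
  activity-critical residues (W1, Q4, H19, S24, E27), a Pearson screen of
  expression against the Q3G + Q7G total (pass at r > 0.75, P < 1e−5,
  p-value from `t = r·sqrt((n−2)/(1−r²))`), and per-compound fold-change
  statistics with a four-fold differential rule.

A seedable forward simulator of karyotype evolution (fusion, inversion,
translocation, whole-genome duplication, gene loss, expression bias)
generates every input with ground truth attached, so the whole pipeline
is exercised end to end without external data.

## Worked example

Run the full simulated-data pipeline (22 blocks × 50 genes, fusion of
ACK6 and ACK8, post-fusion inversion, whole-genome duplication with 5%
per-subgenome gene loss):

```sh
polykaryo run --outdir demo --seed 1
```

The stage summary printed at the end (also in `demo/manifest.json`):

```json
"karyotype": {
  "diploid":    {"projections": 24, "fusions": 1, "intact": 6, "association_recovery": 1.0},
  "tetraploid": {"projections": 48, "fusions": 2, "intact": 12, "association_recovery": 1.0}
},
"subgenome": {
  "homoeolog_chromosome_pairs": 7,
  "homoeolog_gene_pairs": 1004,
  "retention_DsA": 0.9673,
  "retention_DsB": 0.9455,
  "min_dominance_p": 0.375
},
"ks":     {"pairs": 500, "peak": 0.115},
"screen": {"pspg_hits": 20, "screen_pass": 3, "planted_recovered": 3,
           "differential_compounds": 3}
```

Reading this: all 22 ancestral blocks are recovered at one copy in the
simulated diploid and two in the tetraploid; six ancestral chromosomes
are inherited intact and one fusion (ACK6 + ACK8) is called, flagged as
rearranged. Both subgenomes retain ≈ 95% of ancestral genes (the 5%
loss rate), no dominance test reaches significance (unbiased expression),
the Ks peak sits at the simulated divergence of 0.12 (grid argmax 0.115
under the default bandwidth), and the correlation screen recovers exactly
the three genes planted to track the quercetin-glucoside total, while
the three glucosides — but not quercetin itself — exceed the four-fold
differential rule.

Individual stages are available as subcommands (`simulate`, `synteny`,
`karyotype`, `ks`, `screen`; see `polykaryo --help`) operating on GFF3/BED,
TSV and FASTA files.

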