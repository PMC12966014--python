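# Methods

This note documents the models, rules and numerical choices behind each
module, the conditions the simulator emulates, and what the test suite
does and does not establish about real data.

## Coordinate and ordering conventions

All internal intervals are 0-based half-open; GFF3 (1-based closed) is
converted at the I/O boundary. A gene's *rank* is its ordinal position
along its chromosome ordered by start coordinate, ties broken
lexicographically by gene id (ties cannot be resolved biologically
without transcript evidence; the lexicographic rule makes runs
reproducible). Strand is carried through but ignored by the chaining
rule; it only informs fragment orientation labels.

## Syntenic pairs and fragment chaining

A homolog pair (a, b) is called syntenic when at least `min_support`
(default 2) other homolog pairs lie within `flank_window` (default 20)
ranks of *a* and of *b* on the same chromosome combination. These two
parameters are not biologically canonical; small windows enforce strict
collinearity, which is the regime the rest of the pipeline assumes.
Emitted pairs are deduplicated to the best-supported partner per query
gene; a reference-side gene may partner one query gene per query
chromosome, because a polyploid maps 2:1 onto its ancestor with the two
homoeologs on different chromosomes. Ties break by similarity, then id.

Chaining consolidates consecutive pairs (sorted by query rank, per
chromosome combination) when, **in both genomes**, the intervening gene
count is strictly below 50 **or** the genomic distance is at most
300 kb. The strict/inclusive readings and the both-genomes requirement
are deliberate: the count criterion is phrased as "fewer than", the
distance as "within", and requiring both genomes is the conservative
interpretation of a rule whose sidedness is ambiguous (`--one-genome`
relaxation available via `require_both_genomes=False`). Distance is
measured between the nearest ends of the boundary genes. Fragments are
maximal chains, so they partition the input pairs; an in-suite oracle
checks equivalence with the transitive closure of the consecutive-merge
relation on instances of ≤ 200 genes.

## Genomic-block projection and karyotype events

Within each fragment, maximal runs of pairs whose ancestral partner
shares a block label become projections; runs below `min_genes_per_call`
(default 5 — prevents single-gene block calls; any value ≤ block size
works on simulated data) are dropped, and same-label projections left
adjacent on one chromosome within the chaining gap are merged. Purity is
the labelled fraction of the host fragment; unlabelled partners dilute
purity but never error.

**Copy counting** groups projections of a label by descendant chromosome
(default): an intrachromosomal inversion can split a block into two
distant projections, but the block is still present once, and the
per-chromosome rule keeps copy counts invariant under such
rearrangements. The raw-projection count (`distinct_chromosomes=False`)
exists for tandem-duplication questions, where two copies genuinely sit
on one chromosome.

Block associations are unordered adjacent label pairs along a
chromosome (presence/absence comparison only; orientation is not part of
an association). Association recovery is |detected ∩ ancestral| /
|ancestral|.

For chromosome events, an ancestral chromosome *contributes* to a
descendant chromosome when its blocks cover ≥ 10% of the descendant's
projected span — small enough to catch real fusion partners, large
enough to ignore translocated slivers. One contributor ⇒ intact
inheritance, several ⇒ fusion. The rearrangement flag compares the
projected block order per contributor with the ancestral block order,
accepting a full reversal; any other order (including a block split
around foreign blocks) flags the chromosome.

## Subgenome analysis

Homoeologous chromosome pairs come from maximum-weight matching
(networkx) on shared self-synteny pair counts; every chromosome must be
matched, so an odd chromosome count is an error naming the leftovers.
Within each pair the chromosome with higher gene density (genes/Mb)
joins subgenome A, following the density convention for this species
pair; exact ties fall back to name order with a warning. When synteny
links chromosomes across different pairs into linkage groups, a majority
vote harmonizes the group (logged); on clean autotetraploid simulations
each pair is its own group and the local rule decides.

Retention is the fraction of ancestral genes with at least one syntenic
partner in the subgenome, reported globally and in sliding windows
(default 100 genes, step 50 — wide enough to smooth single-gene loss,
narrow enough to localize segmental loss).

Expression dominance uses replicate-mean TPM per tissue and the ratio
`(TPM_A + 0.1) / (TPM_B + 0.1)`. The pseudocount (0.1 TPM) stabilizes
ratios near zero. "Greater than 1- to 8-fold" is read as linear ratio
thresholds f = 1..8 with strict inequality; a log2 mode exists behind a
flag since the phrasing admits both readings. Counts are monotone
non-increasing in f by construction. Bias is assessed with a two-sided
binomial sign test (null p = 0.5 over dominant pairs) — the simplest
test of "more genes dominant on one side", since no specific test is
canonical here.

## Ks estimation and peak detection

The estimator is Nei–Gojobori (1986) with the standard genetic code:
per-codon synonymous site fractions (each of the three changes per
position classified; changes to stop codons are nonsynonymous), averaged
over the two sequences; observed differences resolved by equal-weight
averaging over all substitution pathways, excluding pathways through
stop codons (falling back to all pathways if every one is blocked); and
Jukes–Cantor correction for multiple hits. `ps ≥ 3/4` raises a
saturation error; batch estimation records such pairs as missing.
Codons are precomputed into 64×64 difference tables, so genome-scale
inputs vectorize. The implementation is checked against an exhaustive
in-test pathway enumerator and, on stop-free instances, against an
independent library implementation.

Peak detection evaluates a Gaussian KDE on a fixed grid (0–3, step
0.005) after discarding estimates above Ks = 3 (saturation regime, a
conventional cutoff). Bandwidth defaults to Silverman's rule, with a
fixed-bandwidth option for reproducibility. The major peak is the grid
argmax; secondary peaks need ≥ 10% of the maximum density and ≥ 0.1 Ks
separation. A degenerate (zero-variance) sample returns its value as the
peak rather than failing.

## Candidate screening

The PSPG scan slides a 44-residue window and counts matches at the five
anchor positions (motif positions 1 W, 4 Q, 19 H, 24 S, 27 E);
`min_anchor_matches` defaults to 4, tolerating one substituted anchor.
Overlapping windows collapse to the best-scoring hit. A full
profile-HMM/BLASTP search is an external-tool step; the anchored scan is
the self-contained path and external hit tables can be substituted where
available.

The correlation screen aligns samples by id, computes Pearson r per
candidate against the per-sample metabolite total (Q3G + Q7G by default,
configurable to include the diglucoside), and converts r to a two-sided
p-value through the exact t-transform with n − 2 degrees of freedom.
Constant expression vectors yield r = NaN and never pass. Note that with
few samples the stock thresholds (r > 0.75 *and* P < 1e−5) are extremely
stringent — at n = 6, even r = 0.9 gives p ≈ 0.015 — so the sample count
drives the screen's yield; thresholds are applied as configured rather
than rescaled.

Fold changes are ratios of group means with nearest-integer reporting
(half away from zero) and a symmetric four-fold differential rule; a
zero denominator produces an infinite-fold sentinel flagged
differential rather than an error.

## The simulator: what it emulates, and what it does not

The simulator realizes the study conditions: an 8-chromosome ancestor
carrying 22 labelled blocks (the bundled A–X layout over ACK1–ACK8, with
the two merged sub-block letters unused), descent through fusion of two
ancestral chromosomes followed by an inversion spanning a random 10–30%
of the fused chromosome ("rearranged" is otherwise unspecified, so a
single inversion is the modelling choice, exposed in the scenario
config), an autotetraploid whole-genome duplication (the two subgenomes
start identical, as in autopolyploidy), independent per-subgenome gene
loss below 10%, homoeolog expression log2 fold-changes centred at zero
(no built-in dominance), paralog synonymous divergence at true Ks 0.12,
and metabolite panels whose target-compound levels default to the
measured seed contents of the two accessions.

Genes sit on a uniform grid (10 kb per slot, 2 kb genes), chosen so that
the chaining rule's gene-count and distance criteria are both
exercisable with exact arithmetic. Gene loss vacates the slot rather
than compacting the chromosome, so fractionation genuinely lowers gene
density — which is what the density-based subgenome partition relies on.
Structural events re-grid the affected chromosomes.

Codon alignments use only codon families with C at the second position:
their third position is fully synonymous and their first position fully
nonsynonymous, with no stop codon reachable, so the synonymous sites
form an exact Jukes–Cantor process at the requested divergence and the
estimator's consistency can be tested without confounding. The
nonsynonymous rate defaults to a quarter of the synonymous rate.

Randomness: one root seed; each event and each omics generator draws
from its own stream derived via `SeedSequence(seed, spawn_key=(i,))`, so
appending an event never perturbs earlier ones and runs are
byte-reproducible.

What the simulator does *not* model: nucleotide-level assembly,
transposons and repeats, read-level noise, tandem duplication, unequal
progenitor divergence (allopolyploidy), dosage-dependent expression
evolution, or correlated gene loss. Passing tests therefore demonstrate
that the analysis recovers the generating process under clean,
grid-regular conditions — they do not certify performance on real
assemblies, where fragmentation, annotation error and repeat-driven
false homology dominate the difficulty.

## Problem sizes

The bundled test and demonstration configurations use 22 blocks × 50
genes (1,100-gene genomes) for karyotype recovery, 22 × 100 (2,200
genes per subgenome after duplication) for retention, 2,000 paralog
pairs × 300 codons for the Ks peak, and a few hundred decoy genes for
the screen — sizes at which every statistical check is already stable
while whole runs finish in seconds. The genome-scale counts of a real
species pair (tens of thousands of syntenic pairs and paralogs) require
the deposited assemblies and are outside what a simulation can
meaningfully reproduce; the property-based suites (chaining-rule oracle
equivalence, pathway-averaging equivalence, partition/symmetry/
monotonicity invariants, planted-signal recovery) stand in for them.

## Known limitations

- The per-chromosome copy-counting default undercounts genuine tandem
  block duplications on one chromosome (switch to raw projections for
  that question).
- The density-based subgenome partition needs a real density contrast;
  with equal loss rates the assignment within each pair is effectively
  arbitrary (and warned) — downstream dominance counting is symmetric,
  so conclusions about *absence* of dominance are unaffected.
- The anchored PSPG scan is a motif heuristic, not a domain model; on
  random decoys it admits rare false hits, which the correlation screen
  is expected to remove.
- NG86 assumes equal base frequencies and no transition/transversion
  bias; for real paralog sets a model-based estimator would shift Ks
  slightly.
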