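"""Forward simulator of crucifer karyotype evolution.

Generates every input the analysis pipeline consumes — annotations,
homology, expression, metabolite panels and paralog codon alignments —
from an 8-chromosome ancestral karyotype partitioned into labelled
genomic blocks (GBs), with full ground truth (GB label, subgenome of
origin, true synonymous divergence) recorded for parameter-recovery
tests.

Genes live on a uniform coordinate grid (one slot per gene, configurable
spacing and gene length) so that both halves of the fragment-chaining
rule — intervening-gene counts and base-pair distances — are exercised
with predictable arithmetic.

Evolution is expressed as an ordered list of events (fusion, inversion,
translocation, whole-genome duplication, gene loss, expression bias).
Each event draws from its own RNG stream derived from the scenario seed,
so appending an event never perturbs the outcome of earlier ones.
"""

from __future__ import annotations

import copy
import math
import string
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .ks import CodonAlignment
from .model import (
    ExpressionMatrix,
    GBDefinitionTable,
    GeneModel,
    GenomeAnnotation,
    HomologyTable,
    MetaboliteTable,
    ReferenceError_,
    ValidationError,
)

DEFAULT_SPACING_BP = 10_000
DEFAULT_GENE_LENGTH = 2_000

# Seed contents (mg/kg) measured in the tetraploid (high-quercetin-glucoside)
# and diploid accessions; used as simulation defaults for the metabolite panel.
DEFAULT_METABOLITE_LEVELS = {
    "quercetin": (2.83, 1.48),
    "Q3G": (454.84, 6.88),
    "Q7G": (176.02, 2.91),
    "Q3,7G": (125.96, 0.71),
}


# ---------------------------------------------------------------------------
# events & scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fusion:
    chrom_a: str
    chrom_b: str


@dataclass(frozen=True)
class Inversion:
    """Invert a rank span [start, end) on a chromosome.

    With ``start is None`` the span is drawn at random covering 10-30% of
    the chromosome (the default 'rearranged after fusion' behaviour).
    """

    chromosome: str
    start: int | None = None
    end: int | None = None


@dataclass(frozen=True)
class Translocation:
    src_chrom: str
    start: int
    end: int
    dest_chrom: str
    dest_pos: int


@dataclass(frozen=True)
class WGD:
    pass


@dataclass(frozen=True)
class GeneLoss:
    rate: float
    subgenome: str | None = None  # None: both; "A"/"B": restrict


@dataclass(frozen=True)
class ExpressionBias:
    """Homoeolog log2 fold-change distribution (mean, sd)."""

    log2_mean: float = 0.0
    log2_sd: float = 0.5


Event = Fusion | Inversion | Translocation | WGD | GeneLoss | ExpressionBias


@dataclass
class EvolutionScenario:
    events: list[Event]
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(isinstance(e, WGD) for e in self.events) > 1:
            raise ValidationError("wgd may appear at most once in a scenario")
        for e in self.events:
            if isinstance(e, GeneLoss) and not (0.0 <= e.rate < 1.0):
                raise ValidationError(f"gene_loss rate {e.rate} outside [0, 1)")

    @property
    def expression_bias(self) -> ExpressionBias:
        for e in self.events:
            if isinstance(e, ExpressionBias):
                return e
        return ExpressionBias()

    def event_rng(self, index: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(index,)))


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

@dataclass
class SimGene:
    family: str             # shared by all orthologs/paralogs of one ancestral gene
    strand: str = "+"
    gb_label: str | None = None
    subgenome: str | None = None
    slot: int | None = None  # frozen grid slot; set by gene loss so deletions leave gaps


@dataclass
class SimulatedGenome:
    """Ordered gene content per chromosome on a uniform coordinate grid."""

    genome_id: str
    chromosomes: dict[str, list[SimGene]]
    spacing_bp: int = DEFAULT_SPACING_BP
    gene_length: int = DEFAULT_GENE_LENGTH

    def gene_id(self, gene: SimGene) -> str:
        gid = f"{self.genome_id}_{gene.family}"
        if gene.subgenome:
            gid += f"_{gene.subgenome}"
        return gid

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def annotation(self) -> GenomeAnnotation:
        genes = []
        lengths = {}
        for chrom, content in self.chromosomes.items():
            last_slot = 0
            for pos, g in enumerate(content):
                slot = g.slot if g.slot is not None else pos
                last_slot = max(last_slot, slot)
                start = slot * self.spacing_bp
                genes.append(
                    GeneModel(
                        gene_id=self.gene_id(g),
                        chromosome=chrom,
                        start=start,
                        end=start + self.gene_length,
                        strand=g.strand,
                        family=g.family,
                    )
                )
            lengths[chrom] = max(last_slot + 1, 1) * self.spacing_bp
        return GenomeAnnotation(self.genome_id, genes, lengths)

    def truth(self) -> pd.DataFrame:
        """Per-gene ground truth: GB label and subgenome of origin."""
        rows = []
        for chrom, content in self.chromosomes.items():
            for pos, g in enumerate(content):
                rows.append(
                    {
                        "gene_id": self.gene_id(g),
                        "chromosome": chrom,
                        "slot": g.slot if g.slot is not None else pos,
                        "family": g.family,
                        "gb_label": g.gb_label,
                        "subgenome": g.subgenome,
                    }
                )
        return pd.DataFrame(rows)

    def subgenome_of(self) -> dict[str, str | None]:
        """Chromosome -> subgenome label (None before WGD)."""
        out: dict[str, str | None] = {}
        for chrom, content in self.chromosomes.items():
            subs = {g.subgenome for g in content}
            out[chrom] = subs.pop() if len(subs) == 1 else None
        return out


@dataclass
class AncestralKaryotype:
    chromosomes: list[str]
    blocks: dict[str, tuple[str, list[str]]]  # label -> (chromosome, gene ids)
    genes_per_block: int

    def gb_table(self) -> GBDefinitionTable:
        return GBDefinitionTable({k: (c, list(g)) for k, (c, g) in self.blocks.items()})


def load_ack_block_layout() -> dict[str, str]:
    """The bundled block -> ancestral-chromosome layout (22 blocks, ACK1..ACK8)."""
    with resources.files("polykaryo.data").joinpath("ack_blocks.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["block"], df["chromosome"]))


def build_ancestral_karyotype(
    n_blocks: int = 22,
    genes_per_block: int = 50,
    spacing_bp: int = DEFAULT_SPACING_BP,
    gene_length: int = DEFAULT_GENE_LENGTH,
    genome_id: str = "ancestor",
) -> tuple[AncestralKaryotype, SimulatedGenome]:
    """Build the ancestral genome: 8 chromosomes carrying labelled blocks.

    With the default 22 blocks the bundled ancestral-crucifer layout is
    used; other block counts are distributed round-robin over the eight
    chromosomes. Block labels beyond 'Z' are unavailable.
    """
    if n_blocks < 1 or genes_per_block < 1:
        raise ValidationError("n_blocks and genes_per_block must be >= 1")
    if n_blocks > 26:
        raise ValidationError(f"cannot label {n_blocks} blocks with single letters A-Z")
    chrom_ids = [f"ACK{i}" for i in range(1, 9)]
    if n_blocks == 22:
        layout = load_ack_block_layout()
    else:
        letters = string.ascii_uppercase[:n_blocks]
        layout = {lab: chrom_ids[i % 8] for i, lab in enumerate(letters)}

    chromosomes: dict[str, list[SimGene]] = {c: [] for c in chrom_ids}
    blocks: dict[str, tuple[str, list[str]]] = {}
    genome = SimulatedGenome(genome_id, chromosomes, spacing_bp, gene_length)
    for label, chrom in layout.items():
        gene_ids = []
        for i in range(genes_per_block):
            fam = f"{label}{i:04d}"
            g = SimGene(family=fam, gb_label=label)
            chromosomes[chrom].append(g)
            gene_ids.append(genome.gene_id(g))
        blocks[label] = (chrom, gene_ids)
    # chromosomes left empty by sparse layouts are dropped
    for c in list(chromosomes):
        if not chromosomes[c]:
            del chromosomes[c]
    kary = AncestralKaryotype(list(chromosomes), blocks, genes_per_block)
    return kary, genome


# ---------------------------------------------------------------------------
# scenario application
# ---------------------------------------------------------------------------

def apply_scenario(
    genome: SimulatedGenome, scenario: EvolutionScenario, new_genome_id: str = "descendant"
) -> SimulatedGenome:
    """Evolve ``genome`` through the scenario's events, in order.

    Returns a new genome (the input is untouched) whose gene ids are
    re-derived from ``new_genome_id`` and each gene's family, so ancestor
    and descendant never share gene ids.
    """
    out = SimulatedGenome(
        new_genome_id,
        {c: [copy.copy(g) for g in genes] for c, genes in genome.chromosomes.items()},
        genome.spacing_bp,
        genome.gene_length,
    )
    for idx, event in enumerate(scenario.events):
        rng = scenario.event_rng(idx)
        _apply_event(out, event, rng)
    return out


def _require_chrom(genome: SimulatedGenome, chrom: str) -> None:
    if chrom not in genome.chromosomes:
        raise ReferenceError_(f"chromosome {chrom!r} not in genome {genome.genome_id}")


def _apply_event(genome: SimulatedGenome, event: Event, rng: np.random.Generator) -> None:
    chroms = genome.chromosomes

    def _reset_slots(*names: str) -> None:
        # structural events re-grid the affected chromosomes
        for name in names:
            for g in chroms.get(name, []):
                g.slot = None

    if isinstance(event, Fusion):
        _require_chrom(genome, event.chrom_a)
        _require_chrom(genome, event.chrom_b)
        fused = chroms[event.chrom_a] + chroms[event.chrom_b]
        name = f"{event.chrom_a}-{event.chrom_b}"
        new: dict[str, list[SimGene]] = {}
        for c, genes in chroms.items():
            if c == event.chrom_a:
                new[name] = fused
            elif c != event.chrom_b:
                new[c] = genes
        genome.chromosomes = new
        _reset_slots(name)
    elif isinstance(event, Inversion):
        _require_chrom(genome, event.chromosome)
        genes = chroms[event.chromosome]
        if event.start is None:
            span = max(1, int(round(len(genes) * rng.uniform(0.1, 0.3))))
            start = int(rng.integers(0, len(genes) - span + 1))
            end = start + span
        else:
            start, end = event.start, event.end if event.end is not None else len(genes)
        if not (0 <= start < end <= len(genes)):
            raise ValidationError(f"inversion span [{start},{end}) outside chromosome")
        segment = genes[start:end][::-1]
        for g in segment:
            g.strand = "-" if g.strand == "+" else "+"
        chroms[event.chromosome] = genes[:start] + segment + genes[end:]
        _reset_slots(event.chromosome)
    elif isinstance(event, Translocation):
        _require_chrom(genome, event.src_chrom)
        _require_chrom(genome, event.dest_chrom)
        src = chroms[event.src_chrom]
        if not (0 <= event.start < event.end <= len(src)):
            raise ValidationError("translocation span outside source chromosome")
        segment = src[event.start:event.end]
        chroms[event.src_chrom] = src[: event.start] + src[event.end:]
        dest = chroms[event.dest_chrom]
        pos = min(event.dest_pos, len(dest))
        chroms[event.dest_chrom] = dest[:pos] + segment + dest[pos:]
        _reset_slots(event.src_chrom, event.dest_chrom)
    elif isinstance(event, WGD):
        if any(g.subgenome for genes in chroms.values() for g in genes):
            raise ValidationError("genome already polyploid; wgd may appear at most once")
        new = {}
        for c, genes in chroms.items():
            for sub in ("A", "B"):
                new[f"{c}_{sub}"] = [
                    SimGene(g.family, g.strand, g.gb_label, sub, g.slot) for g in genes
                ]
        genome.chromosomes = new
    elif isinstance(event, GeneLoss):
        # deletions leave their grid slot vacant: chromosome span is kept, so
        # gene density genuinely drops where fractionation removed genes
        for c, genes in chroms.items():
            for pos, g in enumerate(genes):
                if g.slot is None:
                    g.slot = pos
            kept = []
            for g in genes:
                hit = event.subgenome is None or g.subgenome == event.subgenome
                if hit and rng.random() < event.rate:
                    continue
                kept.append(g)
            chroms[c] = kept
    elif isinstance(event, ExpressionBias):
        pass  # consumed by simulate_expression
    else:  # pragma: no cover
        raise TypeError(f"unknown event {event!r}")


def standard_scenario(
    fuse: tuple[str, str] = ("ACK6", "ACK8"),
    rearrange: bool = True,
    wgd: bool = False,
    loss_rate: float = 0.0,
    bias: ExpressionBias | None = None,
    seed: int = 0,
) -> EvolutionScenario:
    """Fusion of two ancestral chromosomes, post-fusion rearrangement, and
    optionally whole-genome duplication with per-subgenome gene loss."""
    events: list[Event] = [Fusion(*fuse)]
    if rearrange:
        events.append(Inversion(f"{fuse[0]}-{fuse[1]}"))
    if wgd:
        events.append(WGD())
        if loss_rate:
            events.append(GeneLoss(loss_rate, "A"))
            events.append(GeneLoss(loss_rate, "B"))
    elif loss_rate:
        events.append(GeneLoss(loss_rate))
    if bias is not None:
        events.append(bias)
    return EvolutionScenario(events, seed=seed)


# ---------------------------------------------------------------------------
# homology
# ---------------------------------------------------------------------------

def homology_from_families(
    annot_a: GenomeAnnotation, annot_b: GenomeAnnotation, similarity: float = 95.0
) -> HomologyTable:
    """All cross-genome gene pairs sharing a family label.

    Emulates the homology-search input (the analysis consumes a pair table,
    not raw alignments); similarity is a constant placeholder percentage.
    """
    fams_b: dict[str, list[str]] = {}
    for g in annot_b.genes:
        if g.family:
            fams_b.setdefault(g.family, []).append(g.gene_id)
    rows = [
        {"gene_a": ga.gene_id, "gene_b": gb, "similarity": similarity}
        for ga in annot_a.genes
        if ga.family
        for gb in fams_b.get(ga.family, [])
    ]
    return HomologyTable(pd.DataFrame(rows, columns=["gene_a", "gene_b", "similarity"]))


# ---------------------------------------------------------------------------
# omics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedGene:
    """A gene whose expression is an affine function of a metabolite total."""

    gene_id: str
    compounds: tuple[str, ...]
    slope: float
    intercept: float = 5.0
    noise_sd: float = 0.0


@dataclass
class SimulatedOmics:
    expression: ExpressionMatrix
    metabolites: MetaboliteTable
    cds_pairs: list[CodonAlignment] = field(default_factory=list)
    true_ks: np.ndarray | None = None


def sample_design(
    genotypes: Sequence[str] = ("tetra", "di"),
    tissues: Sequence[str] = ("seed", "silique", "leaf"),
    replicates: int = 3,
) -> pd.DataFrame:
    """Genotype x tissue x replicate sample sheet, indexed by sample id."""
    rows = []
    for g in genotypes:
        for t in tissues:
            for r in range(1, replicates + 1):
                rows.append({"genotype": g, "tissue": t, "replicate": f"rep{r}"})
    df = pd.DataFrame(rows)
    df.index = df["genotype"] + "." + df["tissue"] + "." + df["replicate"]
    return df


def simulate_metabolites(
    design: pd.DataFrame,
    levels: dict[str, tuple[float, float]] | None = None,
    n_decoys: int = 10,
    cv: float = 0.1,
    seed: int = 0,
) -> MetaboliteTable:
    """Compound x sample panel: genotype-dependent target compounds plus decoys.

    ``levels`` maps compound -> (content in first genotype, content in
    second genotype) in mg/kg; replicate noise is lognormal with
    coefficient of variation ``cv``.
    """
    rng = np.random.default_rng(seed)
    levels = dict(levels or DEFAULT_METABOLITE_LEVELS)
    genotypes = list(dict.fromkeys(design["genotype"]))
    if len(genotypes) != 2:
        raise ValidationError("metabolite simulation needs exactly two genotypes")
    sigma = math.sqrt(math.log(1 + cv**2))
    rows = {}
    for comp, (hi, lo) in levels.items():
        base = design["genotype"].map({genotypes[0]: hi, genotypes[1]: lo}).to_numpy(float)
        rows[comp] = base * np.exp(rng.normal(-sigma**2 / 2, sigma, len(design)))
    for i in range(n_decoys):
        base = rng.uniform(0.5, 50.0)
        rows[f"decoy{i:03d}"] = base * np.exp(rng.normal(-sigma**2 / 2, sigma, len(design)))
    values = pd.DataFrame(rows, index=design.index).T
    cls = pd.Series(
        {c: ("flavonoid" if c in levels else "decoy") for c in values.index}
    )
    return MetaboliteTable(values, cls)


def simulate_expression(
    genome: SimulatedGenome,
    design: pd.DataFrame,
    bias: ExpressionBias | None = None,
    planted: Sequence[PlantedGene] = (),
    metabolites: MetaboliteTable | None = None,
    base_log_tpm_mean: float = 3.0,
    base_log_tpm_sd: float = 1.0,
    replicate_cv: float = 0.1,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate a TPM matrix over the genome's genes and the design's samples.

    Homoeolog pairs (same family, subgenomes A and B) share a family-level
    baseline split by a log2 fold-change drawn from ``bias``; replicate
    noise is lognormal. Planted genes are overwritten with
    ``intercept + slope * metabolite_total + N(0, noise_sd)`` (clipped at 0),
    which ties them to their target compounds for the correlation screen.
    """
    if len(design) < 2:
        raise ValidationError("design must name at least 2 samples")
    rng = np.random.default_rng(seed)
    bias = bias or ExpressionBias()
    annot = genome.annotation()
    gene_ids = [g.gene_id for g in annot.genes]
    families: dict[str, float] = {}
    truth = genome.truth().set_index("gene_id")

    base = np.empty(len(gene_ids))
    for i, gid in enumerate(gene_ids):
        fam = truth.loc[gid, "family"]
        if fam not in families:
            families[fam] = float(np.exp(rng.normal(base_log_tpm_mean, base_log_tpm_sd)))
        mu = families[fam]
        sub = truth.loc[gid, "subgenome"]
        if sub is not None and not (isinstance(sub, float) and np.isnan(sub)):
            # one delta per family, applied symmetrically to the two homoeologs
            delta_key = ("delta", fam)
            if delta_key not in families:
                families[delta_key] = float(rng.normal(bias.log2_mean, bias.log2_sd))
            delta = families[delta_key]
            mu *= 2.0 ** (delta / 2 if sub == "A" else -delta / 2)
        base[i] = mu

    sigma = math.sqrt(math.log(1 + replicate_cv**2))
    noise = np.exp(rng.normal(-sigma**2 / 2, sigma, size=(len(gene_ids), len(design))))
    values = pd.DataFrame(base[:, None] * noise, index=gene_ids, columns=design.index)

    for p in planted:
        if p.gene_id not in values.index:
            raise ReferenceError_(f"planted gene {p.gene_id!r} not in genome")
        if metabolites is None:
            raise ValidationError("planted genes require a metabolite table")
        total = metabolites.total(p.compounds).reindex(design.index)
        expr = p.intercept + p.slope * total.to_numpy(float)
        if p.noise_sd > 0:
            expr = expr + rng.normal(0.0, p.noise_sd, len(expr))
        values.loc[p.gene_id] = np.clip(expr, 0.0, None)

    return ExpressionMatrix(values, design.copy())


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"
# consensus-like PSPG box: anchors W/Q/H/S/E at motif positions 1/4/19/24/27
_PSPG_CONSENSUS = "WQHSE"


def simulate_proteins(
    gene_ids: Sequence[str],
    ugt_gene_ids: Sequence[str],
    length: int = 300,
    seed: int = 0,
) -> dict[str, str]:
    """Protein sequences: UGT-like genes carry a C-terminal PSPG box.

    Non-UGT genes get random sequences; UGT genes get a 44-residue window
    (starting 60 residues before the C-terminus) whose five anchor
    positions carry the canonical W/Q/H/S/E residues.
    """
    from .screen import PSPG_ANCHORS, PSPG_LENGTH

    rng = np.random.default_rng(seed)
    ugt = set(ugt_gene_ids)
    missing = ugt - set(gene_ids)
    if missing:
        raise ReferenceError_(f"UGT genes not in gene list: {sorted(missing)}")
    proteins = {}
    for gid in gene_ids:
        seq = list(rng.choice(list(_AA), length))
        if gid in ugt:
            start = length - 60
            for off, aa in PSPG_ANCHORS.items():
                seq[start + off] = aa
            assert start + PSPG_LENGTH <= length
        proteins[gid] = "".join(seq)
    return proteins


# ---------------------------------------------------------------------------
# codon divergence
# ---------------------------------------------------------------------------

# codon families with C at the second position: third position is fully
# synonymous (4-fold degenerate) and first-position changes are always
# nonsynonymous and never create a stop codon, so synonymous and
# nonsynonymous sites separate cleanly.
_MIDDLE_C_FIRST = "TCAG"
_BASES = "TCAG"


def _jc_p(distance: float) -> float:
    """Per-site difference probability of a Jukes-Cantor process at ``distance``."""
    if distance < 0 or not np.isfinite(distance):
        raise ValidationError(f"divergence must be finite and >= 0, got {distance}")
    return 0.75 * (1.0 - math.exp(-4.0 * distance / 3.0))


def simulate_codon_divergence(
    n_pairs: int,
    codons: int,
    true_ks: float,
    seed: int = 0,
    true_ka: float | None = None,
) -> tuple[list[CodonAlignment], np.ndarray]:
    """Gap-free codon-alignment pairs with known synonymous divergence.

    Synonymous (third) positions diverge under a Jukes-Cantor process whose
    corrected distance equals ``true_ks``; nonsynonymous (first) positions
    diverge at ``true_ka`` (default ``true_ks/4``). Returns the alignments
    and the per-pair realized synonymous-difference fractions' implied true
    Ks (constant vector — the generating parameter).
    """
    if codons < 1:
        raise ValidationError("codons must be >= 1")
    true_ka = true_ks / 4.0 if true_ka is None else true_ka
    ps, pn = _jc_p(true_ks), _jc_p(true_ka)
    if ps >= 0.75 or pn >= 0.75:
        raise ValidationError("requested divergence saturates the substitution process")
    rng = np.random.default_rng(seed)
    pairs: list[CodonAlignment] = []
    for k in range(n_pairs):
        first = rng.choice(list(_MIDDLE_C_FIRST), codons)
        third = rng.choice(list(_BASES), codons)
        seq_a = "".join(f + "C" + t for f, t in zip(first, third))
        b_first = _mutate_jc(first, pn, rng)
        b_third = _mutate_jc(third, ps, rng)
        seq_b = "".join(f + "C" + t for f, t in zip(b_first, b_third))
        pairs.append(CodonAlignment(f"pair{k:05d}", seq_a, seq_b))
    return pairs, np.full(n_pairs, true_ks)


def _mutate_jc(bases: np.ndarray, p_diff: float, rng: np.random.Generator) -> np.ndarray:
    out = bases.copy()
    hit = rng.random(len(bases)) < p_diff
    for i in np.flatnonzero(hit):
        choices = [b for b in _BASES if b != bases[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out
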