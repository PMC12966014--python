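"""Projection of ancestral genomic blocks (GBs) onto descendant genomes.

Syntenic fragments linking a descendant genome (genome A of the fragment)
to an ancestor-proxy genome (genome B) whose genes carry GB labels are
turned into *GB projections*: intervals of the descendant genome assigned
an ancestral block label. Copy counts, block-adjacency (association)
conservation and chromosome-level events (intact inheritance vs fusion,
with a rearrangement flag) are derived from the projections.

A block fragmented by an intrachromosomal rearrangement is still one
copy of that block: copy counting therefore groups projections of one
label per descendant chromosome by default (``distinct_chromosomes``),
with raw-projection counting available for tandem-duplication studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .model import GBDefinitionTable, GenomeAnnotation, ValidationError
from .synteny import SyntenicFragment

logger = logging.getLogger(__name__)


@dataclass
class GBProjection:
    block_label: str
    chromosome: str          # descendant chromosome
    rank_start: int
    rank_end: int            # inclusive, descendant ranks
    start: int
    end: int                 # bp, half-open
    n_genes: int
    purity: float            # fraction of host-fragment genes carrying this label
    copy_index: int = 0


@dataclass
class ChromosomeEvent:
    kind: str                       # "intact_inheritance" | "fusion"
    descendant: str
    ancestors: tuple[str, ...]
    rearranged: bool = False


@dataclass
class KaryotypeComparison:
    copy_number: pd.Series
    events: list[ChromosomeEvent]
    unassigned: list[str] = field(default_factory=list)

    @property
    def fusions(self) -> list[ChromosomeEvent]:
        return [e for e in self.events if e.kind == "fusion"]

    @property
    def intact(self) -> list[ChromosomeEvent]:
        return [e for e in self.events if e.kind == "intact_inheritance"]


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_genomic_blocks(
    fragments: list[SyntenicFragment],
    gb_table: GBDefinitionTable,
    annot_desc: GenomeAnnotation,
    min_genes_per_call: int = 5,
    merge_gene_gap: int = 50,
    merge_bp_gap: int = 300_000,
) -> list[GBProjection]:
    """Project GB labels through syntenic fragments onto the descendant.

    Within each fragment, maximal runs of pairs whose ancestral partner
    shares a GB label become candidate projections; runs shorter than
    ``min_genes_per_call`` are dropped; same-label projections left
    adjacent on a descendant chromosome (within the chaining gap) are
    merged. Unlabelled ancestral partners reduce purity but never fail.
    """
    candidates: list[GBProjection] = []
    for frag in fragments:
        labels = [gb_table.label_of(p.gene_b) for p in frag.pairs]
        n_frag = len(frag.pairs)
        label_counts: dict[str, int] = {}
        for lab in labels:
            if lab is not None:
                label_counts[lab] = label_counts.get(lab, 0) + 1
        run_start = 0
        for i in range(1, n_frag + 1):
            if i == n_frag or labels[i] != labels[run_start]:
                lab = labels[run_start]
                run = frag.pairs[run_start:i]
                if lab is not None and len(run) >= min_genes_per_call:
                    genes = [annot_desc[p.gene_a] for p in run]
                    candidates.append(
                        GBProjection(
                            block_label=lab,
                            chromosome=frag.chrom_a,
                            rank_start=min(g.rank for g in genes),
                            rank_end=max(g.rank for g in genes),
                            start=min(g.start for g in genes),
                            end=max(g.end for g in genes),
                            n_genes=len(run),
                            purity=label_counts[lab] / n_frag,
                        )
                    )
                run_start = i
    merged = _merge_adjacent(candidates, merge_gene_gap, merge_bp_gap)
    _assign_copy_indices(merged)
    return merged


def _merge_adjacent(
    projections: list[GBProjection], merge_gene_gap: int, merge_bp_gap: int
) -> list[GBProjection]:
    by_key: dict[tuple[str, str], list[GBProjection]] = {}
    for p in projections:
        by_key.setdefault((p.chromosome, p.block_label), []).append(p)
    out: list[GBProjection] = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda p: p.rank_start)
        current = group[0]
        for nxt in group[1:]:
            gene_gap = nxt.rank_start - current.rank_end - 1
            bp_gap = max(0, nxt.start - current.end)
            if gene_gap < merge_gene_gap or bp_gap <= merge_bp_gap:
                current = GBProjection(
                    current.block_label,
                    current.chromosome,
                    current.rank_start,
                    max(current.rank_end, nxt.rank_end),
                    current.start,
                    max(current.end, nxt.end),
                    current.n_genes + nxt.n_genes,
                    max(current.purity, nxt.purity),
                )
            else:
                out.append(current)
                current = nxt
        out.append(current)
    return sorted(out, key=lambda p: (p.chromosome, p.start))


def _assign_copy_indices(projections: list[GBProjection]) -> None:
    by_label: dict[str, list[GBProjection]] = {}
    for p in projections:
        by_label.setdefault(p.block_label, []).append(p)
    for label, group in by_label.items():
        group.sort(key=lambda p: (p.chromosome, p.start))
        chrom_index: dict[str, int] = {}
        for p in group:
            if p.chromosome not in chrom_index:
                chrom_index[p.chromosome] = len(chrom_index) + 1
            p.copy_index = chrom_index[p.chromosome]


# ---------------------------------------------------------------------------
# copy number & associations
# ---------------------------------------------------------------------------

def gb_copy_number(
    projections: list[GBProjection],
    gb_table: GBDefinitionTable,
    distinct_chromosomes: bool = True,
) -> pd.Series:
    """Copies per block label; labels without projections are reported as 0.

    With ``distinct_chromosomes`` (default) a label's copies are the
    distinct descendant chromosomes carrying it — a block split in place
    by rearrangement counts once. Set False to count raw projections
    (relevant when tandem duplications within one chromosome matter).
    """
    counts = {lab: 0 for lab in gb_table.labels}
    if distinct_chromosomes:
        seen: set[tuple[str, str]] = {(p.block_label, p.chromosome) for p in projections}
        for lab, _ in seen:
            counts[lab] = counts.get(lab, 0) + 1
    else:
        for p in projections:
            counts[p.block_label] = counts.get(p.block_label, 0) + 1
    return pd.Series(counts, name="copies").sort_index()


def extract_gb_associations(projections: list[GBProjection]) -> set[frozenset[str]]:
    """Unordered adjacent distinct-label pairs along each descendant chromosome."""
    assoc: set[frozenset[str]] = set()
    by_chrom: dict[str, list[GBProjection]] = {}
    for p in projections:
        by_chrom.setdefault(p.chromosome, []).append(p)
    for group in by_chrom.values():
        group.sort(key=lambda p: p.start)
        for a, b in zip(group, group[1:]):
            if a.block_label != b.block_label:
                assoc.add(frozenset((a.block_label, b.block_label)))
    return assoc


def association_recovery_fraction(
    detected: set[frozenset[str]], ancestral: set[frozenset[str]]
) -> float:
    """|detected ∩ ancestral| / |ancestral|."""
    if not ancestral:
        raise ValidationError("ancestral association set is empty; fraction undefined")
    return len(detected & ancestral) / len(ancestral)


# ---------------------------------------------------------------------------
# chromosome events
# ---------------------------------------------------------------------------

def infer_chromosome_events(
    projections: list[GBProjection],
    gb_table: GBDefinitionTable,
    min_fraction: float = 0.10,
) -> KaryotypeComparison:
    """Intact inheritances and fusions per descendant chromosome.

    An ancestral chromosome *contributes* to a descendant chromosome when
    its blocks cover at least ``min_fraction`` of the descendant's
    projected span. One contributor means intact inheritance; two or more
    mean a fusion. The rearrangement flag is set when the projected block
    order of any contributor matches neither the ancestral block order
    nor its full reversal.
    """
    if not projections:
        raise ValidationError("no projections to infer events from")
    label_chrom = {lab: chrom for lab, (chrom, _) in gb_table.blocks.items()}
    anc_order = gb_table.chromosome_blocks()
    by_chrom: dict[str, list[GBProjection]] = {}
    for p in projections:
        by_chrom.setdefault(p.chromosome, []).append(p)

    events: list[ChromosomeEvent] = []
    for desc in sorted(by_chrom):
        group = sorted(by_chrom[desc], key=lambda p: p.start)
        span_by_anc: dict[str, int] = {}
        total = 0
        for p in group:
            anc = label_chrom.get(p.block_label)
            if anc is None:
                continue
            length = p.end - p.start
            span_by_anc[anc] = span_by_anc.get(anc, 0) + length
            total += length
        contributors = sorted(
            a for a, bp in span_by_anc.items() if total and bp / total >= min_fraction
        )
        if not contributors:
            continue
        rearranged = any(
            not _order_consistent(
                [p.block_label for p in group if label_chrom.get(p.block_label) == anc],
                anc_order[anc],
            )
            for anc in contributors
        )
        kind = "intact_inheritance" if len(contributors) == 1 else "fusion"
        events.append(ChromosomeEvent(kind, desc, tuple(contributors), rearranged))

    copy_number = gb_copy_number(projections, gb_table)
    return KaryotypeComparison(copy_number, events)


def _order_consistent(observed: list[str], ancestral_order: list[str]) -> bool:
    """Whether observed labels follow the ancestral block order or its reverse."""
    dedup: list[str] = []
    for lab in observed:
        if not dedup or dedup[-1] != lab:
            dedup.append(lab)
    expected = [lab for lab in ancestral_order if lab in set(dedup)]
    return dedup == expected or dedup == expected[::-1]


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def projections_to_frame(projections: list[GBProjection]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in projections])


def events_to_frame(comparison: KaryotypeComparison) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kind": e.kind,
                "descendant": e.descendant,
                "ancestors": "+".join(e.ancestors),
                "rearranged": e.rearranged,
            }
            for e in comparison.events
        ]
    )
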