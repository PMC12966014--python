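"""Syntenic-pair detection and fragment chaining.

A homolog pair is *syntenic* when enough other homolog pairs sit within a
rank window around it in both genomes (collinear flanking support).
Syntenic pairs on one chromosome combination are then chained into
syntenic fragments: two consecutive pairs are consolidated when, in both
genomes, they are separated by fewer than ``max_gene_gap`` intervening
genes or by at most ``max_bp_gap`` of genomic distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenomeAnnotation, HomologyTable, ReferenceError_

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntenicPair:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    support: int
    similarity: float


@dataclass
class SyntenicFragment:
    """A maximal chain of syntenic pairs on one chromosome combination."""

    chrom_a: str
    chrom_b: str
    pairs: list[SyntenicPair]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("fragment needs >= 1 member pair")
        self.pairs = sorted(self.pairs, key=lambda p: p.rank_a)

    @property
    def rank_span_a(self) -> tuple[int, int]:
        return self.pairs[0].rank_a, self.pairs[-1].rank_a

    @property
    def rank_span_b(self) -> tuple[int, int]:
        rb = [p.rank_b for p in self.pairs]
        return min(rb), max(rb)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def orientation(self) -> str:
        """'same'/'inverted' when >= 90% of consecutive steps agree, else 'mixed'."""
        if len(self.pairs) < 2:
            return "same"
        steps = np.diff([p.rank_b for p in self.pairs])
        steps = steps[steps != 0]
        if len(steps) == 0:
            return "same"
        frac_up = float((steps > 0).mean())
        if frac_up >= 0.9:
            return "same"
        if frac_up <= 0.1:
            return "inverted"
        return "mixed"


# ---------------------------------------------------------------------------
# pair detection
# ---------------------------------------------------------------------------

def detect_syntenic_pairs(
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    homology: HomologyTable,
    flank_window: int = 20,
    min_support: int = 2,
) -> list[SyntenicPair]:
    """Homolog pairs with collinear flanking support in both genomes.

    A pair (a, b) is emitted iff at least ``min_support`` *other* homolog
    pairs (a', b') exist with a' within ``flank_window`` ranks of a and b'
    within ``flank_window`` ranks of b, on the same chromosome combination.
    Emitted pairs are deduplicated to the best-supported pair per gene
    (ties: higher similarity, then lexicographic partner id).
    """
    if not len(homology):
        return []
    rec = homology.records
    rows = []
    for gene_a, gene_b, sim in rec[["gene_a", "gene_b", "similarity"]].itertuples(index=False):
        ga, gb = annot_a[gene_a], annot_b[gene_b]
        rows.append((gene_a, gene_b, ga.chromosome, gb.chromosome, ga.rank, gb.rank, sim))
    df = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "chrom_a", "chrom_b", "rank_a", "rank_b", "similarity"]
    )
    out: list[SyntenicPair] = []
    for (ca, cb), grp in df.groupby(["chrom_a", "chrom_b"], sort=True):
        ra = grp["rank_a"].to_numpy()
        rb = grp["rank_b"].to_numpy()
        # support = co-windowed homolog pairs, self excluded
        within = (np.abs(ra[:, None] - ra[None, :]) <= flank_window) & (
            np.abs(rb[:, None] - rb[None, :]) <= flank_window
        )
        np.fill_diagonal(within, False)
        support = within.sum(axis=1)
        keep = support >= min_support
        for (row, sup) in zip(grp[keep].itertuples(index=False), support[keep]):
            out.append(
                SyntenicPair(row.gene_a, row.gene_b, ca, cb, row.rank_a, row.rank_b,
                             int(sup), float(row.similarity))
            )
    return _dedup_best_per_gene(out)


def _dedup_best_per_gene(pairs: list[SyntenicPair]) -> list[SyntenicPair]:
    # each genome-A gene keeps its single best partner; a genome-B gene may
    # partner one gene per genome-A chromosome (polyploids map 2:1 onto the
    # ancestor, with homoeologs on different chromosomes)
    def sort_key(p: SyntenicPair):
        return (-p.support, -p.similarity, p.gene_a, p.gene_b)

    best: list[SyntenicPair] = []
    used_a: set[str] = set()
    used_b: set[tuple[str, str]] = set()
    for p in sorted(pairs, key=sort_key):
        if p.gene_a in used_a or (p.gene_b, p.chrom_a) in used_b:
            continue
        used_a.add(p.gene_a)
        used_b.add((p.gene_b, p.chrom_a))
        best.append(p)
    return sorted(best, key=lambda p: (p.chrom_a, p.rank_a, p.chrom_b, p.rank_b))


# ---------------------------------------------------------------------------
# fragment chaining
# ---------------------------------------------------------------------------

def _gap_ok(
    rank_gap: int, bp_gap: int, max_gene_gap: int, max_bp_gap: int
) -> bool:
    """The consolidation rule: fewer than ``max_gene_gap`` intervening genes
    (strict <) OR within ``max_bp_gap`` genomic distance (inclusive <=)."""
    return rank_gap < max_gene_gap or bp_gap <= max_bp_gap


def mergeable(
    p: SyntenicPair,
    q: SyntenicPair,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    max_gene_gap: int = 50,
    max_bp_gap: int = 300_000,
    require_both_genomes: bool = True,
) -> bool:
    """Whether two syntenic pairs satisfy the consolidation rule.

    Intervening-gene counts are rank differences minus one; bp distance is
    measured between the nearest ends of the two boundary genes. With
    ``require_both_genomes`` the rule must hold in genome A and genome B;
    otherwise in genome A alone.
    """
    if (p.chrom_a, p.chrom_b) != (q.chrom_a, q.chrom_b):
        return False
    ga_p, ga_q = annot_a[p.gene_a], annot_a[q.gene_a]
    gb_p, gb_q = annot_b[p.gene_b], annot_b[q.gene_b]
    gap_genes_a = abs(p.rank_a - q.rank_a) - 1
    gap_genes_b = abs(p.rank_b - q.rank_b) - 1
    gap_bp_a = _interval_gap(ga_p.start, ga_p.end, ga_q.start, ga_q.end)
    gap_bp_b = _interval_gap(gb_p.start, gb_p.end, gb_q.start, gb_q.end)
    ok_a = _gap_ok(gap_genes_a, gap_bp_a, max_gene_gap, max_bp_gap)
    if not require_both_genomes:
        return ok_a
    return ok_a and _gap_ok(gap_genes_b, gap_bp_b, max_gene_gap, max_bp_gap)


def _interval_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Distance between the nearest ends of two intervals (0 when overlapping)."""
    if e1 <= s2:
        return s2 - e1
    if e2 <= s1:
        return s1 - e2
    return 0


def chain_fragments(
    pairs: list[SyntenicPair],
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    max_gene_gap: int = 50,
    max_bp_gap: int = 300_000,
    require_both_genomes: bool = True,
) -> list[SyntenicFragment]:
    """Chain syntenic pairs into maximal fragments per chromosome combination.

    Pairs are sorted by genome-A rank; consecutive pairs are joined when
    :func:`mergeable`; the output partitions the input pairs.
    """
    for p in pairs:
        if p.gene_a not in annot_a or p.gene_b not in annot_b:
            raise ReferenceError_(f"pair ({p.gene_a}, {p.gene_b}) references unknown gene")
    by_combo: dict[tuple[str, str], list[SyntenicPair]] = {}
    for p in pairs:
        by_combo.setdefault((p.chrom_a, p.chrom_b), []).append(p)
    fragments: list[SyntenicFragment] = []
    for (ca, cb) in sorted(by_combo):
        members = sorted(by_combo[(ca, cb)], key=lambda p: p.rank_a)
        current = [members[0]]
        for q in members[1:]:
            if mergeable(current[-1], q, annot_a, annot_b, max_gene_gap, max_bp_gap,
                         require_both_genomes):
                current.append(q)
            else:
                fragments.append(SyntenicFragment(ca, cb, current))
                current = [q]
        fragments.append(SyntenicFragment(ca, cb, current))
    return fragments


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def pairs_to_frame(pairs: list[SyntenicPair]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in pairs])


def fragments_to_frame(fragments: list[SyntenicFragment]) -> pd.DataFrame:
    rows = []
    for i, f in enumerate(fragments):
        rows.append(
            {
                "fragment_id": f"frag{i:05d}",
                "chrom_a": f.chrom_a,
                "chrom_b": f.chrom_b,
                "rank_start_a": f.rank_span_a[0],
                "rank_end_a": f.rank_span_a[1],
                "rank_start_b": f.rank_span_b[0],
                "rank_end_b": f.rank_span_b[1],
                "n_pairs": f.n_pairs,
                "orientation": f.orientation,
            }
        )
    return pd.DataFrame(rows)
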