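"""Subgenome partitioning, gene retention and homoeolog expression dominance.

A tetraploid's chromosomes are paired into homoeologous pairs by
maximum-weight matching on shared syntenic-pair counts (self-synteny of
the tetraploid), then split into subgenome A (higher gene density per
pair) and subgenome B. Retention is the fraction of ancestral genes with
a syntenic copy in a subgenome; expression dominance counts homoeolog
pairs whose TPM ratio exceeds each fold threshold, with a two-sided
binomial sign test for subgenome bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .model import ExpressionMatrix, GenomeAnnotation, ValidationError
from .synteny import SyntenicFragment, SyntenicPair

logger = logging.getLogger(__name__)


@dataclass
class SubgenomePartition:
    assignment: dict[str, str]               # chromosome -> "DsA" | "DsB"
    pairs: list[tuple[str, str]]             # (DsA chromosome, DsB chromosome)
    pair_weights: dict[tuple[str, str], int] = field(default_factory=dict)
    densities: dict[str, float] = field(default_factory=dict)

    def chromosomes(self, subgenome: str) -> list[str]:
        return sorted(c for c, s in self.assignment.items() if s == subgenome)


@dataclass
class RetentionProfile:
    global_fraction: float
    windows: pd.DataFrame  # chromosome, window_start_rank, window_end_rank, fraction


@dataclass
class DominanceCount:
    counts: pd.DataFrame   # threshold, a_dominant, b_dominant, n_pairs, p_value
    skipped: int = 0


# ---------------------------------------------------------------------------
# homoeologous pairing & partition
# ---------------------------------------------------------------------------

def pair_homoeologous_chromosomes(
    self_pairs: list[SyntenicPair], annotation: GenomeAnnotation
) -> tuple[list[tuple[str, str]], dict[tuple[str, str], int]]:
    """Match chromosomes into homoeologous pairs.

    ``self_pairs`` are syntenic pairs computed within the tetraploid
    (genome against itself); edge weight between two chromosomes is the
    number of syntenic pairs linking them. Maximum-weight matching must
    cover every chromosome.
    """
    chroms = annotation.chromosomes
    if len(chroms) % 2:
        raise ValidationError(f"odd chromosome count ({len(chroms)}); cannot pair all")
    weights: dict[tuple[str, str], int] = {}
    for p in self_pairs:
        if p.chrom_a == p.chrom_b:
            continue
        key = tuple(sorted((p.chrom_a, p.chrom_b)))
        weights[key] = weights.get(key, 0) + 1
    graph = nx.Graph()
    graph.add_nodes_from(chroms)
    for (a, b), w in weights.items():
        graph.add_edge(a, b, weight=w)
    matching = nx.max_weight_matching(graph, maxcardinality=True)
    matched = {c for edge in matching for c in edge}
    unmatched = [c for c in chroms if c not in matched]
    if unmatched:
        raise ValidationError(f"chromosomes left unmatched: {unmatched}")
    pairs = sorted(tuple(sorted(edge)) for edge in matching)
    return pairs, weights


def assign_subgenomes_by_density(
    pairs: list[tuple[str, str]],
    annotation: GenomeAnnotation,
    pair_weights: dict[tuple[str, str], int] | None = None,
    cross_links: dict[tuple[str, str], int] | None = None,
) -> SubgenomePartition:
    """Within each homoeologous pair, the denser chromosome joins DsA.

    Equal densities are broken by chromosome name order (warned). When
    ``cross_links`` (synteny weights between chromosomes of *different*
    pairs) connect pairs into linkage groups, each group's assignment is
    harmonized by majority over its per-pair calls (logged on override).
    """
    densities = {c: annotation.gene_density(c) for c in annotation.chromosomes}
    assignment: dict[str, str] = {}
    ordered_pairs: list[tuple[str, str]] = []
    for a, b in pairs:
        if densities[a] == densities[b]:
            logger.warning("equal gene density for %s and %s; name order decides", a, b)
            hi, lo = sorted((a, b))
        elif densities[a] > densities[b]:
            hi, lo = a, b
        else:
            hi, lo = b, a
        assignment[hi] = "DsA"
        assignment[lo] = "DsB"
        ordered_pairs.append((hi, lo))

    if cross_links:
        _harmonize_linkage_groups(ordered_pairs, cross_links, assignment)
        ordered_pairs = [
            (a, b) if assignment[a] == "DsA" else (b, a) for a, b in ordered_pairs
        ]
    return SubgenomePartition(assignment, ordered_pairs, dict(pair_weights or {}), densities)


def _harmonize_linkage_groups(
    pairs: list[tuple[str, str]],
    cross_links: dict[tuple[str, str], int],
    assignment: dict[str, str],
) -> None:
    # linkage groups: pairs connected by cross-pair synteny; within a group,
    # linked chromosomes should sit in the same subgenome — majority wins
    graph = nx.Graph()
    graph.add_nodes_from(range(len(pairs)))
    pair_of = {c: i for i, (a, b) in enumerate(pairs) for c in (a, b)}
    for (x, y), w in cross_links.items():
        if x in pair_of and y in pair_of and pair_of[x] != pair_of[y] and w > 0:
            graph.add_edge(pair_of[x], pair_of[y], chroms=(x, y))
    for component in nx.connected_components(graph):
        if len(component) < 2:
            continue
        # orient each linked pair so linked chromosomes agree; majority vote
        votes = {i: assignment[pairs[i][0]] == "DsA" for i in component}
        for i, j, data in graph.subgraph(component).edges(data=True):
            x, y = data["chroms"]
            if assignment[x] != assignment[y]:
                minority = i if sum(votes.values()) > len(votes) / 2 else j
                a, b = pairs[minority]
                assignment[a], assignment[b] = assignment[b], assignment[a]
                logger.info("linkage-group majority flipped pair (%s, %s)", a, b)


# ---------------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------------

def retention_ratio(
    ancestral: GenomeAnnotation,
    retained_ancestral_genes: set[str],
    window: int = 100,
    step: int = 50,
) -> RetentionProfile:
    """Windowed and global fraction of ancestral genes retained in a subgenome.

    ``retained_ancestral_genes`` are ancestral gene ids with at least one
    syntenic partner in the subgenome under study (derive with
    :func:`retained_genes_from_pairs`).
    """
    if window < 1 or step < 1:
        raise ValidationError("window and step must be >= 1")
    rows = []
    total = retained = 0
    for chrom in ancestral.chromosomes:
        genes = ancestral.chromosome_genes(chrom)
        flags = np.array([g.gene_id in retained_ancestral_genes for g in genes])
        total += len(flags)
        retained += int(flags.sum())
        win = window
        if win > len(flags):
            logger.warning("window %d > %d genes on %s; using whole chromosome",
                           window, len(flags), chrom)
            win = len(flags)
        for start in range(0, max(1, len(flags) - win + 1), step):
            chunk = flags[start:start + win]
            rows.append(
                {
                    "chromosome": chrom,
                    "window_start_rank": start,
                    "window_end_rank": start + len(chunk) - 1,
                    "fraction": float(chunk.mean()),
                }
            )
    if total == 0:
        raise ValidationError("ancestral annotation has no genes")
    return RetentionProfile(retained / total, pd.DataFrame(rows))


def retained_genes_from_pairs(
    pairs: list[SyntenicPair], subgenome_chromosomes: set[str]
) -> set[str]:
    """Ancestral gene ids (genome B of the pairs) with a syntenic partner on
    the given subgenome's chromosomes (genome A of the pairs)."""
    return {p.gene_b for p in pairs if p.chrom_a in subgenome_chromosomes}


# ---------------------------------------------------------------------------
# expression dominance
# ---------------------------------------------------------------------------

def homoeolog_gene_pairs(
    annotation: GenomeAnnotation, partition: SubgenomePartition
) -> list[tuple[str, str]]:
    """(DsA gene, DsB gene) pairs sharing a family label across subgenomes."""
    a_chroms = set(partition.chromosomes("DsA"))
    b_chroms = set(partition.chromosomes("DsB"))
    fams_a: dict[str, str] = {}
    fams_b: dict[str, str] = {}
    for g in annotation.genes:
        if not g.family:
            continue
        if g.chromosome in a_chroms:
            fams_a.setdefault(g.family, g.gene_id)
        elif g.chromosome in b_chroms:
            fams_b.setdefault(g.family, g.gene_id)
    return [(fams_a[f], fams_b[f]) for f in sorted(set(fams_a) & set(fams_b))]


def expression_dominance(
    gene_pairs: list[tuple[str, str]],
    expression: ExpressionMatrix,
    thresholds: range = range(1, 9),
    pseudocount: float = 0.1,
    tissue: str | None = None,
    log2_thresholds: bool = False,
) -> DominanceCount:
    """Count homoeolog pairs dominated by each subgenome at fold thresholds.

    fold = (TPM_A + pseudocount) / (TPM_B + pseudocount) on replicate-mean
    TPM (per ``tissue`` when given). A pair is A-dominant at threshold f
    iff fold > f, B-dominant iff 1/fold > f (with ``log2_thresholds`` the
    comparison is |log2 fold| > f instead). A two-sided binomial sign test
    (null p = 0.5 over dominant pairs) is reported per threshold.
    """
    means = expression.tissue_means(tissue)
    folds = []
    skipped = 0
    for ga, gb in gene_pairs:
        if ga not in means.index or gb not in means.index:
            skipped += 1
            continue
        folds.append((means[ga] + pseudocount) / (means[gb] + pseudocount))
    folds_arr = np.asarray(folds)
    rows = []
    for f in thresholds:
        if log2_thresholds:
            a_dom = int((np.log2(folds_arr) > f).sum())
            b_dom = int((-np.log2(folds_arr) > f).sum())
        else:
            a_dom = int((folds_arr > f).sum())
            b_dom = int((1.0 / folds_arr > f).sum())
        n_dom = a_dom + b_dom
        p = binomtest(a_dom, n_dom, 0.5).pvalue if n_dom else 1.0
        rows.append(
            {"threshold": f, "a_dominant": a_dom, "b_dominant": b_dom,
             "n_pairs": len(folds_arr), "p_value": float(p)}
        )
    return DominanceCount(pd.DataFrame(rows), skipped)
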