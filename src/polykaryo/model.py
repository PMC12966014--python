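"""Core in-memory types shared by every analysis stage.

All genomic coordinates are 0-based half-open. File-format conversions
(GFF3's 1-based closed intervals in particular) happen at the I/O boundary,
never here. Gene *rank* is the ordinal position of a gene along its
chromosome, ordered by start coordinate with ties broken lexicographically
by gene id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd


class ValidationError(ValueError):
    """An input violated a structural invariant (bad range, duplicate id...)."""


class ReferenceError_(KeyError):
    """A record referenced a gene or chromosome that does not exist."""


@dataclass(frozen=True)
class GeneModel:
    """A single gene: location, strand and its ordinal rank on the chromosome."""

    gene_id: str
    chromosome: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "+"
    rank: int = -1
    family: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeAnnotation:
    """A genome's gene models with per-chromosome rank indexing.

    Parameters
    ----------
    genome_id:
        Free-form identifier used in reports.
    genes:
        Gene models; ranks are (re)computed here, so the caller may pass
        rank=-1.
    chromosome_lengths:
        Optional chromosome -> length (bp). Missing chromosomes get a length
        just past their last gene.
    """

    def __init__(
        self,
        genome_id: str,
        genes: Iterable[GeneModel],
        chromosome_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.genome_id = genome_id
        genes = list(genes)
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)
        # assign ranks per chromosome: by start, ties by gene id
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        ranked: dict[str, GeneModel] = {}
        self._chrom_genes: dict[str, list[GeneModel]] = {}
        for chrom in sorted(by_chrom):
            ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
            relabelled = [
                GeneModel(g.gene_id, g.chromosome, g.start, g.end, g.strand, i, g.family)
                for i, g in enumerate(ordered)
            ]
            self._chrom_genes[chrom] = relabelled
            for g in relabelled:
                ranked[g.gene_id] = g
        self._genes = ranked
        lengths = dict(chromosome_lengths or {})
        for chrom, glist in self._chrom_genes.items():
            needed = glist[-1].end if glist else 0
            if chrom not in lengths:
                lengths[chrom] = needed
            elif lengths[chrom] < needed:
                raise ValidationError(
                    f"chromosome {chrom}: length {lengths[chrom]} < last gene end {needed}"
                )
        self.chromosome_lengths = lengths

    # -- access -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise ReferenceError_(f"unknown gene id {gene_id!r}") from None

    @property
    def genes(self) -> list[GeneModel]:
        return [g for chrom in sorted(self._chrom_genes) for g in self._chrom_genes[chrom]]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._chrom_genes)

    def chromosome_genes(self, chromosome: str) -> list[GeneModel]:
        """Genes on one chromosome in rank order."""
        try:
            return list(self._chrom_genes[chromosome])
        except KeyError:
            raise ReferenceError_(f"unknown chromosome {chromosome!r}") from None

    def gene_density(self, chromosome: str) -> float:
        """Genes per Mb on one chromosome."""
        length = self.chromosome_lengths[chromosome]
        if length <= 0:
            return 0.0
        return len(self._chrom_genes[chromosome]) / (length / 1e6)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "chromosome": g.chromosome,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "rank": g.rank,
                    "family": g.family,
                }
                for g in self.genes
            ]
        )


@dataclass
class HomologyTable:
    """Gene-level homology: (gene_a, gene_b, percent similarity)."""

    records: pd.DataFrame  # columns gene_a, gene_b, similarity

    def __post_init__(self) -> None:
        required = {"gene_a", "gene_b", "similarity"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValidationError(f"homology table missing columns: {sorted(missing)}")
        sim = self.records["similarity"]
        if ((sim < 0) | (sim > 100)).any():
            bad = self.records.loc[(sim < 0) | (sim > 100)].index[0]
            raise ValidationError(f"similarity out of [0,100] at row {bad}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GBDefinitionTable:
    """Ancestral genomic-block system: block label -> chromosome + member genes.

    ``blocks`` maps each label (A..X) to its ancestral chromosome and the
    ordered gene ids that define it; the ancestral association list (adjacent
    block pairs along each ancestral chromosome) is derived from block order.
    """

    blocks: dict[str, tuple[str, list[str]]]  # label -> (chromosome, ordered gene ids)

    def __post_init__(self) -> None:
        if len(self.blocks) != len(set(self.blocks)):
            raise ValidationError("duplicate block labels")

    @property
    def labels(self) -> list[str]:
        return list(self.blocks)

    def label_of(self, gene_id: str) -> str | None:
        if not hasattr(self, "_gene2label"):
            self._gene2label = {
                g: lab for lab, (_, genes) in self.blocks.items() for g in genes
            }
        return self._gene2label.get(gene_id)

    def chromosome_blocks(self) -> dict[str, list[str]]:
        """Ordered block labels per ancestral chromosome (insertion order)."""
        out: dict[str, list[str]] = {}
        for lab, (chrom, _) in self.blocks.items():
            out.setdefault(chrom, []).append(lab)
        return out

    def ancestral_associations(self) -> set[frozenset[str]]:
        """Unordered adjacent block pairs along each ancestral chromosome."""
        assoc: set[frozenset[str]] = set()
        for labs in self.chromosome_blocks().values():
            for a, b in zip(labs, labs[1:]):
                if a != b:
                    assoc.add(frozenset((a, b)))
        return assoc


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM table with per-sample metadata.

    ``metadata`` is indexed by sample id with at least the columns
    genotype, tissue, replicate.
    """

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValidationError("negative TPM value in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        if len(self.metadata) and not self.metadata.index.equals(self.values.columns):
            self.metadata = self.metadata.reindex(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def tissue_means(self, tissue: str | None = None) -> pd.Series | pd.DataFrame:
        """Mean TPM per gene, averaged over replicates of one tissue (or all samples)."""
        if tissue is None or "tissue" not in self.metadata.columns:
            return self.values.mean(axis=1)
        cols = self.metadata.index[self.metadata["tissue"] == tissue]
        if not len(cols):
            raise ValidationError(f"no samples for tissue {tissue!r}")
        return self.values[cols].mean(axis=1)


@dataclass
class MetaboliteTable:
    """Compounds x samples content table (mg/kg) with optional class labels."""

    values: pd.DataFrame  # index: compound, columns: sample ids
    compound_class: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValidationError("negative metabolite content")

    def total(self, compounds: Iterable[str]) -> pd.Series:
        """Per-sample summed content of the named compounds."""
        compounds = list(compounds)
        missing = [c for c in compounds if c not in self.values.index]
        if missing:
            raise ReferenceError_(f"unknown compounds: {missing}")
        return self.values.loc[compounds].sum(axis=0)
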