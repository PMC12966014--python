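"""Readers and writers for the standard formats the pipeline touches.

One coordinate convention everywhere: internal intervals are 0-based
half-open. GFF3 (1-based closed) is converted at this boundary; BED is
already half-open and passes through unchanged. Downstream modules never
parse files themselves.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ExpressionMatrix,
    GBDefinitionTable,
    GeneModel,
    GenomeAnnotation,
    HomologyTable,
    MetaboliteTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

_GENE_FEATURES = {"gene", "mRNA"}


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, format: str = "gff3", genome_id: str | None = None) -> GenomeAnnotation:
    """Read gene models from a GFF3 or BED file into a :class:`GenomeAnnotation`.

    GFF3 features that are not typed gene/mRNA are skipped with a logged
    warning; BED files must have at least 4 columns (name required).
    """
    path = Path(path)
    genome_id = genome_id or path.stem
    if format == "gff3":
        genes = _read_gff3(path)
    elif format == "bed":
        genes = _read_bed(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return GenomeAnnotation(genome_id, genes)


def _read_gff3(path: Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="error", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.all_features():
        if feat.featuretype not in _GENE_FEATURES:
            logger.warning("skipping %s feature %s (not gene/mRNA)", feat.featuretype, feat.id)
            continue
        family = feat.attributes.get("family", [None])[0]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chromosome=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based closed
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                family=family,
            )
        )
    return genes


def _read_bed(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValidationError("BED file needs >= 4 columns (chrom,start,end,name)")
    genes = []
    for row in df.itertuples(index=False):
        strand = row[5] if df.shape[1] >= 6 else "+"
        genes.append(GeneModel(str(row[3]), str(row[0]), int(row[1]), int(row[2]), strand))
    return genes


def write_annotation(annot: GenomeAnnotation, path: str | Path, format: str = "gff3") -> None:
    """Write gene models as GFF3 (1-based closed) or BED6 (0-based half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for chrom in annot.chromosomes:
                fh.write(f"##sequence-region {chrom} 1 {annot.chromosome_lengths[chrom]}\n")
            for g in annot.genes:
                attrs = f"ID={g.gene_id}"
                if g.family:
                    attrs += f";family={g.family}"
                fh.write(
                    f"{g.chromosome}\tpolykaryo\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
        elif format == "bed":
            for g in annot.genes:
                fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
        else:
            raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# typed tables
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "homology": ["gene_a", "gene_b", "similarity"],
    "gb": ["block", "chromosome", "gene_id"],
    "expression": None,   # wide: gene_id + one column per sample
    "metabolite": None,   # wide: compound [+ class] + one column per sample
}


def read_table(path: str | Path, schema: str):
    """Read one of the pipeline's TSV inputs into its typed container.

    schema is one of ``homology``, ``gb``, ``expression``, ``metabolite``.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    df = pd.read_csv(path, sep="\t")
    if schema == "homology":
        _require_columns(df, _SCHEMAS["homology"], path)
        df["similarity"] = df["similarity"].astype(float)
        return HomologyTable(df[_SCHEMAS["homology"]])
    if schema == "gb":
        _require_columns(df, _SCHEMAS["gb"], path)
        blocks: dict[str, tuple[str, list[str]]] = {}
        for row in df.itertuples(index=False):
            chrom, genes = blocks.setdefault(str(row.block), (str(row.chromosome), []))
            if chrom != str(row.chromosome):
                raise ValidationError(
                    f"block {row.block} listed on two chromosomes ({chrom}, {row.chromosome})"
                )
            genes.append(str(row.gene_id))
        return GBDefinitionTable(blocks)
    if schema == "expression":
        _require_columns(df, ["gene_id"], path)
        values = df.set_index("gene_id")
        meta = _parse_sample_metadata(values.columns)
        return ExpressionMatrix(values.astype(float), meta)
    # metabolite
    _require_columns(df, ["compound"], path)
    cls = None
    if "class" in df.columns:
        cls = df.set_index("compound")["class"]
        df = df.drop(columns=["class"])
    return MetaboliteTable(df.set_index("compound").astype(float), cls)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def _parse_sample_metadata(sample_ids) -> pd.DataFrame:
    """Recover genotype/tissue/replicate from 'genotype.tissue.repN' sample ids."""
    rows = []
    for sid in sample_ids:
        parts = str(sid).split(".")
        rows.append(
            {
                "genotype": parts[0] if len(parts) > 0 else "",
                "tissue": parts[1] if len(parts) > 1 else "",
                "replicate": parts[2] if len(parts) > 2 else "",
            }
        )
    return pd.DataFrame(rows, index=list(sample_ids))


def write_homology(table: HomologyTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def write_gb_table(gb: GBDefinitionTable, path: str | Path) -> None:
    rows = [
        {"block": lab, "chromosome": chrom, "gene_id": g}
        for lab, (chrom, genes) in gb.blocks.items()
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.rename_axis("gene_id").to_csv(path, sep="\t")


def write_metabolites(table: MetaboliteTable, path: str | Path) -> None:
    df = table.values.copy()
    if table.compound_class is not None:
        df.insert(0, "class", table.compound_class)
    df.rename_axis("compound").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (order preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
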