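"""End-to-end orchestration: simulate → synteny → karyotype → subgenome →
Ks → screen, with a run manifest for reproducibility.

Every stage writes its outputs under the run's output directory with
fixed names; the manifest records the config snapshot, input checksums,
per-stage record counts and wall-clock times, and is written atomically
at the end of the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pk_io
from . import karyotype as kar
from . import ks as ksmod
from . import screen as scr
from . import simulate as sim
from . import subgenome as sub
from . import synteny as syn
from .model import ValidationError

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    outdir: str = "polykaryo_run"
    seed: int = 0
    # simulation
    n_blocks: int = 22
    genes_per_block: int = 50
    spacing_bp: int = sim.DEFAULT_SPACING_BP
    gene_length: int = sim.DEFAULT_GENE_LENGTH
    loss_rate: float = 0.05
    bias_log2_mean: float = 0.0
    bias_log2_sd: float = 0.5
    replicates: int = 3
    tissues: tuple[str, ...] = ("seed", "silique", "leaf")
    n_planted_ugts: int = 3
    planted_slope: float = 0.2
    planted_noise_sd: float = 0.5
    # synteny
    flank_window: int = 20
    min_support: int = 2
    max_gene_gap: int = 50
    max_bp_gap: int = 300_000
    # karyotype
    min_genes_per_call: int = 5
    fusion_min_fraction: float = 0.10
    # subgenome
    retention_window: int = 100
    retention_step: int = 50
    dominance_pseudocount: float = 0.1
    # ks
    ks_pairs: int = 500
    ks_codons: int = 300
    true_ks: float = 0.12
    ks_bandwidth: str | float = "silverman"
    # screen
    r_min: float = 0.75
    p_max: float = 1e-05
    differential_ratio: float = 4.0
    target_compounds: tuple[str, ...] = ("Q3G", "Q7G")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tissues", "target_compounds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    version: str
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
        os.replace(tmp, path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the whole analysis on simulated inputs. Returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(__version__, config.snapshot())

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_

            def __exit__(self_, *exc):
                manifest.stage_seconds[name] = round(time.perf_counter() - self_.t0, 3)
                logger.info("stage %s: done (%.2fs)", name, manifest.stage_seconds[name])

        return _Timer()

    # ---- simulate ---------------------------------------------------------
    with stage("simulate"):
        kary, ancestor = sim.build_ancestral_karyotype(
            config.n_blocks, config.genes_per_block, config.spacing_bp, config.gene_length
        )
        gb_table = kary.gb_table()
        diploid = sim.apply_scenario(
            ancestor, sim.standard_scenario(seed=config.seed), "diploid"
        )
        tetra_scenario = sim.standard_scenario(
            wgd=True, loss_rate=config.loss_rate,
            bias=sim.ExpressionBias(config.bias_log2_mean, config.bias_log2_sd),
            seed=config.seed,
        )
        tetraploid = sim.apply_scenario(ancestor, tetra_scenario, "tetraploid")
        anc_annot, dip_annot, tet_annot = (
            ancestor.annotation(), diploid.annotation(), tetraploid.annotation()
        )
        design = sim.sample_design(("tetra", "di"), config.tissues, config.replicates)
        metabolites = sim.simulate_metabolites(design, seed=config.seed + 1)
        planted_ids = [
            g.gene_id for g in tet_annot.genes[:: max(1, len(tet_annot.genes) // max(config.n_planted_ugts, 1))]
        ][: config.n_planted_ugts]
        planted = [
            sim.PlantedGene(g, config.target_compounds, config.planted_slope,
                            noise_sd=config.planted_noise_sd)
            for g in planted_ids
        ]
        expression = sim.simulate_expression(
            tetraploid, design, tetra_scenario.expression_bias, planted, metabolites,
            seed=config.seed + 2,
        )
        proteins = sim.simulate_proteins(
            [g.gene_id for g in tet_annot.genes], planted_ids, seed=config.seed + 3
        )
        pk_io.write_annotation(anc_annot, out / "ancestor.gff3")
        pk_io.write_annotation(dip_annot, out / "diploid.gff3")
        pk_io.write_annotation(tet_annot, out / "tetraploid.gff3")
        pk_io.write_gb_table(gb_table, out / "gb_definition.tsv")
        pk_io.write_expression(expression, out / "expression.tsv")
        pk_io.write_metabolites(metabolites, out / "metabolites.tsv")
        pk_io.write_fasta(proteins, out / "proteins.faa")
        manifest.stage_counts["simulate"] = {
            "ancestor_genes": len(anc_annot),
            "diploid_genes": len(dip_annot),
            "tetraploid_genes": len(tet_annot),
            "samples": len(design),
        }
        for f in ("ancestor.gff3", "diploid.gff3", "tetraploid.gff3",
                  "gb_definition.tsv", "expression.tsv", "metabolites.tsv", "proteins.faa"):
            manifest.input_checksums[f] = _sha256(out / f)

    # ---- synteny ----------------------------------------------------------
    with stage("synteny"):
        results = {}
        for name, desc_annot in (("diploid", dip_annot), ("tetraploid", tet_annot)):
            hom = sim.homology_from_families(desc_annot, anc_annot)
            pairs = syn.detect_syntenic_pairs(
                desc_annot, anc_annot, hom, config.flank_window, config.min_support
            )
            frags = syn.chain_fragments(
                pairs, desc_annot, anc_annot, config.max_gene_gap, config.max_bp_gap
            )
            results[name] = (pairs, frags)
            syn.pairs_to_frame(pairs).to_csv(out / f"synteny_pairs_{name}.tsv", sep="\t", index=False)
            syn.fragments_to_frame(frags).to_csv(out / f"synteny_fragments_{name}.tsv", sep="\t", index=False)
        manifest.stage_counts["synteny"] = {
            name: {"pairs": len(p), "fragments": len(f)} for name, (p, f) in results.items()
        }

    # ---- karyotype --------------------------------------------------------
    with stage("karyotype"):
        karyo = {}
        for name, desc_annot in (("diploid", dip_annot), ("tetraploid", tet_annot)):
            _, frags = results[name]
            proj = kar.project_genomic_blocks(
                frags, gb_table, desc_annot, config.min_genes_per_call,
                config.max_gene_gap, config.max_bp_gap,
            )
            comparison = kar.infer_chromosome_events(proj, gb_table, config.fusion_min_fraction)
            recovery = kar.association_recovery_fraction(
                kar.extract_gb_associations(proj), gb_table.ancestral_associations()
            )
            karyo[name] = (proj, comparison, recovery)
            kar.projections_to_frame(proj).to_csv(out / f"gb_projections_{name}.tsv", sep="\t", index=False)
            comparison.copy_number.rename_axis("block").to_csv(out / f"gb_copy_number_{name}.tsv", sep="\t")
            kar.events_to_frame(comparison).to_csv(out / f"karyotype_events_{name}.tsv", sep="\t", index=False)
        manifest.stage_counts["karyotype"] = {
            name: {
                "projections": len(p),
                "fusions": len(c.fusions),
                "intact": len(c.intact),
                "association_recovery": round(r, 4),
            }
            for name, (p, c, r) in karyo.items()
        }

    # ---- subgenome --------------------------------------------------------
    with stage("subgenome"):
        self_hom = sim.homology_from_families(tet_annot, tet_annot)
        rec = self_hom.records
        self_hom.records = rec[rec["gene_a"] < rec["gene_b"]].reset_index(drop=True)
        self_pairs = syn.detect_syntenic_pairs(
            tet_annot, tet_annot, self_hom, config.flank_window, config.min_support
        )
        pairing, weights = sub.pair_homoeologous_chromosomes(self_pairs, tet_annot)
        partition = sub.assign_subgenomes_by_density(pairing, tet_annot, weights)
        tet_pairs, _ = results["tetraploid"]
        retention = {}
        for sg in ("DsA", "DsB"):
            retained = sub.retained_genes_from_pairs(tet_pairs, set(partition.chromosomes(sg)))
            profile = sub.retention_ratio(
                anc_annot, retained, config.retention_window, config.retention_step
            )
            retention[sg] = profile
            profile.windows.to_csv(out / f"retention_{sg}.tsv", sep="\t", index=False)
        gene_pairs = sub.homoeolog_gene_pairs(tet_annot, partition)
        dominance = sub.expression_dominance(
            gene_pairs, expression, pseudocount=config.dominance_pseudocount
        )
        dominance.counts.to_csv(out / "dominance.tsv", sep="\t", index=False)
        manifest.stage_counts["subgenome"] = {
            "homoeolog_chromosome_pairs": len(pairing),
            "homoeolog_gene_pairs": len(gene_pairs),
            "retention_DsA": round(retention["DsA"].global_fraction, 4),
            "retention_DsB": round(retention["DsB"].global_fraction, 4),
            "min_dominance_p": float(dominance.counts["p_value"].min()),
        }

    # ---- ks ---------------------------------------------------------------
    with stage("ks"):
        alns, _ = sim.simulate_codon_divergence(
            config.ks_pairs, config.ks_codons, config.true_ks, seed=config.seed + 4
        )
        estimates = ksmod.estimate_many(alns)
        summary = ksmod.ks_distribution_peak(estimates, bandwidth=config.ks_bandwidth)
        est_rows = [e.__dict__ for e in estimates if e is not None]
        pd.DataFrame(est_rows).to_csv(out / "ks_estimates.tsv", sep="\t", index=False)
        with open(out / "ks_summary.json", "w") as fh:
            json.dump(
                {"peak": summary.peak, "secondary_peaks": summary.secondary_peaks,
                 "bandwidth": summary.bandwidth, "n_pairs": summary.n_pairs},
                fh, indent=2,
            )
        manifest.stage_counts["ks"] = {"pairs": summary.n_pairs, "peak": summary.peak}

    # ---- screen -----------------------------------------------------------
    with stage("screen"):
        hits = scr.scan_pspg(proteins)
        hit_genes = [h.protein_id for h in hits]
        total = metabolites.total(config.target_compounds)
        screen_results = scr.correlation_screen(
            expression, total, hit_genes, config.r_min, config.p_max
        )
        passed = [r.gene_id for r in screen_results if r.passed]
        tet_samples = [s for s in design.index if design.loc[s, "genotype"] == "tetra"]
        di_samples = [s for s in design.index if design.loc[s, "genotype"] == "di"]
        folds = scr.metabolite_folds(metabolites, tet_samples, di_samples,
                                     config.differential_ratio)
        scr.hits_to_frame(hits).to_csv(out / "pspg_hits.tsv", sep="\t", index=False)
        scr.screen_to_frame(screen_results).to_csv(out / "correlation_screen.tsv", sep="\t", index=False)
        scr.folds_to_frame(folds).to_csv(out / "metabolite_folds.tsv", sep="\t", index=False)
        manifest.stage_counts["screen"] = {
            "pspg_hits": len(hits),
            "screen_pass": len(passed),
            "planted_recovered": len(set(passed) & set(planted_ids)),
            "differential_compounds": sum(f.differential for f in folds),
        }

    manifest.write(out / "manifest.json")
    return manifest
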