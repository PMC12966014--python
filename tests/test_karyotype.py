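"""Genomic-block projection, copy counting, associations and event inference."""

import pytest

from polykaryo import karyotype as kar
from polykaryo import simulate as sim
from polykaryo import synteny as syn
from polykaryo.karyotype import GBProjection
from polykaryo.model import GBDefinitionTable, ValidationError
from polykaryo.synteny import SyntenicFragment, SyntenicPair

from conftest import grid_annotation


def fragment_with_labels(labels, annot_a, annot_b, prefix_a="a", prefix_b="b"):
    """Fragment whose i-th pair links a{i} -> b{i}; b-genes carry ``labels``."""
    pairs = [
        SyntenicPair(f"{prefix_a}{i:03d}", f"{prefix_b}{i:03d}", "chr1", "chr1", i, i, 1, 95.0)
        for i in range(len(labels))
    ]
    gb = {}
    for i, lab in enumerate(labels):
        if lab is None:
            continue
        chrom, genes = gb.setdefault(lab, ("anc1", []))
        genes.append(f"{prefix_b}{i:03d}")
    return SyntenicFragment("chr1", "chr1", pairs), GBDefinitionTable(gb)


class TestProjectGenomicBlocks:
    def test_pure_fragment_single_projection(self):
        a = grid_annotation("A", 40, "a")
        b = grid_annotation("B", 40, "b")
        frag, gb = fragment_with_labels(["F"] * 40, a, b)
        proj = kar.project_genomic_blocks([frag], gb, a)
        assert len(proj) == 1
        assert proj[0].block_label == "F"
        assert proj[0].purity == 1.0
        assert proj[0].n_genes == 40

    def test_minor_label_dropped_below_threshold(self):
        a = grid_annotation("A", 10, "a")
        b = grid_annotation("B", 10, "b")
        frag, gb = fragment_with_labels(["F"] * 7 + ["G"] * 3, a, b)
        proj = kar.project_genomic_blocks([frag], gb, a, min_genes_per_call=5)
        assert [p.block_label for p in proj] == ["F"]
        assert proj[0].purity == pytest.approx(0.7)

    def test_whole_fragment_below_threshold(self):
        a = grid_annotation("A", 3, "a")
        b = grid_annotation("B", 3, "b")
        frag, gb = fragment_with_labels(["F"] * 3, a, b)
        assert kar.project_genomic_blocks([frag], gb, a, min_genes_per_call=5) == []

    def test_unlabelled_partner_reduces_purity(self):
        a = grid_annotation("A", 10, "a")
        b = grid_annotation("B", 10, "b")
        frag, gb = fragment_with_labels(["F"] * 8 + [None, None], a, b)
        proj = kar.project_genomic_blocks([frag], gb, a)
        assert len(proj) == 1
        assert proj[0].purity == pytest.approx(0.8)

    def test_split_block_merged_within_gap(self):
        # same label in two runs a few unlabelled genes apart -> one projection
        a = grid_annotation("A", 20, "a")
        b = grid_annotation("B", 20, "b")
        frag, gb = fragment_with_labels(["F"] * 8 + [None] * 2 + ["F"] * 8 + [None] * 2, a, b)
        proj = kar.project_genomic_blocks([frag], gb, a)
        assert len(proj) == 1
        assert proj[0].n_genes == 16


def proj(label, chrom, start, end, rank_start=0, rank_end=0, n=10):
    return GBProjection(label, chrom, rank_start, rank_end, start, end, n, 1.0)


class TestCopyNumberAndAssociations:
    def test_copy_number_counts_and_zeros(self):
        gb = GBDefinitionTable({"F": ("c1", []), "G": ("c1", []), "H": ("c2", [])})
        projections = [proj("F", "x1", 0, 100), proj("F", "x2", 0, 100), proj("G", "x1", 200, 300)]
        counts = kar.gb_copy_number(projections, gb)
        assert counts.to_dict() == {"F": 2, "G": 1, "H": 0}

    def test_split_block_on_one_chromosome_is_one_copy(self):
        gb = GBDefinitionTable({"F": ("c1", [])})
        projections = [proj("F", "x1", 0, 100), proj("F", "x1", 900_000, 950_000)]
        assert kar.gb_copy_number(projections, gb)["F"] == 1
        assert kar.gb_copy_number(projections, gb, distinct_chromosomes=False)["F"] == 2

    def test_empty_projections_all_zero(self):
        gb = GBDefinitionTable({"F": ("c1", []), "G": ("c1", [])})
        assert kar.gb_copy_number([], gb).sum() == 0

    def test_associations_ordered_blocks(self):
        projections = [proj("F", "x1", 0, 10), proj("G", "x1", 20, 30), proj("H", "x1", 40, 50)]
        assert kar.extract_gb_associations(projections) == {
            frozenset("FG"), frozenset("GH")
        }

    def test_single_block_no_association(self):
        assert kar.extract_gb_associations([proj("F", "x1", 0, 10)]) == set()

    def test_duplicate_adjacency_deduplicated(self):
        projections = [proj("F", "x1", 0, 10), proj("G", "x1", 20, 30), proj("F", "x1", 40, 50)]
        assert kar.extract_gb_associations(projections) == {frozenset("FG")}


class TestAssociationRecovery:
    def test_identical_sets(self):
        s = {frozenset("AB"), frozenset("BC")}
        assert kar.association_recovery_fraction(s, s) == 1.0

    def test_disjoint_sets(self):
        assert kar.association_recovery_fraction({frozenset("AB")}, {frozenset("CD")}) == 0.0

    def test_fifteen_of_seventeen(self):
        letters = "ABCDEFGHIJKLMNOPQR"
        ancestral = {frozenset(letters[i:i + 2]) for i in range(17)}
        detected = set(sorted(ancestral, key=sorted)[:15])
        assert kar.association_recovery_fraction(detected, ancestral) == pytest.approx(
            0.8824, abs=1e-4
        )

    def test_empty_ancestral_rejected(self):
        with pytest.raises(ValidationError):
            kar.association_recovery_fraction(set(), set())

    def test_invariant_under_chromosome_relabelling(self):
        # associations only mention block labels: renaming chromosomes in the
        # projections changes nothing
        projections = [proj("F", "x1", 0, 10), proj("G", "x1", 20, 30)]
        renamed = [proj(p.block_label, "zz9", p.start, p.end) for p in projections]
        anc = {frozenset("FG"), frozenset("GH")}
        assert kar.association_recovery_fraction(
            kar.extract_gb_associations(projections), anc
        ) == kar.association_recovery_fraction(kar.extract_gb_associations(renamed), anc)


class TestInferChromosomeEvents:
    def run_scenario(self, ancestor, scenario, name="desc"):
        desc = sim.apply_scenario(ancestor, scenario, name)
        aa, da = ancestor.annotation(), desc.annotation()
        hom = sim.homology_from_families(da, aa)
        pairs = syn.detect_syntenic_pairs(da, aa, hom)
        frags = syn.chain_fragments(pairs, da, aa)
        return desc, frags, da

    def test_no_events_all_intact(self, small_ancestor):
        kary, anc = small_ancestor
        gb = kary.gb_table()
        desc, frags, da = self.run_scenario(anc, sim.EvolutionScenario([], seed=0))
        projections = kar.project_genomic_blocks(frags, gb, da)
        comp = kar.infer_chromosome_events(projections, gb)
        assert len(comp.intact) == 8
        assert comp.fusions == []
        assert not any(e.rearranged for e in comp.events)

    def test_fusion_scenario_six_intact_one_fusion(self, small_ancestor, small_diploid):
        kary, _ = small_ancestor
        _, anc = small_ancestor
        gb = kary.gb_table()
        dip, scenario = small_diploid
        aa, da = anc.annotation(), dip.annotation()
        pairs = syn.detect_syntenic_pairs(da, aa, sim.homology_from_families(da, aa))
        frags = syn.chain_fragments(pairs, da, aa)
        projections = kar.project_genomic_blocks(frags, gb, da)
        comp = kar.infer_chromosome_events(projections, gb)
        assert len(comp.intact) == 6
        assert len(comp.fusions) == 1
        assert comp.fusions[0].ancestors == ("ACK6", "ACK8")

    def test_block_crossing_inversion_sets_rearranged_flag(self, small_ancestor):
        kary, anc = small_ancestor
        gb = kary.gb_table()
        # invert across the O|P block boundary on ACK6 (blocks of 10 genes)
        scenario = sim.EvolutionScenario(
            [sim.Fusion("ACK6", "ACK8"), sim.Inversion("ACK6-ACK8", 5, 25)], seed=1
        )
        desc, frags, da = self.run_scenario(anc, scenario)
        projections = kar.project_genomic_blocks(frags, gb, da)
        comp = kar.infer_chromosome_events(projections, gb)
        fusion = comp.fusions[0]
        assert fusion.rearranged

    def test_copy_number_doubles_after_wgd(self, small_ancestor):
        kary, anc = small_ancestor
        gb = kary.gb_table()
        for wgd, expected in ((False, 1), (True, 2)):
            scenario = sim.standard_scenario(wgd=wgd, seed=2)
            desc = sim.apply_scenario(anc, scenario, "d")
            aa, da = anc.annotation(), desc.annotation()
            pairs = syn.detect_syntenic_pairs(da, aa, sim.homology_from_families(da, aa))
            frags = syn.chain_fragments(pairs, da, aa)
            projections = kar.project_genomic_blocks(frags, gb, da)
            counts = kar.gb_copy_number(projections, gb)
            assert (counts == expected).all()
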