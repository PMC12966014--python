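"""NG86 estimator: hand-computed oracles, exhaustive pathway enumeration,
independent-library cross-check, and distribution-peak detection."""

import math
import warnings
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polykaryo import ks as ksm
from polykaryo import simulate as sim
from polykaryo.ks import CodonAlignment, ng86_pairwise
from polykaryo.model import ValidationError

STOPS = {"TAA", "TAG", "TGA"}
BASES = "TCAG"


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def translate(codon):
    from Bio.Seq import Seq

    return "*" if codon in STOPS else str(Seq(codon).translate())


def enum_pathway_diffs(ca, cb):
    """Exhaustive pathway enumerator: walk every substitution order."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    valid, everything = [], []
    for order in permutations(diffs):
        cur, syn, non, blocked = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            blocked = blocked or nxt in STOPS
            if translate(cur) == translate(nxt):
                syn += 1
            else:
                non += 1
            cur = nxt
        everything.append((syn, non))
        if not blocked:
            valid.append((syn, non))
    pool = valid or everything
    return (sum(x for x, _ in pool) / len(pool), sum(y for _, y in pool) / len(pool))


def enum_syn_sites(codon):
    s = 0.0
    for pos in range(3):
        for alt in BASES:
            if alt != codon[pos]:
                mutant = codon[:pos] + alt + codon[pos + 1:]
                if mutant not in STOPS and translate(mutant) == translate(codon):
                    s += 1 / 3
    return s


def naive_ng86(seq_a, seq_b):
    codons_a = [seq_a[i:i + 3] for i in range(0, len(seq_a), 3)]
    codons_b = [seq_b[i:i + 3] for i in range(0, len(seq_b), 3)]
    S = sum((enum_syn_sites(a) + enum_syn_sites(b)) / 2 for a, b in zip(codons_a, codons_b))
    Sd = sum(enum_pathway_diffs(a, b)[0] for a, b in zip(codons_a, codons_b))
    ps = Sd / S
    return S, Sd, -0.75 * math.log(1 - 4 * ps / 3)


def random_stopfree_pair(rng, n=50, p=0.2):
    codons = [c for c in (a + b + c2 for a in BASES for b in BASES for c2 in BASES)
              if c not in STOPS]
    sa, sb = [], []
    for _ in range(n):
        ca = codons[rng.integers(len(codons))]
        cb = list(ca)
        for i in range(3):
            if rng.random() < p:
                cb[i] = BASES[rng.integers(4)]
        cb = "".join(cb)
        sa.append(ca)
        sb.append(cb if cb not in STOPS else ca)
    return "".join(sa), "".join(sb)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class TestNG86:
    def test_identical_sequences(self):
        est = ng86_pairwise(CodonAlignment("id", "ATGGCT", "ATGGCT"))
        assert est.Sd == 0 and est.Nd == 0 and est.ks == 0.0

    def test_hand_computed_synonymous_change(self):
        # 9 glycine codons (1 syn site each) + Phe TTT/TTC (1/3 syn site each):
        # S = 9 + 1/3, Sd = 1, ps = 1/9.3333, Ks = -(3/4)ln(1 - 4ps/3) = 0.115613
        seq_a = "GGT" * 9 + "TTT"
        seq_b = "GGT" * 9 + "TTC"
        est = ng86_pairwise(CodonAlignment("phe", seq_a, seq_b))
        assert est.S == pytest.approx(9 + 1 / 3)
        assert est.Sd == 1.0
        assert est.Nd == 0.0
        assert est.ks == pytest.approx(0.115613, abs=1e-6)

    def test_saturation_error(self):
        # every codon differs by a synonymous third-position change: ps = 1
        est_in = CodonAlignment("sat", "GGA" * 4, "GGC" * 4)
        with pytest.raises(ksm.SaturationError):
            ng86_pairwise(est_in)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            CodonAlignment("bad", "ATGN", "ATGA")  # length not multiple of 3
        with pytest.raises(ValidationError):
            CodonAlignment("bad", "ATGNNN", "ATGAAA")  # ambiguity code
        with pytest.raises(ValidationError):
            CodonAlignment("bad", "ATGTAAGGG", "ATGAAAGGG")  # internal stop

    def test_site_conservation(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            sa, sb = random_stopfree_pair(rng)
            est = ng86_pairwise(CodonAlignment("x", sa, sb))
            assert est.S + est.N == pytest.approx(len(sa))

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            sa, sb = random_stopfree_pair(rng)
            e1 = ng86_pairwise(CodonAlignment("f", sa, sb))
            e2 = ng86_pairwise(CodonAlignment("r", sb, sa))
            assert e1.ks == pytest.approx(e2.ks)
            assert e1.S == pytest.approx(e2.S)

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_exhaustive_enumerator(self, seed):
        """Pathway averaging matches the naive exhaustive enumerator exactly."""
        rng = np.random.default_rng(seed)
        sa, sb = random_stopfree_pair(rng, n=50, p=0.3)
        S, Sd, ks = naive_ng86(sa, sb)
        est = ng86_pairwise(CodonAlignment("o", sa, sb))
        assert est.S == pytest.approx(S)
        assert est.Sd == pytest.approx(Sd)
        assert est.ks == pytest.approx(ks)

    def test_cross_check_against_biopython(self):
        """On alignments whose pathways avoid stop codons the estimate matches
        the independently implemented NG86 in Biopython exactly."""
        from Bio import Align
        from Bio.Align import analysis
        from Bio.Seq import Seq

        pairs, _ = sim.simulate_codon_divergence(10, 80, 0.3, seed=8)
        for p in pairs:
            est = ng86_pairwise(p)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dn, ds = analysis.calculate_dn_ds(
                    Align.Alignment([Seq(p.seq_a), Seq(p.seq_b)]), method="NG86"
                )
            assert est.ks == pytest.approx(ds, abs=1e-9)
            assert est.ka == pytest.approx(dn, abs=1e-9)

    def test_consistency_with_sequence_length(self):
        """Mean estimate approaches the true divergence as codon count grows."""
        errs = []
        for codons in (20, 1000):
            pairs, _ = sim.simulate_codon_divergence(300, codons, 0.12, seed=13)
            ests = [e.ks for e in ksm.estimate_many(pairs) if e is not None]
            errs.append(abs(np.mean(ests) - 0.12))
        # short alignments carry the convexity bias of the multiple-hit
        # correction; long alignments estimate the true rate closely
        assert errs[1] < errs[0]
        assert errs[1] < 0.005


_NONSTOP = [c for c in (a + b + c2 for a in BASES for b in BASES for c2 in BASES)
            if c not in STOPS]
codon_pairs = st.lists(
    st.tuples(st.sampled_from(_NONSTOP), st.sampled_from(_NONSTOP)),
    min_size=2, max_size=30,
)


class TestNG86Properties:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(codon_pairs)
    def test_sites_partition_sequence_length(self, pairs):
        sa = "".join(a for a, _ in pairs)
        sb = "".join(b for _, b in pairs)
        try:
            est = ng86_pairwise(CodonAlignment("h", sa, sb))
        except ksm.SaturationError:
            return  # heavily diverged draws are legitimately saturated
        assert est.S + est.N == pytest.approx(len(sa))
        assert est.Sd >= 0 and est.Nd >= 0
        assert est.Sd + est.Nd == pytest.approx(
            sum(a != b for ca, cb in pairs for a, b in zip(ca, cb))
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(codon_pairs)
    def test_direction_symmetry(self, pairs):
        sa = "".join(a for a, _ in pairs)
        sb = "".join(b for _, b in pairs)
        try:
            fwd = ng86_pairwise(CodonAlignment("f", sa, sb))
            rev = ng86_pairwise(CodonAlignment("r", sb, sa))
        except ksm.SaturationError:
            return
        assert fwd.ks == pytest.approx(rev.ks)
        assert fwd.ka == pytest.approx(rev.ka)


# ---------------------------------------------------------------------------
# distribution peak
# ---------------------------------------------------------------------------

class TestKsDistributionPeak:
    def test_degenerate_point_mass(self):
        summary = ksm.ks_distribution_peak([0.5] * 20)
        assert summary.peak == pytest.approx(0.5)

    def test_insufficient_data(self):
        with pytest.raises(ksm.InsufficientDataError):
            ksm.ks_distribution_peak([0.1] * 9)

    def test_bimodal_two_peaks(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([
            rng.normal(0.1, 0.02, 500).clip(0), rng.normal(1.0, 0.1, 500)
        ])
        summary = ksm.ks_distribution_peak(list(values))
        peaks = sorted([summary.peak] + summary.secondary_peaks)
        assert any(abs(p - 0.1) < 0.05 for p in peaks)
        assert any(abs(p - 1.0) < 0.1 for p in peaks)

    def test_filter_removes_saturated(self):
        values = [0.2] * 30 + [5.0] * 100  # beyond the Ks <= 3 filter
        summary = ksm.ks_distribution_peak(values)
        assert summary.n_pairs == 30
        assert summary.peak == pytest.approx(0.2, abs=0.01)
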