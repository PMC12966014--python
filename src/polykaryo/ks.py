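"""Synonymous-rate (Ks) estimation and Ks-distribution peak detection.

Implements the Nei–Gojobori (1986) codon-counting estimator: synonymous
and nonsynonymous site counts per codon (each of the three possible
changes at each position classified by the standard genetic code),
averaged over the two sequences; observed differences resolved by
averaging over all equally weighted mutational pathways between the two
codons, with pathways passing through stop codons excluded; and the
Jukes–Cantor multiple-hit correction

    Ks = -(3/4) * ln(1 - (4/3) * ps),   ps = Sd / S.

Whole-genome duplications appear as peaks in the Ks distribution of
paralog pairs; peak detection is a Gaussian kernel density estimate over
a fixed grid with the argmax reported as the major peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .model import ValidationError

_BASES = "TCAG"
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CODON_TABLE.stop_codons)


class SaturationError(ValueError):
    """ps >= 3/4: the Jukes-Cantor correction is undefined."""


class InsufficientDataError(ValueError):
    pass


def _translate(codon: str) -> str:
    return "*" if codon in _STOPS else _CODON_TABLE.forward_table[codon]


def _codon_index(codon: str) -> int:
    return _BASES.index(codon[0]) * 16 + _BASES.index(codon[1]) * 4 + _BASES.index(codon[2])


_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]


def _build_site_table() -> np.ndarray:
    """Synonymous-site count per codon (NaN for stops).

    Each position contributes (synonymous changes)/3; changes producing a
    stop codon count as nonsynonymous.
    """
    table = np.full(64, np.nan)
    for codon in _ALL_CODONS:
        if codon in _STOPS:
            continue
        aa = _translate(codon)
        s = 0.0
        for pos in range(3):
            for alt in _BASES:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1:]
                if mutant not in _STOPS and _translate(mutant) == aa:
                    s += 1.0 / 3.0
        table[_codon_index(codon)] = s
    return table


def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair by equal-weight pathway averaging.

    Pathways that pass through a stop codon are excluded; if every pathway
    is excluded the average is taken over all of them instead.
    """
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    fallback = []
    for order in permutations(positions):
        syn = nonsyn = 0.0
        current = codon_a
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in _STOPS:
                blocked = True
            if _translate_or_star(current) == _translate_or_star(nxt):
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        fallback.append((syn, nonsyn))
        if not blocked:
            results.append((syn, nonsyn))
    pool = results if results else fallback
    sd = sum(r[0] for r in pool) / len(pool)
    nd = sum(r[1] for r in pool) / len(pool)
    return sd, nd


def _translate_or_star(codon: str) -> str:
    return "*" if codon in _STOPS else _translate(codon)


def _build_diff_tables() -> tuple[np.ndarray, np.ndarray]:
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i, ca in enumerate(_ALL_CODONS):
        if ca in _STOPS:
            continue
        for j, cb in enumerate(_ALL_CODONS):
            if cb in _STOPS or j < i:
                continue
            s, n = _pathway_diffs(ca, cb)
            sd[i, j] = sd[j, i] = s
            nd[i, j] = nd[j, i] = n
    return sd, nd


_SYN_SITES = _build_site_table()
_SD_TABLE, _ND_TABLE = _build_diff_tables()


# ---------------------------------------------------------------------------
# public types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonAlignment:
    """A gap-free pairwise codon alignment (equal length, multiple of 3)."""

    pair_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValidationError(f"{self.pair_id}: unequal sequence lengths")
        if len(a) == 0 or len(a) % 3:
            raise ValidationError(f"{self.pair_id}: length must be a positive multiple of 3")
        for seq, name in ((a, "seq_a"), (b, "seq_b")):
            if set(seq) - set("ACGT"):
                raise ValidationError(f"{self.pair_id}: {name} has non-ACGT characters")
            for k in range(0, len(seq), 3):
                if seq[k:k + 3] in _STOPS:
                    raise ValidationError(f"{self.pair_id}: internal stop codon in {name}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return _encode(self.seq_a), _encode(self.seq_b)


def _encode(seq: str) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    return arr[0::3] * 16 + arr[1::3] * 4 + arr[2::3]


@dataclass(frozen=True)
class KsEstimate:
    pair_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ks: float
    ka: float


@dataclass
class KsDistributionSummary:
    grid: np.ndarray
    density: np.ndarray
    peak: float
    secondary_peaks: list[float]
    bandwidth: float
    n_pairs: int
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion of differences {p:.4f} >= 3/4")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pairwise(aln: CodonAlignment) -> KsEstimate:
    """Nei–Gojobori Ka/Ks for one codon alignment.

    Raises :class:`SaturationError` when synonymous or nonsynonymous
    differences exceed the Jukes–Cantor correction domain.
    """
    ia, ib = aln.codon_indices()
    s_sites = 0.5 * (_SYN_SITES[ia] + _SYN_SITES[ib])
    if np.isnan(s_sites).any():  # pragma: no cover - stops rejected at construction
        raise ValidationError(f"{aln.pair_id}: stop codon in alignment")
    S = float(s_sites.sum())
    N = 3.0 * aln.n_codons - S
    Sd = float(_SD_TABLE[ia, ib].sum())
    Nd = float(_ND_TABLE[ia, ib].sum())
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return KsEstimate(aln.pair_id, S, N, Sd, Nd, ps, pn, _jc_correct(ps), _jc_correct(pn))


def estimate_many(alignments: Iterable[CodonAlignment]) -> list[KsEstimate | None]:
    """NG86 over many pairs; saturated pairs yield None instead of raising."""
    out: list[KsEstimate | None] = []
    for aln in alignments:
        try:
            out.append(ng86_pairwise(aln))
        except SaturationError:
            out.append(None)
    return out


# ---------------------------------------------------------------------------
# distribution
# ---------------------------------------------------------------------------

def ks_distribution_peak(
    estimates: Sequence[KsEstimate | float | None],
    grid_max: float = 3.0,
    grid_step: float = 0.005,
    bandwidth: str | float = "silverman",
    ks_max_filter: float = 3.0,
) -> KsDistributionSummary:
    """Gaussian-KDE peak(s) of a Ks distribution on a fixed grid.

    Estimates above ``ks_max_filter`` (saturation regime) are discarded.
    Secondary peaks are reported when separated from a larger peak by at
    least 0.1 Ks and reaching at least 10% of the maximum density.
    """
    values = np.array(
        [e.ks if isinstance(e, KsEstimate) else e for e in estimates if e is not None],
        dtype=float,
    )
    values = values[np.isfinite(values) & (values >= 0) & (values <= ks_max_filter)]
    if len(values) < 10:
        raise InsufficientDataError(f"only {len(values)} usable Ks estimates (need >= 10)")
    grid = np.arange(0.0, grid_max + grid_step / 2, grid_step)
    std = values.std(ddof=1)
    if std == 0.0:
        # degenerate: all mass at one value; peak is that value snapped to grid
        peak = grid[np.argmin(np.abs(grid - values[0]))]
        density = np.zeros_like(grid)
        density[np.argmin(np.abs(grid - values[0]))] = 1.0 / grid_step
        return KsDistributionSummary(grid, density, float(peak), [], 0.0, len(values))
    if bandwidth == "silverman":
        kde = gaussian_kde(values, bw_method="silverman")
    else:
        kde = gaussian_kde(values, bw_method=float(bandwidth) / std)
    density = kde(grid)
    h = kde.factor * std
    peak_idx = int(np.argmax(density))
    min_sep = max(1, int(round(0.1 / grid_step)))
    cand, _ = find_peaks(density, height=0.1 * density[peak_idx], distance=min_sep)
    secondary = [float(grid[i]) for i in cand if i != peak_idx]
    return KsDistributionSummary(
        grid, density, float(grid[peak_idx]), secondary, float(h), len(values)
    )
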