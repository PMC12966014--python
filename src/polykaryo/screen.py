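"""UGT candidate screening and metabolite fold-change statistics.

Family-1 UDP-glycosyltransferases (UGTs) carry the ~44-residue PSPG box
near the C-terminus; residues at motif positions 1 (W), 4 (Q), 19 (H),
24 (S) and 27 (E) are critical for activity and serve as scan anchors.
Candidates are then ranked by the Pearson correlation between their
expression and the total content of the target quercetin glucosides,
with the p-value from the exact t-transform
t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionMatrix, MetaboliteTable, ValidationError

logger = logging.getLogger(__name__)

PSPG_LENGTH = 44
# 0-based offsets within the motif window -> required residue
PSPG_ANCHORS = {0: "W", 3: "Q", 18: "H", 23: "S", 26: "E"}


@dataclass(frozen=True)
class PSPGMotifHit:
    protein_id: str
    start: int               # 0-based offset of the motif window
    window: str
    anchor_matches: int
    anchor_score: float      # matched anchors / 5


@dataclass(frozen=True)
class CorrelationScreenResult:
    gene_id: str
    r: float
    p_value: float
    n: int
    passed: bool


@dataclass(frozen=True)
class FoldChangeRecord:
    compound: str
    mean_group1: float
    mean_group2: float
    fold: float
    rounded_fold: int
    differential: bool


# ---------------------------------------------------------------------------
# PSPG motif scan
# ---------------------------------------------------------------------------

def scan_pspg(
    proteins: dict[str, str], min_anchor_matches: int = 4
) -> list[PSPGMotifHit]:
    """Anchored PSPG-motif scan over protein sequences.

    Every 44-residue window with at least ``min_anchor_matches`` of the
    five anchor residues is a hit; overlapping hits within a protein are
    collapsed to the best-scoring one (ties: leftmost). Sequences shorter
    than the motif yield no hit.
    """
    hits: list[PSPGMotifHit] = []
    for pid, seq in proteins.items():
        seq = seq.upper().rstrip("*")
        if len(seq) < PSPG_LENGTH:
            logger.warning("protein %s shorter than %d aa; skipped", pid, PSPG_LENGTH)
            continue
        raw: list[PSPGMotifHit] = []
        for start in range(len(seq) - PSPG_LENGTH + 1):
            window = seq[start:start + PSPG_LENGTH]
            matches = sum(window[off] == aa for off, aa in PSPG_ANCHORS.items())
            if matches >= min_anchor_matches:
                raw.append(PSPGMotifHit(pid, start, window, matches, matches / 5.0))
        hits.extend(_collapse_overlaps(raw))
    return hits


def _collapse_overlaps(raw: list[PSPGMotifHit]) -> list[PSPGMotifHit]:
    out: list[PSPGMotifHit] = []
    cluster: list[PSPGMotifHit] = []
    for hit in raw:  # raw is in start order
        if cluster and hit.start >= cluster[-1].start + PSPG_LENGTH:
            out.append(max(cluster, key=lambda h: (h.anchor_matches, -h.start)))
            cluster = []
        cluster.append(hit)
    if cluster:
        out.append(max(cluster, key=lambda h: (h.anchor_matches, -h.start)))
    return out


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

def correlation_screen(
    expression: ExpressionMatrix,
    metabolite_total: pd.Series,
    candidates: Iterable[str],
    r_min: float = 0.75,
    p_max: float = 1e-05,
) -> list[CorrelationScreenResult]:
    """Pearson screen of candidate genes against a per-sample metabolite total.

    Samples are aligned by id between the expression matrix and the
    metabolite total; candidates pass when r > ``r_min`` and the two-sided
    p-value < ``p_max``. Constant expression vectors give r = NaN and
    never pass.
    """
    missing = set(expression.samples) ^ set(metabolite_total.index)
    if missing:
        raise ValidationError(f"sample ids differ between expression and metabolites: {sorted(missing)}")
    y = metabolite_total.reindex(expression.samples).to_numpy(float)
    n = len(y)
    if n < 3:
        raise ValidationError(f"need >= 3 samples for the correlation screen, got {n}")
    results = []
    for gene in candidates:
        if gene not in expression.values.index:
            raise ValidationError(f"candidate gene {gene!r} not in expression matrix")
        x = expression.values.loc[gene].to_numpy(float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            results.append(CorrelationScreenResult(gene, float("nan"), float("nan"), n, False))
            continue
        r, p = stats.pearsonr(x, y)
        results.append(
            CorrelationScreenResult(gene, float(r), float(p), n, bool(r > r_min and p < p_max))
        )
    return results


# ---------------------------------------------------------------------------
# metabolite folds
# ---------------------------------------------------------------------------

def metabolite_folds(
    table: MetaboliteTable,
    group1: Sequence[str],
    group2: Sequence[str],
    differential_ratio: float = 4.0,
) -> list[FoldChangeRecord]:
    """Per-compound fold change between two sample groups.

    fold = mean(group1) / mean(group2); the rounded fold is the nearest
    integer (half away from zero); a compound is *differential* when the
    fold exceeds ``differential_ratio`` in either direction (the
    'less-than-one-fourth' rule at the default ratio of 4). A zero
    denominator yields an infinite-fold record flagged differential.
    """
    if not len(group1) or not len(group2):
        raise ValidationError("both groups need at least one sample")
    records = []
    for compound in table.values.index:
        m1 = float(table.values.loc[compound, list(group1)].mean())
        m2 = float(table.values.loc[compound, list(group2)].mean())
        if m2 == 0.0:
            fold = math.inf if m1 > 0 else 1.0
        else:
            fold = m1 / m2
        rounded = int(math.floor(fold + 0.5)) if math.isfinite(fold) else -1
        differential = fold > differential_ratio or (
            fold > 0 and fold < 1.0 / differential_ratio
        )
        records.append(FoldChangeRecord(compound, m1, m2, fold, rounded, differential))
    return records


def folds_to_frame(records: list[FoldChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def screen_to_frame(results: list[CorrelationScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def hits_to_frame(hits: list[PSPGMotifHit]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits])
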