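"""Gene-level copy-number states and between-group frequency tests.

Purity/ploidy-adjusted segment ratios are aggregated to genes by
overlap-length-weighted mean, standardized within each sample by dividing
by the standard deviation of the sample's gene ratios (no centering:
ploidy adjustment already places neutral at 0), and discretized with the
study-specific z thresholds:

    amplification  z >  2.0
    gain           1.0 < z <= 2.0
    neutral       -1.5 <= z <= 1.0
    loss          -2.5 <= z < -1.5
    deletion       z < -2.5

Per-gene event frequencies between sample groups are compared with a
two-sided two-proportion test (chi-squared with continuity correction,
falling back to Fisher's exact test when expected counts are small), and
genes are selected by the volcano rule |delta| >= 0.20 and -log10 p >= 1.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import stats

from .core import GeneModel, SegmentProfile

logger = logging.getLogger(__name__)

__all__ = [
    "CNState",
    "CnaComparisonRow",
    "gene_level_ratios",
    "standardize",
    "call_states",
    "compare_cna_frequency",
    "two_proportion_test",
]

DELTA_SELECT = 0.20
NEGLOG10P_SELECT = 1.5


class CNState(IntEnum):
    """Discrete copy-number states, ordered from deletion to amplification."""

    DELETION = 0
    LOSS = 1
    NEUTRAL = 2
    GAIN = 3
    AMPLIFICATION = 4

    @property
    def label(self) -> str:
        return self.name.lower()


def gene_level_ratios(profile: SegmentProfile, genes: GeneModel) -> dict[str, float]:
    """Overlap-length-weighted mean adjusted ratio per gene.

    Genes with no overlapping segment are absent from the result.
    """
    segs_by_chrom: dict[str, list] = {}
    for seg in profile.segments:
        segs_by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in segs_by_chrom.values():
        segs.sort(key=lambda s: s.start)

    out: dict[str, float] = {}
    for gene in genes:
        total_overlap = 0
        weighted = 0.0
        for seg in segs_by_chrom.get(gene.chrom, []):
            overlap = min(gene.end, seg.end) - max(gene.start, seg.start) + 1
            if overlap > 0:
                total_overlap += overlap
                weighted += overlap * seg.log2_ratio
        if total_overlap > 0:
            out[gene.symbol] = weighted / total_overlap
    return out


def standardize(gene_ratios: dict[str, float]) -> dict[str, float]:
    """Within-sample standardization: z = r / SD(r), SD with n-1 denominator.

    No centering is applied.  A zero SD (all ratios identical at 0) yields
    all-zero z with a warning.
    """
    if len(gene_ratios) < 2:
        raise ValueError("standardization needs at least 2 gene ratios")
    values = np.array(list(gene_ratios.values()), dtype=float)
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        logger.warning("zero SD across gene ratios; all z set to 0")
        return {g: 0.0 for g in gene_ratios}
    return {g: r / sd for g, r in gene_ratios.items()}


def call_states(z: float) -> CNState:
    """Discretize a standardized ratio into a copy-number state."""
    if not math.isfinite(z):
        raise ValueError(f"non-finite z score: {z}")
    if z > 2.0:
        return CNState.AMPLIFICATION
    if z > 1.0:
        return CNState.GAIN
    if z >= -1.5:
        return CNState.NEUTRAL
    if z >= -2.5:
        return CNState.LOSS
    return CNState.DELETION


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided test of equal proportions on a 2x2 table.

    Chi-squared with continuity correction (the R ``prop.test`` default);
    Fisher's exact test when any expected count is below 5.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    if total == 0 or 0 in col:
        return 1.0
    expected = np.outer(row, col) / total
    if expected.min() < 5:
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    return float(stats.chi2_contingency(table, correction=True)[1])


@dataclass(frozen=True)
class CnaComparisonRow:
    gene: str
    freq_a: float
    freq_b: float
    delta: float
    p_value: float
    selected: bool


def compare_cna_frequency(
    states_a: dict[str, dict[str, CNState]],
    states_b: dict[str, dict[str, CNState]],
    event: str,
) -> list[CnaComparisonRow]:
    """Per-gene comparison of CNA event frequency between two sample groups.

    ``states_*`` map sample_id -> gene -> state; ``event`` is ``gain-or-amp``
    or ``loss-or-del``.  Genes missing from either group are excluded with a
    log message.
    """
    if event == "gain-or-amp":
        hit = {CNState.GAIN, CNState.AMPLIFICATION}
    elif event == "loss-or-del":
        hit = {CNState.LOSS, CNState.DELETION}
    else:
        raise ValueError(f"unknown event {event!r}")
    if not states_a or not states_b:
        raise ValueError("both groups must be nonempty")

    genes_a = set.intersection(*(set(g) for g in states_a.values()))
    genes_b = set.intersection(*(set(g) for g in states_b.values()))
    common = genes_a & genes_b
    dropped = (genes_a | genes_b) - common
    if dropped:
        logger.info("excluding %d genes missing from one group", len(dropped))

    n_a, n_b = len(states_a), len(states_b)
    rows = []
    for gene in sorted(common):
        k_a = sum(states[gene] in hit for states in states_a.values())
        k_b = sum(states[gene] in hit for states in states_b.values())
        freq_a, freq_b = k_a / n_a, k_b / n_b
        delta = freq_a - freq_b
        p = two_proportion_test(k_a, n_a, k_b, n_b)
        selected = abs(delta) >= DELTA_SELECT and -math.log10(max(p, 1e-300)) >= NEGLOG10P_SELECT
        rows.append(CnaComparisonRow(gene, freq_a, freq_b, delta, p, selected))
    return rows
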