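"""Tumour purity/ploidy consensus and purity-aware segment adjustment.

Model-based purity and ploidy estimates are accepted unless one of three
curation triggers fires: (a) a cfDNA sample whose model estimate disagrees
with the orthogonal ulpWGS estimate by more than 0.15, (b) a model ploidy
outside [1.5, 3.5], or (c) a tissue sample with model purity <= 0.35.  When
curation fires, purity is re-derived from the median somatic VAF under the
clonal-heterozygous-diploid inversion (p = 2 * median VAF, clamped to 1),
standing in for the study's manual review, and ploidy falls back to 2
unless the model ploidy was itself in range.

Segment log2 ratios are then converted to tumour copy number with the
standard two-population mixture inversion

    n = (2^r * (p*psi + 2*(1-p)) - 2*(1-p)) / p

and re-expressed as an adjusted ratio log2(n/2), so neutral diploid tumour
sits at 0 regardless of purity and ploidy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .core import Segment, SegmentProfile

logger = logging.getLogger(__name__)

__all__ = [
    "CurationFlag",
    "PurityCall",
    "consensus_purity",
    "estimate_purity_from_vaf",
    "adjust_segments",
    "ADJUST_EPSILON",
]

#: floor on inferred copy number before taking log2, avoiding -inf for
#: homozygous deletions
ADJUST_EPSILON = 0.01

PLOIDY_RANGE = (1.5, 3.5)
ULPWGS_MAX_DIFF = 0.15
TISSUE_MIN_PURITY = 0.35
MIN_CURATED_PURITY = 0.01


class CurationFlag(str, Enum):
    ULPWGS_DISCORDANT = "ulpwgs_discordant"
    PLOIDY_OUT_OF_RANGE = "ploidy_out_of_range"
    LOW_TISSUE_PURITY = "low_tissue_purity"
    NO_SOMATIC_VAF = "no_somatic_vaf"


@dataclass(frozen=True)
class PurityCall:
    purity: float
    ploidy: float
    source: str  # "model_estimate" | "curated"
    flags: frozenset[CurationFlag] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity {self.purity} outside (0, 1]")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy {self.ploidy} must be positive")
        if (self.source == "curated") != bool(self.flags):
            raise ValueError("source is curated iff flags are nonempty")


def estimate_purity_from_vaf(median_vaf: float) -> float:
    """Purity implied by the median somatic VAF of a sample.

    For clonal heterozygous variants in a diploid genome, VAF = p/2; the
    inversion is 2 * median VAF, clamped at 1.
    """
    if not (0.0 <= median_vaf <= 1.0):
        raise ValueError(f"median VAF {median_vaf} outside [0, 1]")
    return min(1.0, 2.0 * median_vaf)


def consensus_purity(
    model_purity: float,
    model_ploidy: float,
    ulpwgs_purity: Optional[float],
    sample_type: str,
    median_vaf: float,
) -> PurityCall:
    """Resolve consensus purity/ploidy for one sample.

    ``sample_type`` is ``"cfDNA"`` or ``"tissue"``.  A cfDNA sample with no
    ulpWGS estimate skips the discordance trigger (logged).
    """
    if sample_type not in ("cfDNA", "tissue"):
        raise ValueError(f"sample_type must be cfDNA or tissue, got {sample_type!r}")
    flags: set[CurationFlag] = set()
    if sample_type == "cfDNA":
        if ulpwgs_purity is None:
            logger.warning("cfDNA sample without ulpWGS estimate; discordance check skipped")
        elif abs(model_purity - ulpwgs_purity) > ULPWGS_MAX_DIFF:
            flags.add(CurationFlag.ULPWGS_DISCORDANT)
    if model_ploidy > PLOIDY_RANGE[1] or model_ploidy < PLOIDY_RANGE[0]:
        flags.add(CurationFlag.PLOIDY_OUT_OF_RANGE)
    if sample_type == "tissue" and model_purity <= TISSUE_MIN_PURITY:
        flags.add(CurationFlag.LOW_TISSUE_PURITY)

    if not flags:
        return PurityCall(model_purity, model_ploidy, "model_estimate")

    purity = estimate_purity_from_vaf(median_vaf)
    if purity < MIN_CURATED_PURITY:
        flags.add(CurationFlag.NO_SOMATIC_VAF)
        purity = MIN_CURATED_PURITY
    ploidy = model_ploidy if PLOIDY_RANGE[0] <= model_ploidy <= PLOIDY_RANGE[1] else 2.0
    return PurityCall(purity, ploidy, "curated", frozenset(flags))


def adjust_segments(profile: SegmentProfile, call: PurityCall) -> SegmentProfile:
    """Adjust segment log2 ratios for tumour purity and ploidy.

    Each observed ratio r is inverted to tumour copy number n (clamped at
    zero) and re-expressed as log2(max(n, eps)/2).
    """
    p, psi = call.purity, call.ploidy
    adjusted = []
    for seg in profile.segments:
        n = (2.0 ** seg.log2_ratio * (p * psi + 2.0 * (1.0 - p)) - 2.0 * (1.0 - p)) / p
        n = max(n, 0.0)
        r_adj = math.log2(max(n, ADJUST_EPSILON) / 2.0)
        adjusted.append(Segment(seg.chrom, seg.start, seg.end, r_adj))
    return SegmentProfile(sample_id=profile.sample_id, segments=adjusted)
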