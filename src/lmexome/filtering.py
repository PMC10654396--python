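"""Multi-caller consensus merging and the somatic filter cascade.

Variants reported by at least two of the four callers are merged into a
single call per locus, then filtered by (a) restriction to exonic/splicing
regions, (b) read-support thresholds, (c) a purity-stratified minimum VAF
with an elevated threshold for the FFPE deamination artifact class (C>T and
its G>A strand mirror), and (d) cross-sample rescue: a variant failing in
one sample of a patient is exempted from filtering when the same variant
passes in another sample of that patient.

Tumour mutational burden is the size of the final filtered set divided by
the exome panel footprint in megabases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .core import FunctionalClass, Preservation, SampleMeta, VariantCall, VariantKey

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterReason",
    "FilterVerdict",
    "PurityStratum",
    "purity_stratum",
    "vaf_threshold",
    "merge_callers",
    "apply_filters",
    "rescue_cross_sample",
    "compute_tmb",
]

ARTIFACT_CLASS = "C>T"  # pyrimidine-strand fold of both C>T and G>A


class PurityStratum(str, Enum):
    HIGH = "high"  # purity > 0.5
    INTERMEDIATE = "intermediate"  # 0.2 < purity <= 0.5
    LOW = "low"  # purity <= 0.2


class FilterReason(str, Enum):
    TOO_FEW_CALLERS = "too_few_callers"
    LOW_TUMOUR_READS = "low_tumour_reads"
    HIGH_GERMLINE_READS = "high_germline_reads"
    LOW_DEPTH = "low_depth"
    BELOW_VAF_THRESHOLD = "below_vaf_threshold"
    NON_EXONIC = "non_exonic"


@dataclass(frozen=True)
class ReadThresholds:
    min_tumour_reads: int = 5
    max_germline_reads: int = 2
    min_depth: int = 10


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade.

    ``vaf_thresholds`` maps (stratum, artifact-class flag) to the minimum
    VAF; the artifact-class entry applies only to FFPE samples.  Samples
    named in ``per_sample_overrides`` (the study used this for low-coverage
    samples) replace the three read thresholds.
    """

    min_callers: int = 2
    read_thresholds: ReadThresholds = field(default_factory=ReadThresholds)
    vaf_thresholds: dict[tuple[PurityStratum, bool], float] = field(
        default_factory=lambda: {
            (PurityStratum.HIGH, False): 0.05,
            (PurityStratum.HIGH, True): 0.07,
            (PurityStratum.INTERMEDIATE, False): 0.03,
            (PurityStratum.INTERMEDIATE, True): 0.05,
            (PurityStratum.LOW, False): 0.01,
            (PurityStratum.LOW, True): 0.03,
        }
    )
    per_sample_overrides: dict[str, ReadThresholds] = field(default_factory=dict)
    ffpe_artifact_thresholds: bool = True
    target_panel_mb: float = 60.0
    tmb_high_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        for (stratum, _), v in self.vaf_thresholds.items():
            if v < 0:
                raise ValueError(f"negative VAF threshold for {stratum}")
        for stratum in PurityStratum:
            std = self.vaf_thresholds[(stratum, False)]
            art = self.vaf_thresholds[(stratum, True)]
            if art < std:
                raise ValueError(
                    f"{stratum.value}: artifact-class threshold {art} below "
                    f"standard threshold {std}"
                )


@dataclass
class FilterVerdict:
    variant: VariantKey
    call: VariantCall
    kept: bool
    reasons: frozenset[FilterReason]
    rescued: bool = False


def purity_stratum(purity: float) -> PurityStratum:
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity {purity} outside (0, 1]")
    if purity > 0.5:
        return PurityStratum.HIGH
    if purity <= 0.2:
        return PurityStratum.LOW
    return PurityStratum.INTERMEDIATE


def vaf_threshold(
    purity: float,
    preservation: Preservation,
    substitution: str,
    config: FilterConfig | None = None,
) -> float:
    """Minimum VAF for a variant given sample purity and preservation.

    The elevated FFPE threshold applies only when the sample is FFPE and
    the substitution folds to C>T (raw C>T or G>A); all other variants in
    FFPE samples use the standard threshold of the same purity stratum.
    """
    config = config or FilterConfig()
    stratum = purity_stratum(purity)
    artifact_class = (
        config.ffpe_artifact_thresholds
        and preservation is Preservation.FFPE
        and substitution == ARTIFACT_CLASS
    )
    return config.vaf_thresholds[(stratum, artifact_class)]


def merge_callers(
    per_caller_calls: dict[str, list[VariantCall]], min_callers: int = 2
) -> list[VariantCall]:
    """Merge one sample's per-caller calls into consensus calls.

    A variant is retained when reported by ``min_callers`` or more callers.
    Read counts are reconciled by taking the maximum over reporting callers
    (tumour alt reads, depth, and germline alt reads over the callers that
    report one), with VAF recomputed; duplicate keys within one caller are
    max-merged with a warning.
    """
    by_key: dict[VariantKey, list[VariantCall]] = {}
    for caller_id, calls in per_caller_calls.items():
        seen: dict[VariantKey, VariantCall] = {}
        for call in calls:
            if call.key in seen:
                logger.warning("caller %s: duplicate record for %s", caller_id, call.key)
                prev = seen[call.key]
                call = VariantCall(
                    key=call.key,
                    callers=call.callers,
                    tumour_alt_reads=max(prev.tumour_alt_reads, call.tumour_alt_reads),
                    depth=max(prev.depth, call.depth),
                    vaf=max(prev.vaf, call.vaf),
                    germline_alt_reads=_max_or_none(
                        prev.germline_alt_reads, call.germline_alt_reads
                    ),
                    functional_class=prev.functional_class,
                    substitution=prev.substitution,
                    context=prev.context or call.context,
                )
            seen[call.key] = call
        for key, call in seen.items():
            by_key.setdefault(key, []).append(call)

    merged: list[VariantCall] = []
    for key in sorted(by_key):
        group = by_key[key]
        callers = frozenset().union(*(c.callers for c in group))
        if len(callers) < min_callers:
            continue
        alt = max(c.tumour_alt_reads for c in group)
        depth = max(c.depth for c in group)
        germ_values = [c.germline_alt_reads for c in group if c.germline_alt_reads is not None]
        fclass = next(
            (c.functional_class for c in group if c.functional_class is not FunctionalClass.OTHER),
            group[0].functional_class,
        )
        context = next((c.context for c in group if c.context), None)
        merged.append(
            VariantCall(
                key=key,
                callers=callers,
                tumour_alt_reads=alt,
                depth=depth,
                vaf=alt / depth if depth else 0.0,
                germline_alt_reads=max(germ_values) if germ_values else None,
                functional_class=fclass,
                substitution=group[0].substitution,
                context=context,
            )
        )
    return merged


def _max_or_none(a: Optional[int], b: Optional[int]) -> Optional[int]:
    values = [v for v in (a, b) if v is not None]
    return max(values) if values else None


def apply_filters(
    merged: list[VariantCall], meta: SampleMeta, config: FilterConfig | None = None
) -> list[FilterVerdict]:
    """Apply the quality-filter cascade to one sample's merged calls.

    Requires the sample's consensus purity to be resolved (``meta.purity``).
    The germline-read filter is waived when no reporting caller exposes
    germline support.
    """
    config = config or FilterConfig()
    if meta.purity is None:
        raise ValueError(f"{meta.sample_id}: purity not resolved before filtering")
    thresholds = config.per_sample_overrides.get(meta.sample_id, config.read_thresholds)

    verdicts = []
    for call in merged:
        reasons: set[FilterReason] = set()
        if len(call.callers) < config.min_callers:
            reasons.add(FilterReason.TOO_FEW_CALLERS)
        if not call.functional_class.is_exonic_or_splicing:
            reasons.add(FilterReason.NON_EXONIC)
        if call.tumour_alt_reads < thresholds.min_tumour_reads:
            reasons.add(FilterReason.LOW_TUMOUR_READS)
        if (
            call.germline_alt_reads is not None
            and call.germline_alt_reads > thresholds.max_germline_reads
        ):
            reasons.add(FilterReason.HIGH_GERMLINE_READS)
        if call.depth < thresholds.min_depth:
            reasons.add(FilterReason.LOW_DEPTH)
        min_vaf = vaf_threshold(meta.purity, meta.preservation, call.substitution, config)
        if call.vaf < min_vaf:
            reasons.add(FilterReason.BELOW_VAF_THRESHOLD)
        verdicts.append(
            FilterVerdict(
                variant=call.key,
                call=call,
                kept=not reasons,
                reasons=frozenset(reasons),
            )
        )
    return verdicts


def rescue_cross_sample(
    verdicts_by_sample: dict[str, list[FilterVerdict]],
) -> dict[str, list[VariantCall]]:
    """Cross-sample rescue within one patient.

    A variant that fails filtering in sample S but was called in S and
    passes in any other sample of the same patient is exempted from the
    filters (all of them) and added to S's final set with ``rescued`` set.
    Variants never called in S are not invented.
    """
    passing_anywhere: set[VariantKey] = set()
    for verdicts in verdicts_by_sample.values():
        passing_anywhere.update(v.variant for v in verdicts if v.kept)

    final: dict[str, list[VariantCall]] = {}
    for sample_id, verdicts in verdicts_by_sample.items():
        kept = []
        for v in verdicts:
            if v.kept:
                kept.append(v.call)
            elif v.variant in passing_anywhere:
                v.rescued = True
                v.kept = True
                kept.append(v.call)
        final[sample_id] = kept
    return final


def compute_tmb(
    final_set: list[VariantCall], config: FilterConfig | None = None
) -> tuple[float, bool]:
    """Tumour mutational burden: filtered variants per targeted megabase."""
    config = config or FilterConfig()
    if config.target_panel_mb <= 0:
        raise ValueError("target_panel_mb must be positive")
    tmb = len(final_set) / config.target_panel_mb
    return tmb, tmb > config.tmb_high_cutoff
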