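"""Core domain types shared across the pipeline.

The central objects are somatic variant calls keyed by genomic locus and
alleles, segmented copy-number profiles, sample metadata, and per-gene
copy-number states.  Substitutions are always reported on the pyrimidine
strand (COSMIC convention), so a G>A call is folded to C>T with its
trinucleotide context reverse-complemented; this single convention serves
both the FFPE-artifact filter and the 96-context mutational catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "COMPLEMENT",
    "SUBSTITUTION_CLASSES",
    "CONTEXTS_96",
    "FunctionalClass",
    "SiteType",
    "Preservation",
    "VariantKey",
    "VariantCall",
    "SampleMeta",
    "SegmentProfile",
    "GeneModel",
    "fold_substitution",
    "reverse_complement",
    "left_normalize",
    "context_bin",
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The six pyrimidine-strand single-base substitution classes.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

INDEL = "INDEL"


def _build_contexts() -> tuple[str, ...]:
    bins = []
    for sub in SUBSTITUTION_CLASSES:
        ref = sub[0]
        for five in "ACGT":
            for three in "ACGT":
                bins.append(f"{five}[{sub}]{three}")
    return tuple(bins)


#: The 96 trinucleotide mutation types in COSMIC order (substitution-major,
#: flanking bases alphabetical within each substitution class).
CONTEXTS_96: tuple[str, ...] = _build_contexts()
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


class FunctionalClass(str, Enum):
    EXONIC_NONSILENT = "exonic_nonsilent"
    EXONIC_SYNONYMOUS = "exonic_synonymous"
    SPLICING = "splicing"
    OTHER = "other"

    @property
    def is_exonic_or_splicing(self) -> bool:
        return self is not FunctionalClass.OTHER

    @property
    def is_nonsilent(self) -> bool:
        return self in (FunctionalClass.EXONIC_NONSILENT, FunctionalClass.SPLICING)


class SiteType(str, Enum):
    CSF = "CSF"
    PLASMA = "plasma"
    PRIMARY = "primary"
    METASTASIS = "metastasis"


class Preservation(str, Enum):
    CFDNA = "cfDNA"
    FFPE = "FFPE"
    FRESH = "fresh"


def reverse_complement(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-nucleotide base in {seq!r}") from exc


def left_normalize(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Normalize an indel representation.

    Shared trailing bases are trimmed, then shared leading bases are trimmed
    down to a single anchor base (the VCF convention of retaining one shared
    leading base), advancing ``pos`` accordingly.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def fold_substitution(ref: str, alt: str) -> str:
    """Return the pyrimidine-strand substitution class, or ``INDEL``.

    Purine-strand SNVs (ref A or G) are complemented so that e.g. G>A
    becomes C>T.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        return INDEL
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def context_bin(ref: str, alt: str, context: str) -> str:
    """Map (ref, alt, trinucleotide context) to its 96-bin label.

    ``context`` is the reference trinucleotide centred on the variant as
    read from the reference strand; purine-strand substitutions are folded
    with the context reverse-complemented.
    """
    ref, alt = ref.upper(), alt.upper()
    context = context.upper()
    if len(context) != 3 or any(b not in "ACGT" for b in context):
        raise ValueError(f"malformed trinucleotide context {context!r}")
    if context[1] != ref:
        raise ValueError(f"context {context!r} centre does not match ref {ref!r}")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context = reverse_complement(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in _CONTEXT_INDEX:
        raise ValueError(f"not a valid mutation type: {label}")
    return label


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a somatic variant: locus and alleles.

    This is the merge key across callers and samples.  Indels are stored
    left-normalized; ``pos`` is 1-based.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")

    @classmethod
    def normalized(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        pos, ref, alt = left_normalize(pos, ref, alt)
        return cls(chrom, pos, ref, alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant observed in one sample.

    ``germline_alt_reads`` is ``None`` when no reporting caller exposes the
    normal-sample allele depth (the LoFreq-style situation).
    """

    key: VariantKey
    callers: frozenset[str]
    tumour_alt_reads: int
    depth: int
    vaf: float
    germline_alt_reads: Optional[int] = None
    functional_class: FunctionalClass = FunctionalClass.OTHER
    substitution: str = INDEL
    context: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.callers:
            raise ValueError("callers set must be nonempty")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.tumour_alt_reads > self.depth:
            raise ValueError(
                f"tumour_alt_reads {self.tumour_alt_reads} exceeds depth {self.depth}"
            )
        expected = fold_substitution(self.key.ref, self.key.alt)
        if self.substitution != expected:
            raise ValueError(
                f"substitution {self.substitution!r} inconsistent with "
                f"{self.key.ref}>{self.key.alt} (expected {expected!r})"
            )

    @property
    def is_snv(self) -> bool:
        return self.key.is_snv

    def with_callers(self, callers: Iterable[str]) -> "VariantCall":
        return replace(self, callers=frozenset(callers))


@dataclass
class SampleMeta:
    """Identity and properties of one sequenced sample."""

    sample_id: str
    patient: str
    site_type: SiteType
    preservation: Preservation
    purity_model: float
    ploidy_model: float
    purity_ulpwgs: Optional[float] = None
    median_coverage: Optional[float] = None
    #: resolved purity used by filtering; set after purity consensus
    purity: Optional[float] = None
    ploidy: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.purity_model <= 1.0):
            raise ValueError(
                f"{self.sample_id}: model purity {self.purity_model} not in (0,1]"
            )
        if self.ploidy_model <= 0:
            raise ValueError(f"{self.sample_id}: ploidy must be positive")

    @property
    def is_cfdna(self) -> bool:
        return self.preservation is Preservation.CFDNA


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SegmentProfile:
    """Segmented copy-number log2 ratios for one sample."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"[{a.start}-{a.end}] and [{b.start}-{b.end}]"
                    )

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class Gene:
    symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.symbol}: start must be < end")


@dataclass
class GeneModel:
    """Gene coordinates used to aggregate segment ratios per gene."""

    genes: list[Gene]

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.genes]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate gene symbols: {dupes}")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)
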