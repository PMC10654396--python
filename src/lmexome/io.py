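"""Readers and writers for the formats the pipeline touches.

Four somatic-caller VCF dialects are normalized into one variant
representation.  A dialect is configuration data, not code: it declares
which columns and tags carry the tumour/normal allele depths and the
annotation tags, so caller-version differences are handled by editing a
mapping rather than the parser.

Coordinate conventions: VCF and the internal tables are 1-based inclusive;
BED gene models are 0-based half-open and converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    CONTEXTS_96,
    FunctionalClass,
    Gene,
    GeneModel,
    Preservation,
    SampleMeta,
    Segment,
    SegmentProfile,
    SiteType,
    VariantCall,
    VariantKey,
    fold_substitution,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CallerDialect",
    "DEFAULT_DIALECTS",
    "read_caller_vcf",
    "write_vcf",
    "read_segments",
    "write_segments",
    "read_gene_model_bed",
    "write_gene_model_bed",
    "read_reference_signatures",
    "write_reference_signatures",
    "read_gmt",
    "write_gmt",
    "read_metadata",
    "write_metadata",
    "read_variants_tsv",
    "write_variants_tsv",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ConfigurationError(ValueError):
    """Raised for invalid run/dialect configuration."""


@dataclass(frozen=True)
class CallerDialect:
    """How one caller's VCF exposes the fields the pipeline needs.

    Two mechanisms are supported: sample-column allele depths (``ad_tag`` in
    FORMAT, with named tumour and optional normal sample columns) and
    INFO-only output (``info_depth_tag``/``info_af_tag``; no normal column,
    so germline support is unavailable).
    """

    caller_id: str
    tumour_sample: Optional[str] = "TUMOR"
    normal_sample: Optional[str] = "NORMAL"
    ad_tag: str = "AD"
    info_depth_tag: Optional[str] = None
    info_af_tag: Optional[str] = None
    functional_class_tag: str = "FCLASS"
    context_tag: str = "TNC"

    @property
    def info_based(self) -> bool:
        return self.info_depth_tag is not None


#: Dialects for the four callers of the consensus set.  The LoFreq-style
#: caller reports no normal-sample column, so its germline support is
#: unavailable by construction.
DEFAULT_DIALECTS: dict[str, CallerDialect] = {
    "mutect2": CallerDialect("mutect2"),
    "muse": CallerDialect("muse"),
    "strelka": CallerDialect("strelka"),
    "lofreq": CallerDialect(
        "lofreq",
        tumour_sample=None,
        normal_sample=None,
        info_depth_tag="DP",
        info_af_tag="AF",
    ),
}


def _scalar(value):
    if isinstance(value, (tuple, list, np.ndarray)):
        return value[0]
    return value


def read_caller_vcf(
    path: str | Path, caller_id: str, dialect: CallerDialect | None = None
) -> list[VariantCall]:
    """Parse one caller's VCF into normalized :class:`VariantCall` records.

    Only PASS-equivalent (FILTER of PASS or '.') biallelic records are
    retained; multiallelic records are skipped with a warning.  Indels are
    left-normalized on read so the merge key is caller-independent.
    """
    if dialect is None:
        if caller_id not in DEFAULT_DIALECTS:
            raise ConfigurationError(
                f"unknown caller dialect {caller_id!r}; known: "
                f"{sorted(DEFAULT_DIALECTS)}"
            )
        dialect = DEFAULT_DIALECTS[caller_id]

    vcf = VCF(str(path))
    samples = list(vcf.samples)

    def sample_index(name: Optional[str]) -> Optional[int]:
        if name is None:
            return None
        if name not in samples:
            raise ConfigurationError(
                f"{path}: dialect expects sample column {name!r}, "
                f"file has {samples}"
            )
        return samples.index(name)

    t_idx = sample_index(dialect.tumour_sample) if not dialect.info_based else None
    n_idx = sample_index(dialect.normal_sample) if not dialect.info_based else None

    calls: list[VariantCall] = []
    for rec in vcf:
        if rec.FILTER is not None:  # cyvcf2: None means PASS/'.'
            continue
        if len(rec.ALT) != 1:
            logger.warning(
                "%s: skipping multiallelic record %s:%d %s>%s",
                path,
                rec.CHROM,
                rec.POS,
                rec.REF,
                ",".join(rec.ALT),
            )
            continue
        key = VariantKey.normalized(rec.CHROM, rec.POS, rec.REF, rec.ALT[0])

        germline: Optional[int] = None
        if dialect.info_based:
            depth = int(rec.INFO.get(dialect.info_depth_tag))
            af = float(_scalar(rec.INFO.get(dialect.info_af_tag)))
            alt_reads = int(round(af * depth))
        else:
            ad = rec.format(dialect.ad_tag)
            if ad is None:
                raise FormatError(f"{path}: FORMAT/{dialect.ad_tag} missing")
            alt_reads = int(ad[t_idx][1])
            depth = int(ad[t_idx][0]) + alt_reads
            if n_idx is not None:
                germline = int(ad[n_idx][1])
        alt_reads = min(alt_reads, depth)

        fclass_raw = rec.INFO.get(dialect.functional_class_tag)
        try:
            fclass = FunctionalClass(fclass_raw) if fclass_raw else FunctionalClass.OTHER
        except ValueError:
            fclass = FunctionalClass.OTHER
        context = rec.INFO.get(dialect.context_tag) or None

        calls.append(
            VariantCall(
                key=key,
                callers=frozenset([caller_id]),
                tumour_alt_reads=alt_reads,
                depth=depth,
                vaf=alt_reads / depth if depth else 0.0,
                germline_alt_reads=germline,
                functional_class=fclass,
                substitution=fold_substitution(key.ref, key.alt),
                context=context,
            )
        )
    return calls


def write_vcf(
    path: str | Path,
    records: list[dict],
    dialect: CallerDialect,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write caller-dialect VCF 4.2 text.

    Each record dict needs chrom, pos, ref, alt, tumour_alt, depth and
    optionally germline_alt, fclass, context.  Used by the synthetic-cohort
    emitter; kept here so dialect knowledge stays in one module.
    """
    lines = ["##fileformat=VCFv4.2", f"##source=lmexome-{dialect.caller_id}"]
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        f'##INFO=<ID={dialect.functional_class_tag},Number=1,Type=String,'
        'Description="Functional class">'
    )
    lines.append(
        f'##INFO=<ID={dialect.context_tag},Number=1,Type=String,'
        'Description="Reference trinucleotide context">'
    )
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if dialect.info_based:
        lines.append(
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">'
        )
        lines.append(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">'
        )
    else:
        lines.append(
            f'##FORMAT=<ID={dialect.ad_tag},Number=R,Type=Integer,'
            'Description="Allelic depths">'
        )
        header += f"\tFORMAT\t{dialect.tumour_sample}\t{dialect.normal_sample}"
    lines.append(header)

    for r in sorted(records, key=lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"])):
        info = [f"{dialect.functional_class_tag}={r.get('fclass', 'other')}"]
        if r.get("context"):
            info.append(f"{dialect.context_tag}={r['context']}")
        if dialect.info_based:
            af = r["tumour_alt"] / r["depth"] if r["depth"] else 0.0
            info = [f"DP={r['depth']}", f"AF={af:.6f}"] + info
            row = (
                f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t."
                f"\tPASS\t{';'.join(info)}"
            )
        else:
            ref_reads = r["depth"] - r["tumour_alt"]
            g_alt = r.get("germline_alt", 0)
            g_depth = r.get("germline_depth", r["depth"])
            row = (
                f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t."
                f"\tPASS\t{';'.join(info)}\t{dialect.ad_tag}"
                f"\t{ref_reads},{r['tumour_alt']}\t{g_depth - g_alt},{g_alt}"
            )
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# segment / gene tables


def read_segments(path: str | Path) -> SegmentProfile:
    """Read a SEG-like TSV (chrom, start, end, log2) into a profile.

    Overlapping segments within a chromosome are a format error naming the
    offending rows.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "log2"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    segments = [
        Segment(str(r.chrom), int(r.start), int(r.end), float(r.log2))
        for r in df.itertuples()
    ]
    sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns and len(df) else Path(path).stem
    try:
        return SegmentProfile(sample_id=sample_id, segments=segments)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_segments(path: str | Path, profile: SegmentProfile) -> None:
    rows = [
        {
            "sample_id": profile.sample_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "log2": s.log2_ratio,
        }
        for s in profile.segments
    ]
    pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "log2"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_model_bed(path: str | Path) -> GeneModel:
    """Read a BED gene model (0-based half-open) into 1-based inclusive genes."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: BED line needs chrom/start/end/name: {line!r}")
            chrom, start, end, name = parts[:4]
            genes.append(Gene(name, chrom, int(start) + 1, int(end)))
    return GeneModel(genes)


def write_gene_model_bed(path: str | Path, model: GeneModel) -> None:
    with open(path, "w") as fh:
        for g in model:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\n")


# ---------------------------------------------------------------------------
# reference signatures / gene sets


def read_reference_signatures(path: str | Path) -> pd.DataFrame:
    """Read a COSMIC-v3.2-layout signature matrix (96 contexts x signatures).

    Rows are reindexed into canonical COSMIC context order; columns are
    renormalized to sum to one.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise FormatError(f"{path}: expected 96 context rows, found {df.shape[0]}")
    if set(df.index) != set(CONTEXTS_96):
        missing = sorted(set(CONTEXTS_96) - set(df.index))[:3]
        raise FormatError(f"{path}: context labels not in COSMIC format (missing e.g. {missing})")
    df = df.reindex(list(CONTEXTS_96)).astype(float)
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative signature entries")
    sums = df.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise FormatError(f"{path}: signature columns sum to zero: {bad}")
    return df / sums


def write_reference_signatures(path: str | Path, matrix: pd.DataFrame) -> None:
    out = matrix.copy()
    out.index.name = "Type"
    out.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT-like annotation sets: set-id, description, then genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(path: str | Path, sets: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na"] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# sample metadata


_META_COLUMNS = [
    "sample_id",
    "patient",
    "site_type",
    "preservation",
    "purity_model",
    "ploidy_model",
    "purity_ulpwgs",
    "median_coverage",
]


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_META_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    metas = []
    for r in df.itertuples():
        ulp = getattr(r, "purity_ulpwgs", None)
        cov = getattr(r, "median_coverage", None)
        metas.append(
            SampleMeta(
                sample_id=str(r.sample_id),
                patient=str(r.patient),
                site_type=SiteType(r.site_type),
                preservation=Preservation(r.preservation),
                purity_model=float(r.purity_model),
                ploidy_model=float(r.ploidy_model),
                purity_ulpwgs=None if ulp is None or pd.isna(ulp) else float(ulp),
                median_coverage=None if cov is None or pd.isna(cov) else float(cov),
            )
        )
    return metas


def write_metadata(path: str | Path, metas: list[SampleMeta]) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "patient": m.patient,
            "site_type": m.site_type.value,
            "preservation": m.preservation.value,
            "purity_model": m.purity_model,
            "ploidy_model": m.ploidy_model,
            "purity_ulpwgs": m.purity_ulpwgs,
            "median_coverage": m.median_coverage,
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant TSV interchange


_NA = "NA"


def write_variants_tsv(path: str | Path, calls_by_sample: dict[str, list[VariantCall]]) -> None:
    rows = []
    for sample_id, calls in calls_by_sample.items():
        for c in sorted(calls, key=lambda c: c.key):
            rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": c.key.chrom,
                    "pos": c.key.pos,
                    "ref": c.key.ref,
                    "alt": c.key.alt,
                    "callers": ",".join(sorted(c.callers)),
                    "tumour_alt_reads": c.tumour_alt_reads,
                    "germline_alt_reads": _NA
                    if c.germline_alt_reads is None
                    else c.germline_alt_reads,
                    "depth": c.depth,
                    "vaf": f"{c.vaf:.6g}",
                    "functional_class": c.functional_class.value,
                    "substitution": c.substitution,
                    "context": c.context or _NA,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "chrom",
            "pos",
            "ref",
            "alt",
            "callers",
            "tumour_alt_reads",
            "germline_alt_reads",
            "depth",
            "vaf",
            "functional_class",
            "substitution",
            "context",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> dict[str, list[VariantCall]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, list[VariantCall]] = {}
    for r in df.itertuples():
        call = VariantCall(
            key=VariantKey(r.chrom, int(r.pos), r.ref, r.alt),
            callers=frozenset(r.callers.split(",")),
            tumour_alt_reads=int(r.tumour_alt_reads),
            depth=int(r.depth),
            vaf=float(r.vaf),
            germline_alt_reads=None
            if r.germline_alt_reads == _NA
            else int(r.germline_alt_reads),
            functional_class=FunctionalClass(r.functional_class),
            substitution=r.substitution,
            context=None if r.context == _NA else r.context,
        )
        out.setdefault(r.sample_id, []).append(call)
    return out
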