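"""Synthetic multi-site cohort generator.

Emulates the statistical structure the downstream analysis assumes: each
patient carries a founder clone present at every tumour site plus
site-private subclones; CSF and plasma cfDNA, FFPE primary tumour and
(for a subset of patients) FFPE metastasis samples with configurable
purity; binomial read counts at Poisson-distributed depth; four callers
with logistic sensitivity in the alt-read count and caller-private false
positives; FFPE-only C>T/G>A deamination artifacts with Beta-distributed
VAF; trinucleotide contexts drawn from per-site signature mixtures
(chemotherapy signatures enriched in plasma); and arm-level integer copy
number diluted by normal cells.

Every draw descends from a single seed, hierarchically split per patient,
sample and stage, so any subset of the cohort is reproducible in
isolation.  The forward segment model

    r = log2((p*n + 2*(1-p)) / (p*psi + 2*(1-p))) + Normal(0, sd)

is exactly inverted by :func:`lmexome.purity.adjust_segments` at sd = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cna
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
    reverse_complement,
)
from .io import DEFAULT_DIALECTS, write_gene_model_bed, write_metadata, write_segments, write_vcf
from .purity import ADJUST_EPSILON
from .signatures import synthetic_reference_signatures

__all__ = [
    "SimConfig",
    "CallerProfile",
    "TrueVariant",
    "SimSample",
    "PatientTruth",
    "simulate_patient",
    "simulate_cohort",
    "emit_caller_calls",
    "emit_segments",
    "true_gene_states",
    "expected_vaf",
    "forward_log2_ratio",
    "default_gene_model",
    "write_cohort",
    "GENOME_ARMS",
]

# synthetic genome: 8 chromosomes of 100 Mb, two 50 Mb arms each
_N_CHROM = 8
_ARM_LEN = 50_000_000
GENOME_ARMS: list[tuple[str, str, int, int]] = []
for _c in range(1, _N_CHROM + 1):
    GENOME_ARMS.append((f"chr{_c}", "p", 1, _ARM_LEN))
    GENOME_ARMS.append((f"chr{_c}", "q", _ARM_LEN + 1, 2 * _ARM_LEN))

CONTIG_LENGTHS = {f"chr{c}": 2 * _ARM_LEN for c in range(1, _N_CHROM + 1)}

_SITE_ORDER = (SiteType.CSF, SiteType.PLASMA, SiteType.PRIMARY, SiteType.METASTASIS)
_PRESERVATION = {
    SiteType.CSF: Preservation.CFDNA,
    SiteType.PLASMA: Preservation.CFDNA,
    SiteType.PRIMARY: Preservation.FFPE,
    SiteType.METASTASIS: Preservation.FFPE,
}

_FOUNDER = "founder"


def default_gene_model(genes_per_arm: int = 15, gene_length: int = 50_000) -> GeneModel:
    """Evenly spaced synthetic genes, ``genes_per_arm`` per chromosome arm."""
    genes = []
    for chrom, arm, start, end in GENOME_ARMS:
        span = end - start + 1
        for i in range(genes_per_arm):
            g_start = start + (i + 1) * span // (genes_per_arm + 2)
            genes.append(
                Gene(f"GENE_{chrom[3:]}{arm}_{i:02d}", chrom, g_start, g_start + gene_length)
            )
    return GeneModel(genes)


@dataclass(frozen=True)
class CallerProfile:
    """Detection behaviour of one simulated caller."""

    caller_id: str
    sensitivity_midpoint: float = 4.0  # alt reads at 50% detection
    sensitivity_scale: float = 1.0
    false_positive_mean: float = 8.0  # Poisson mean FP records per sample
    reports_germline: bool = True


def _default_caller_profiles() -> dict[str, CallerProfile]:
    return {
        "mutect2": CallerProfile("mutect2"),
        "muse": CallerProfile("muse"),
        "strelka": CallerProfile("strelka"),
        "lofreq": CallerProfile("lofreq", reports_germline=False),
    }


def _default_mixtures() -> dict[str, dict[str, float]]:
    # chemotherapy signatures carry more weight in plasma than CSF,
    # mirroring the sanctuary-site contrast the cohort analysis tests
    return {
        _FOUNDER: {"SBS1": 0.45, "SBS5": 0.45, "SBS13": 0.10},
        SiteType.CSF.value: {"SBS1": 0.30, "SBS5": 0.40, "SBS13": 0.25, "SBS31": 0.05},
        SiteType.PLASMA.value: {
            "SBS1": 0.20,
            "SBS5": 0.25,
            "SBS13": 0.10,
            "SBS11": 0.10,
            "SBS31": 0.20,
            "SBS35": 0.15,
        },
        SiteType.PRIMARY.value: {"SBS1": 0.45, "SBS5": 0.45, "SBS13": 0.10},
        SiteType.METASTASIS.value: {
            "SBS1": 0.35,
            "SBS5": 0.35,
            "SBS13": 0.10,
            "SBS31": 0.10,
            "SBS35": 0.10,
        },
    }


def _default_cn_probs() -> dict[int, float]:
    return {0: 0.02, 1: 0.06, 2: 0.75, 3: 0.07, 4: 0.04, 5: 0.04, 6: 0.02}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults match the reference test bed: 20 patients, purity 0.5 and mean
    depth 100x at every site, 50 founder plus 20 site-private variants per
    patient, and a metastasis sample for 40% of patients.
    """

    seed: int
    n_patients: int = 20
    purity: float | dict[str, float] = 0.5
    ploidy: float = 2.0
    depth: float | dict[str, float] = 100.0
    founder_count: int = 50
    private_count: int = 20
    private_prevalence: float = 0.6
    indel_fraction: float = 0.05
    metastasis_fraction: float = 0.4
    signature_mixtures: dict[str, dict[str, float]] = field(default_factory=_default_mixtures)
    ffpe_artifact_mean: float = 40.0
    ffpe_artifact_beta: tuple[float, float] = (1.0, 50.0)
    germline_error_rate: float = 0.001
    caller_profiles: dict[str, CallerProfile] = field(default_factory=_default_caller_profiles)
    cn_state_probs: dict[int, float] = field(default_factory=_default_cn_probs)
    segment_noise_sd: float = 0.1
    functional_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "exonic_nonsilent": 0.75,
            "exonic_synonymous": 0.15,
            "splicing": 0.10,
        }
    )
    reference: Optional[pd.DataFrame] = None
    genes_per_arm: int = 15

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.reference is None:
            self.reference = synthetic_reference_signatures()
        for site, weights in self.signature_mixtures.items():
            vals = np.array(list(weights.values()))
            if (vals < 0).any() or not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"mixture for {site} must be non-negative and sum to 1")
            unknown = set(weights) - set(self.reference.columns)
            if unknown:
                raise ValueError(f"mixture for {site} names unknown signatures {unknown}")
        for site in _SITE_ORDER:
            if not (0.0 < self.purity_for(site) <= 1.0):
                raise ValueError(f"purity for {site.value} must be in (0, 1]")
        probs = np.array(list(self.cn_state_probs.values()))
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("cn_state_probs must sum to 1")

    def purity_for(self, site: SiteType) -> float:
        if isinstance(self.purity, dict):
            return self.purity[site.value]
        return float(self.purity)

    def depth_for(self, site: SiteType) -> float:
        if isinstance(self.depth, dict):
            return self.depth[site.value]
        return float(self.depth)

    def gene_model(self) -> GeneModel:
        return default_gene_model(self.genes_per_arm)


@dataclass(frozen=True)
class TrueVariant:
    key: VariantKey
    functional_class: FunctionalClass
    substitution: str
    context: Optional[str]
    clone: str  # "founder" or the private site's name
    multiplicity: int = 1
    prevalence: float = 1.0

    def present_in(self, site: SiteType) -> bool:
        return self.clone == _FOUNDER or self.clone == site.value


@dataclass(frozen=True)
class SimSample:
    sample_id: str
    patient: str
    site: SiteType
    preservation: Preservation
    purity: float
    ploidy: float
    depth: float


@dataclass
class PatientTruth:
    patient: str
    patient_index: int
    samples: list[SimSample]
    variants: list[TrueVariant]
    arm_cn: dict[str, dict[tuple[str, str], int]]  # sample_id -> (chrom, arm) -> n
    gene_cn: dict[str, dict[str, int]]  # sample_id -> gene -> n

    def sample(self, sample_id: str) -> SimSample:
        return next(s for s in self.samples if s.sample_id == sample_id)

    def variants_in(self, sample_id: str) -> list[TrueVariant]:
        site = self.sample(sample_id).site
        return [v for v in self.variants if v.present_in(site)]


def expected_vaf(purity: float, ploidy: float, multiplicity: int = 1, prevalence: float = 1.0) -> float:
    """Expected VAF of a tumour variant under the two-population mixture."""
    return purity * prevalence * multiplicity / (purity * ploidy + 2.0 * (1.0 - purity))


def forward_log2_ratio(purity: float, ploidy: float, n: int) -> float:
    """Noise-free observed log2 ratio for true tumour copy number ``n``."""
    num = max(purity * n + 2.0 * (1.0 - purity), 1e-4)
    den = purity * ploidy + 2.0 * (1.0 - purity)
    return math.log2(num / den)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def spectrum_from_mixture(reference: pd.DataFrame, weights: dict[str, float]) -> np.ndarray:
    """96-bin probability vector implied by a signature mixture."""
    spectrum = np.zeros(96)
    for sig, w in weights.items():
        spectrum += w * reference[sig].to_numpy()
    return spectrum / spectrum.sum()


def sample_context_bins(rng: np.random.Generator, spectrum: np.ndarray, n: int) -> list[str]:
    idx = rng.choice(96, size=n, p=spectrum)
    return [CONTEXTS_96[i] for i in idx]


def _variant_from_bin(
    rng: np.random.Generator, bin_label: str, used: set[tuple[str, int]]
) -> tuple[VariantKey, str]:
    """Place a mutation of the given 96-bin type at a fresh genic position.

    Half the time the variant is represented on the purine strand (e.g.
    C>T emitted as G>A with reverse-complemented context), exercising the
    folding convention downstream.
    """
    five, ref, _, alt, three = bin_label[0], bin_label[2], bin_label[3], bin_label[4], bin_label[6]
    context = five + ref + three
    if rng.random() < 0.5:
        ref, alt = reverse_complement(ref), reverse_complement(alt)
        context = reverse_complement(context)
    chrom, pos = _fresh_position(rng, used)
    return VariantKey(chrom, pos, ref, alt), context


_GENE_MODEL_CACHE: dict[int, GeneModel] = {}


def _fresh_position(rng: np.random.Generator, used: set[tuple[str, int]]) -> tuple[str, int]:
    genes = _GENE_MODEL_CACHE.setdefault(15, default_gene_model(15))
    while True:
        g = genes.genes[rng.integers(len(genes))]
        pos = int(rng.integers(g.start, g.end + 1))
        if (g.chrom, pos) not in used:
            used.add((g.chrom, pos))
            return g.chrom, pos


def _draw_fclass(rng: np.random.Generator, probs: dict[str, float]) -> FunctionalClass:
    names = list(probs)
    p = np.array([probs[n] for n in names])
    return FunctionalClass(str(rng.choice(names, p=p / p.sum())))


def _patient_sites(config: SimConfig, patient_index: int) -> list[SiteType]:
    sites = [SiteType.CSF, SiteType.PLASMA, SiteType.PRIMARY]
    # deterministic assignment of metastasis samples to ~the configured fraction
    period = 5
    cutoff = round(config.metastasis_fraction * period)
    if patient_index % period < cutoff:
        sites.append(SiteType.METASTASIS)
    return sites


def simulate_patient(config: SimConfig, patient_index: int) -> PatientTruth:
    """Generate one patient's ground truth, deterministic in (seed, index)."""
    patient = f"P{patient_index:03d}"
    rng = _rng(config.seed, patient_index, 0)
    sites = _patient_sites(config, patient_index)
    samples = [
        SimSample(
            sample_id=f"{patient}-{site.value}",
            patient=patient,
            site=site,
            preservation=_PRESERVATION[site],
            purity=config.purity_for(site),
            ploidy=config.ploidy,
            depth=config.depth_for(site),
        )
        for site in sites
    ]

    used: set[tuple[str, int]] = set()
    variants: list[TrueVariant] = []

    def make_variants(count: int, mixture: dict[str, float], clone: str, prevalence: float):
        spectrum = spectrum_from_mixture(config.reference, mixture)
        bins = sample_context_bins(rng, spectrum, count)
        for bin_label in bins:
            if rng.random() < config.indel_fraction:
                chrom, pos = _fresh_position(rng, used)
                base = "ACGT"[rng.integers(4)]
                ins = "ACGT"[rng.integers(4)]
                if rng.random() < 0.5:
                    key = VariantKey(chrom, pos, base, base + ins)
                else:
                    key = VariantKey(chrom, pos, base + ins, base)
                context = None
            else:
                key, context = _variant_from_bin(rng, bin_label, used)
            variants.append(
                TrueVariant(
                    key=key,
                    functional_class=_draw_fclass(rng, config.functional_class_probs),
                    substitution=fold_substitution(key.ref, key.alt),
                    context=context,
                    clone=clone,
                    prevalence=prevalence,
                )
            )

    make_variants(config.founder_count, config.signature_mixtures[_FOUNDER], _FOUNDER, 1.0)
    for site in sites:
        make_variants(
            config.private_count,
            config.signature_mixtures[site.value],
            site.value,
            config.private_prevalence,
        )

    arm_cn: dict[str, dict[tuple[str, str], int]] = {}
    gene_cn: dict[str, dict[str, int]] = {}
    states = np.array(list(config.cn_state_probs.keys()))
    probs = np.array(list(config.cn_state_probs.values()))
    genes = config.gene_model()
    for s_ord, sample in enumerate(samples):
        cn_rng = _rng(config.seed, patient_index, 1, s_ord)
        arms = {
            (chrom, arm): int(cn_rng.choice(states, p=probs))
            for chrom, arm, _, _ in GENOME_ARMS
        }
        arm_cn[sample.sample_id] = arms
        gene_cn[sample.sample_id] = {
            g.symbol: arms[(g.chrom, "p" if g.start <= _ARM_LEN else "q")] for g in genes
        }

    return PatientTruth(patient, patient_index, samples, variants, arm_cn, gene_cn)


def simulate_cohort(config: SimConfig) -> list[PatientTruth]:
    return [simulate_patient(config, i) for i in range(config.n_patients)]


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def emit_caller_calls(
    truth: PatientTruth, config: SimConfig
) -> dict[str, dict[str, list[VariantCall]]]:
    """Simulate per-caller call sets for every sample of one patient.

    True variants receive Binomial(depth, VAF) alt reads and are detected
    by each caller independently with logistic sensitivity in the alt-read
    count; caller false positives are private to one caller with 1-4 alt
    reads; FFPE samples additionally receive C>T/G>A deamination artifacts
    with Beta-distributed VAF.
    """
    out: dict[str, dict[str, list[VariantCall]]] = {}
    for s_ord, sample in enumerate(truth.samples):
        rng = _rng(config.seed, truth.patient_index, 2, s_ord)
        per_caller: dict[str, list[VariantCall]] = {c: [] for c in config.caller_profiles}
        used = {(v.key.chrom, v.key.pos) for v in truth.variants}

        def emit(key, context, fclass, alt, depth, germ):
            detected_any = False
            for caller_id, prof in config.caller_profiles.items():
                p_det = _logistic((alt - prof.sensitivity_midpoint) / prof.sensitivity_scale)
                if rng.random() >= p_det:
                    continue
                rep_alt = int(np.clip(alt + rng.integers(-1, 2), 1, depth))
                per_caller[caller_id].append(
                    VariantCall(
                        key=key,
                        callers=frozenset([caller_id]),
                        tumour_alt_reads=rep_alt,
                        depth=depth,
                        vaf=rep_alt / depth,
                        germline_alt_reads=germ if prof.reports_germline else None,
                        functional_class=fclass,
                        substitution=fold_substitution(key.ref, key.alt),
                        context=context,
                    )
                )
                detected_any = True
            return detected_any

        # true somatic variants
        for v in truth.variants_in(sample.sample_id):
            depth = max(1, int(rng.poisson(sample.depth)))
            vaf = expected_vaf(sample.purity, sample.ploidy, v.multiplicity, v.prevalence)
            alt = int(rng.binomial(depth, min(vaf, 1.0)))
            if alt == 0:
                continue
            germ = int(rng.binomial(depth, config.germline_error_rate))
            emit(v.key, v.context, v.functional_class, alt, depth, germ)

        # FFPE deamination artifacts: C>T on the pyrimidine strand only
        if sample.preservation is Preservation.FFPE and config.ffpe_artifact_mean > 0:
            ct_bins = [c for c in CONTEXTS_96 if "[C>T]" in c]
            for _ in range(rng.poisson(config.ffpe_artifact_mean)):
                bin_label = ct_bins[rng.integers(len(ct_bins))]
                key, context = _variant_from_bin(rng, bin_label, used)
                depth = max(1, int(rng.poisson(sample.depth)))
                vaf = rng.beta(*config.ffpe_artifact_beta)
                alt = int(rng.binomial(depth, vaf))
                if alt == 0:
                    continue
                emit(key, context, FunctionalClass.EXONIC_NONSILENT, alt, depth, 0)

        # caller-private false positives with 1-4 supporting reads
        for caller_id, prof in config.caller_profiles.items():
            for _ in range(rng.poisson(prof.false_positive_mean)):
                bin_label = CONTEXTS_96[rng.integers(96)]
                key, context = _variant_from_bin(rng, bin_label, used)
                depth = max(5, int(rng.poisson(sample.depth)))
                alt = int(rng.integers(1, 5))
                per_caller[caller_id].append(
                    VariantCall(
                        key=key,
                        callers=frozenset([caller_id]),
                        tumour_alt_reads=alt,
                        depth=depth,
                        vaf=alt / depth,
                        germline_alt_reads=0 if prof.reports_germline else None,
                        functional_class=_draw_fclass(rng, config.functional_class_probs),
                        substitution=fold_substitution(key.ref, key.alt),
                        context=context,
                    )
                )
        out[sample.sample_id] = per_caller
    return out


def emit_segments(
    truth: PatientTruth, config: SimConfig, noise_sd: Optional[float] = None
) -> dict[str, SegmentProfile]:
    """Observed (purity-diluted, noisy) arm-level segment profiles."""
    sd = config.segment_noise_sd if noise_sd is None else noise_sd
    out = {}
    for s_ord, sample in enumerate(truth.samples):
        rng = _rng(config.seed, truth.patient_index, 3, s_ord)
        segments = []
        for chrom, arm, start, end in GENOME_ARMS:
            n = truth.arm_cn[sample.sample_id][(chrom, arm)]
            r = forward_log2_ratio(sample.purity, sample.ploidy, n)
            if sd > 0:
                r += rng.normal(0.0, sd)
            segments.append(Segment(chrom, start, end, r))
        out[sample.sample_id] = SegmentProfile(sample_id=sample.sample_id, segments=segments)
    return out


def true_gene_states(truth: PatientTruth, sample_id: str, genes: GeneModel | None = None):
    """Ground-truth discrete states: the noise-free pipeline applied to true CN."""
    cn_map = truth.gene_cn[sample_id]
    ratios = {g: math.log2(max(n, ADJUST_EPSILON) / 2.0) for g, n in cn_map.items()}
    z = cna.standardize(ratios)
    return {g: cna.call_states(v) for g, v in z.items()}


def metadata_for(truths: list[PatientTruth]) -> list[SampleMeta]:
    """Sample metadata table as the purity/filtering stages consume it."""
    metas = []
    for truth in truths:
        for sample in truth.samples:
            metas.append(
                SampleMeta(
                    sample_id=sample.sample_id,
                    patient=sample.patient,
                    site_type=sample.site,
                    preservation=sample.preservation,
                    purity_model=sample.purity,
                    ploidy_model=sample.ploidy,
                    purity_ulpwgs=sample.purity if sample.preservation is Preservation.CFDNA else None,
                    median_coverage=sample.depth,
                )
            )
    return metas


def write_cohort(config: SimConfig, outdir: str | Path) -> list[PatientTruth]:
    """Simulate and write a full cohort: VCFs, segments, metadata, truth."""
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    (outdir / "segments").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    truths = simulate_cohort(config)
    truth_rows = []
    for truth in truths:
        calls = emit_caller_calls(truth, config)
        segs = emit_segments(truth, config)
        for sample_id, per_caller in calls.items():
            for caller_id, variant_calls in per_caller.items():
                dialect = DEFAULT_DIALECTS[caller_id]
                records = [
                    {
                        "chrom": c.key.chrom,
                        "pos": c.key.pos,
                        "ref": c.key.ref,
                        "alt": c.key.alt,
                        "tumour_alt": c.tumour_alt_reads,
                        "depth": c.depth,
                        "germline_alt": c.germline_alt_reads or 0,
                        "fclass": c.functional_class.value,
                        "context": c.context,
                    }
                    for c in variant_calls
                ]
                write_vcf(
                    outdir / "vcf" / f"{sample_id}.{caller_id}.vcf",
                    records,
                    dialect,
                    contigs=CONTIG_LENGTHS,
                )
            write_segments(outdir / "segments" / f"{sample_id}.seg.tsv", segs[sample_id])
        for v in truth.variants:
            truth_rows.append(
                {
                    "patient": truth.patient,
                    "chrom": v.key.chrom,
                    "pos": v.key.pos,
                    "ref": v.key.ref,
                    "alt": v.key.alt,
                    "clone": v.clone,
                    "functional_class": v.functional_class.value,
                    "prevalence": v.prevalence,
                }
            )

    pd.DataFrame(truth_rows).to_csv(outdir / "truth" / "variants.tsv", sep="\t", index=False)
    cn_rows = [
        {"sample_id": sid, "gene": g, "cn": n}
        for truth in truths
        for sid, genes_cn in truth.gene_cn.items()
        for g, n in genes_cn.items()
    ]
    pd.DataFrame(cn_rows).to_csv(outdir / "truth" / "gene_cn.tsv", sep="\t", index=False)
    write_metadata(outdir / "metadata.tsv", metadata_for(truths))
    write_gene_model_bed(outdir / "genes.bed", config.gene_model())
    echo = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "purity": config.purity,
        "ploidy": config.ploidy,
        "depth": config.depth,
        "founder_count": config.founder_count,
        "private_count": config.private_count,
        "segment_noise_sd": config.segment_noise_sd,
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    return truths
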