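"""End-to-end orchestration: simulate -> filter -> purity -> cna ->
signatures -> cohort, with a machine-readable JSON report.

The pipeline is deliberately file-centric: every stage reads the persisted
outputs of the previous one (VCFs, SEG TSVs, metadata TSV), so each stage
is individually re-runnable and a fixed config + seed yields a
byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cna, cohort, filtering, io, purity, signatures, simulate
from .core import Preservation, SampleMeta, SiteType, VariantCall

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    outdir: Path
    seed: int
    sim: Optional[simulate.SimConfig] = None
    cohort_dir: Optional[Path] = None  # pre-existing cohort (vcf/, segments/, metadata.tsv)
    filter_config: filtering.FilterConfig = field(default_factory=filtering.FilterConfig)
    reference_signatures: Optional[Path] = None
    cgc_path: Optional[Path] = None
    bc_drivers_path: Optional[Path] = None
    annotations_path: Optional[Path] = None
    external_rates_path: Optional[Path] = None
    log_level: str = "INFO"


def validate_config(path: str | Path) -> tuple[Optional[RunConfig], list[str]]:
    """Parse and validate a YAML run configuration, collecting all errors."""
    errors: list[str] = []
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"cannot read config: {exc}"]

    seed = raw.get("seed")
    if not isinstance(seed, int):
        errors.append("seed must be an integer and is mandatory")
    outdir = raw.get("outdir")
    if not outdir:
        errors.append("outdir is required")

    sim_cfg = None
    if raw.get("simulate") is not None:
        sim_raw = dict(raw["simulate"])
        try:
            sim_cfg = simulate.SimConfig(seed=seed if isinstance(seed, int) else 0, **sim_raw)
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate: {exc}")
    cohort_dir = raw.get("cohort_dir")
    if sim_cfg is None and cohort_dir is None:
        errors.append("either a simulate block or cohort_dir is required")
    if cohort_dir is not None and not Path(cohort_dir).exists():
        errors.append(f"cohort_dir does not exist: {cohort_dir}")

    fc = filtering.FilterConfig()
    if "filter" in raw:
        f_raw = dict(raw["filter"])
        overrides = {
            sid: filtering.ReadThresholds(*vals)
            for sid, vals in f_raw.pop("per_sample_overrides", {}).items()
        }
        try:
            fc = filtering.FilterConfig(per_sample_overrides=overrides, **f_raw)
        except (TypeError, ValueError) as exc:
            errors.append(f"filter: {exc}")

    for key in ("reference_signatures", "cgc", "bc_drivers", "annotations", "external_rates"):
        if key in raw and not Path(raw[key]).exists():
            errors.append(f"{key} path does not exist: {raw[key]}")

    if errors:
        return None, errors
    return (
        RunConfig(
            outdir=Path(outdir),
            seed=seed,
            sim=sim_cfg,
            cohort_dir=Path(cohort_dir) if cohort_dir else None,
            filter_config=fc,
            reference_signatures=Path(raw["reference_signatures"]) if "reference_signatures" in raw else None,
            cgc_path=Path(raw["cgc"]) if "cgc" in raw else None,
            bc_drivers_path=Path(raw["bc_drivers"]) if "bc_drivers" in raw else None,
            annotations_path=Path(raw["annotations"]) if "annotations" in raw else None,
            external_rates_path=Path(raw["external_rates"]) if "external_rates" in raw else None,
            log_level=raw.get("log_level", "INFO"),
        ),
        [],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_gene_sets(config: RunConfig, gene_model) -> tuple[set[str], set[str], dict[str, set[str]]]:
    symbols = [g.symbol for g in gene_model]
    cgc = (
        set(Path(config.cgc_path).read_text().split())
        if config.cgc_path
        else set(symbols[: len(symbols) // 4])
    )
    bc = (
        set(Path(config.bc_drivers_path).read_text().split())
        if config.bc_drivers_path
        else set(symbols[len(symbols) // 4 : len(symbols) // 4 + len(symbols) // 8])
    )
    if config.annotations_path:
        annotations = io.read_gmt(config.annotations_path)
    else:
        annotations = {}
        for g in gene_model:
            arm = g.symbol.split("_")[1]
            annotations.setdefault(f"ARM_{arm}", set()).add(g.symbol)
    return cgc, bc, annotations


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and persist) the JSON-serializable report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage: cohort inputs -------------------------------------------
    if config.sim is not None:
        cohort_dir = outdir / "cohort"
        logger.info("simulating cohort into %s", cohort_dir)
        simulate.write_cohort(config.sim, cohort_dir)
    else:
        cohort_dir = Path(config.cohort_dir)

    metas = io.read_metadata(cohort_dir / "metadata.tsv")
    gene_model = io.read_gene_model_bed(cohort_dir / "genes.bed")
    if config.reference_signatures:
        reference = io.read_reference_signatures(config.reference_signatures)
    else:
        reference = signatures.synthetic_reference_signatures()

    # --- stage: merge + purity + filter ---------------------------------
    merged_by_sample: dict[str, list[VariantCall]] = {}
    purity_calls: dict[str, purity.PurityCall] = {}
    for meta in metas:
        per_caller = {}
        for caller_id in io.DEFAULT_DIALECTS:
            vcf_path = cohort_dir / "vcf" / f"{meta.sample_id}.{caller_id}.vcf"
            if vcf_path.exists():
                per_caller[caller_id] = io.read_caller_vcf(vcf_path, caller_id)
        merged = filtering.merge_callers(per_caller, config.filter_config.min_callers)
        merged_by_sample[meta.sample_id] = merged
        median_vaf = float(np.median([c.vaf for c in merged])) if merged else 0.0
        call = purity.consensus_purity(
            model_purity=meta.purity_model,
            model_ploidy=meta.ploidy_model,
            ulpwgs_purity=meta.purity_ulpwgs,
            sample_type="cfDNA" if meta.preservation is Preservation.CFDNA else "tissue",
            median_vaf=median_vaf,
        )
        purity_calls[meta.sample_id] = call
        meta.purity, meta.ploidy = call.purity, call.ploidy

    metas_by_patient: dict[str, list[SampleMeta]] = {}
    for meta in metas:
        metas_by_patient.setdefault(meta.patient, []).append(meta)

    final_sets: dict[str, list[VariantCall]] = {}
    verdict_counts: dict[str, dict[str, int]] = {}
    for patient, patient_metas in metas_by_patient.items():
        verdicts = {
            m.sample_id: filtering.apply_filters(
                merged_by_sample[m.sample_id], m, config.filter_config
            )
            for m in patient_metas
        }
        finals = filtering.rescue_cross_sample(verdicts)
        final_sets.update(finals)
        for sid, vs in verdicts.items():
            verdict_counts[sid] = {
                "merged": len(vs),
                "kept": sum(v.kept for v in vs),
                "rescued": sum(v.rescued for v in vs),
            }
    io.write_variants_tsv(outdir / "variants.filtered.tsv", final_sets)

    tmb = {
        sid: filtering.compute_tmb(calls, config.filter_config)
        for sid, calls in final_sets.items()
    }

    # --- stage: copy number ---------------------------------------------
    gene_states: dict[str, dict[str, cna.CNState]] = {}
    state_rows = []
    for meta in metas:
        profile = io.read_segments(cohort_dir / "segments" / f"{meta.sample_id}.seg.tsv")
        adjusted = purity.adjust_segments(profile, purity_calls[meta.sample_id])
        ratios = cna.gene_level_ratios(adjusted, gene_model)
        z = cna.standardize(ratios)
        states = {g: cna.call_states(v) for g, v in z.items()}
        gene_states[meta.sample_id] = states
        for g in sorted(states):
            state_rows.append(
                {
                    "sample_id": meta.sample_id,
                    "gene": g,
                    "r_adj": ratios[g],
                    "z": z[g],
                    "state": states[g].label,
                }
            )
    pd.DataFrame(state_rows).to_csv(outdir / "gene_states.tsv", sep="\t", index=False)

    # --- stage: signatures ----------------------------------------------
    refits: dict[str, signatures.SignatureRefit] = {}
    for meta in metas:
        snvs = [c for c in final_sets[meta.sample_id] if c.is_snv]
        catalog = signatures.build_catalog(meta.sample_id, snvs)
        refits[meta.sample_id] = signatures.refit_exposures(catalog, reference)
    by_site = lambda site: [m.sample_id for m in metas if m.site_type is site]
    chemo_stats = {}
    csf_ids, plasma_ids = by_site(SiteType.CSF), by_site(SiteType.PLASMA)
    if csf_ids and plasma_ids:
        p, mean_csf, mean_plasma = signatures.chemo_contribution_compare(
            [refits[s] for s in csf_ids], [refits[s] for s in plasma_ids]
        )
        chemo_stats = {"p_value": p, "mean_csf": mean_csf, "mean_plasma": mean_plasma}

    # --- stage: cohort statistics ---------------------------------------
    nonsilent_keys = {
        sid: {c.key for c in calls if c.functional_class.is_nonsilent}
        for sid, calls in final_sets.items()
    }
    site_of = {m.sample_id: m.site_type for m in metas}
    partitions = {"csf_vs_primary": [], "csf_vs_plasma": []}
    for patient, patient_metas in metas_by_patient.items():
        ids = {m.site_type: m.sample_id for m in patient_metas}
        for label, other in (("csf_vs_primary", SiteType.PRIMARY), ("csf_vs_plasma", SiteType.PLASMA)):
            if SiteType.CSF in ids and other in ids:
                a, b = nonsilent_keys[ids[SiteType.CSF]], nonsilent_keys[ids[other]]
                if a or b:
                    partitions[label].append(
                        cohort.partition_variants(a, b, patient, ids[SiteType.CSF], ids[other])
                    )
    partition_summary = {
        label: cohort.cohort_partition_summary(parts).to_dict()
        for label, parts in partitions.items()
        if parts
    }

    gene_span = {
        g.symbol: (g.chrom, g.start, g.end) for g in gene_model
    }

    def genes_hit(keys) -> set[str]:
        hits = set()
        for key in keys:
            for sym, (chrom, start, end) in gene_span.items():
                if key.chrom == chrom and start <= key.pos <= end:
                    hits.add(sym)
                    break
        return hits

    nonsilent_genes = {sid: genes_hit(keys) for sid, keys in nonsilent_keys.items()}
    matrices = {
        site: cohort.build_alteration_matrix(
            {s: nonsilent_genes[s] for s in by_site(site)},
            {s: gene_states[s] for s in by_site(site)},
        )
        for site in (SiteType.CSF, SiteType.PLASMA, SiteType.PRIMARY)
        if by_site(site)
    }

    cgc, bc_drivers, annotations = _read_gene_sets(config, gene_model)
    drivers = cohort.select_driver_genes(matrices[SiteType.CSF], cgc, bc_drivers)

    exclusivity = {}
    csf_matrix = matrices[SiteType.CSF]
    top = csf_matrix.sum(axis=1).sort_values(ascending=False)
    if len(top) >= 2 and top.iloc[1] > 0:
        g1, g2 = top.index[0], top.index[1]
        p, table = cohort.mutual_exclusivity(csf_matrix, g1, g2)
        exclusivity = {"gene_a": g1, "gene_b": g2, "p_value": p, "table": list(table)}

    enrichment = {}
    if SiteType.PRIMARY in matrices:
        gene_list = cohort.enrichment_gene_list(
            csf_matrix, matrices[SiteType.PRIMARY], min_focal=4, max_tissue=2
        )
        background = set(csf_matrix.index)
        enr = (
            cohort.overrepresentation_test(gene_list, annotations, background)
            if gene_list
            else []
        )
        enrichment = {
            "n_genes": len(gene_list),
            "retained_sets": [r.set_id for r in enr if r.retained],
        }

    external = {}
    if config.external_rates_path:
        rates_df = pd.read_csv(config.external_rates_path, sep="\t")
        rates = {r.gene: (int(r.altered), int(r.total)) for r in rates_df.itertuples()}
        cmp_df = cohort.compare_alteration_rates(csf_matrix, rates)
        cmp_df.to_csv(outdir / "external_rates.tsv", sep="\t", index=False)
        external = {"n_tested": len(cmp_df), "n_significant": int(cmp_df["significant"].sum())}

    # --- report ----------------------------------------------------------
    state_tallies = {
        sid: {s.label: sum(1 for v in states.values() if v is s) for s in cna.CNState}
        for sid, states in gene_states.items()
    }
    report = {
        "seed": config.seed,
        "inputs": {
            "metadata_sha256": _sha256(cohort_dir / "metadata.tsv"),
            "genes_sha256": _sha256(cohort_dir / "genes.bed"),
        },
        "samples": {
            m.sample_id: {
                "patient": m.patient,
                "site": m.site_type.value,
                "counts": verdict_counts[m.sample_id],
                "n_final": len(final_sets[m.sample_id]),
                "tmb": round(tmb[m.sample_id][0], 6),
                "tmb_high": tmb[m.sample_id][1],
                "purity": round(purity_calls[m.sample_id].purity, 6),
                "ploidy": round(purity_calls[m.sample_id].ploidy, 6),
                "purity_source": purity_calls[m.sample_id].source,
                "purity_flags": sorted(f.value for f in purity_calls[m.sample_id].flags),
                "cn_states": state_tallies[m.sample_id],
                "chemo_contribution": round(refits[m.sample_id].chemo_contribution, 6),
                "refit_cosine": round(refits[m.sample_id].cosine, 6),
            }
            for m in metas
        },
        "partitions": partition_summary,
        "chemo_comparison": chemo_stats,
        "driver_genes": drivers,
        "mutual_exclusivity": exclusivity,
        "enrichment": enrichment,
        "external_comparison": external,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
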