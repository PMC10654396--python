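"""Recovery benchmarks of the pipeline on synthetic cohorts.

These drivers score each stage against the generator's ground truth:
precision/recall of the filter cascade, the FFPE-threshold effect on
deamination artifacts, copy-number state recovery under segment noise, and
signature-refit accuracy.  They are used by the test suite and by
``scripts/acceptance.py`` so the same measurement is computed in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cna, filtering, purity, signatures, simulate
from .core import Preservation, SampleMeta

__all__ = [
    "FilterRecovery",
    "score_filter_cascade",
    "score_cn_state_recovery",
    "score_signature_recovery",
]


@dataclass
class FilterRecovery:
    precision: float
    recall: float
    n_artifacts_merged: int
    artifact_pass_rate_ffpe: float
    artifact_pass_rate_standard: float


def _meta_for(truth: simulate.PatientTruth, sample: simulate.SimSample) -> SampleMeta:
    return SampleMeta(
        sample_id=sample.sample_id,
        patient=truth.patient,
        site_type=sample.site,
        preservation=sample.preservation,
        purity_model=sample.purity,
        ploidy_model=sample.ploidy,
        purity=sample.purity,
        ploidy=sample.ploidy,
    )


def score_filter_cascade(config: simulate.SimConfig) -> FilterRecovery:
    """Precision/recall of final variant sets against truth, plus the
    pass-rate of merged FFPE artifacts with and without the elevated
    artifact-class VAF thresholds."""
    fc_on = filtering.FilterConfig()
    fc_off = filtering.FilterConfig(ffpe_artifact_thresholds=False)
    tp = fp = fn = 0
    art_total = art_on = art_off = 0
    for truth in simulate.simulate_cohort(config):
        calls = simulate.emit_caller_calls(truth, config)
        true_keys_all = {v.key for v in truth.variants}
        verdicts = {}
        for sample in truth.samples:
            merged = filtering.merge_callers(calls[sample.sample_id], fc_on.min_callers)
            meta = _meta_for(truth, sample)
            verdicts[sample.sample_id] = filtering.apply_filters(merged, meta, fc_on)
            if sample.preservation is Preservation.FFPE:
                # merged non-true calls in FFPE samples are deamination
                # artifacts: caller-private false positives never reach
                # the two-caller consensus
                artifacts = [c for c in merged if c.key not in true_keys_all]
                art_total += len(artifacts)
                art_on += sum(v.kept for v in filtering.apply_filters(artifacts, meta, fc_on))
                art_off += sum(v.kept for v in filtering.apply_filters(artifacts, meta, fc_off))
        finals = filtering.rescue_cross_sample(verdicts)
        for sample in truth.samples:
            true_keys = {v.key for v in truth.variants_in(sample.sample_id)}
            got = {c.key for c in finals[sample.sample_id]}
            tp += len(got & true_keys)
            fp += len(got - true_keys)
            fn += len(true_keys - got)
    return FilterRecovery(
        precision=tp / (tp + fp),
        recall=tp / (tp + fn),
        n_artifacts_merged=art_total,
        artifact_pass_rate_ffpe=art_on / art_total if art_total else 0.0,
        artifact_pass_rate_standard=art_off / art_total if art_total else 0.0,
    )


def score_cn_state_recovery(
    seed: int,
    purities: tuple[float, ...] = (0.4, 0.55, 0.7, 0.85, 1.0),
    noise_sd: float = 0.1,
    n_patients: int = 4,
) -> float:
    """Fraction of gene states recovered after the noisy forward model,
    purity adjustment, standardization and state calling."""
    total = match = 0
    for p_idx, p in enumerate(purities):
        cfg = simulate.SimConfig(
            seed=seed + p_idx, purity=p, n_patients=n_patients, segment_noise_sd=noise_sd
        )
        genes = cfg.gene_model()
        for i in range(n_patients):
            truth = simulate.simulate_patient(cfg, i)
            segs = simulate.emit_segments(truth, cfg)
            for sample in truth.samples:
                adjusted = purity.adjust_segments(
                    segs[sample.sample_id],
                    purity.PurityCall(sample.purity, sample.ploidy, "model_estimate"),
                )
                z = cna.standardize(cna.gene_level_ratios(adjusted, genes))
                called = {g: cna.call_states(v) for g, v in z.items()}
                expected = simulate.true_gene_states(truth, sample.sample_id)
                for g, s in expected.items():
                    total += 1
                    match += called[g] is s
    return match / total


def score_signature_recovery(
    seed: int, n_replicates: int = 200, n_snvs: int = 500
) -> float:
    """Mean L1 error of refit contributions over random two-signature
    Poisson-noised mixtures."""
    reference = signatures.synthetic_reference_signatures()
    rng = np.random.default_rng(seed)
    errors = []
    n_sigs = reference.shape[1]
    for _ in range(n_replicates):
        i, j = rng.choice(n_sigs, size=2, replace=False)
        w = rng.uniform(0.2, 0.8)
        truth = w * reference.iloc[:, i].to_numpy() + (1 - w) * reference.iloc[:, j].to_numpy()
        counts = rng.poisson(n_snvs * truth)
        refit = signatures.refit_exposures(
            signatures.MutationalCatalog("rep", counts), reference
        )
        want = np.zeros(n_sigs)
        want[i], want[j] = w, 1 - w
        errors.append(float(np.abs(refit.contributions - want).sum()))
    return float(np.mean(errors))
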