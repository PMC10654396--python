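"""Mutational catalogs and single-base-substitution signature refitting.

Filtered SNVs are binned into the 96 trinucleotide mutation types on the
pyrimidine strand and refit against a reference signature matrix by
non-negative least squares on raw counts; exposures are reported both raw
and as relative contributions (normalized to sum 1), together with the
cosine similarity between the reconstruction and the catalog.

The six chemotherapy-related signatures (SBS11, SBS17b, SBS28, SBS31,
SBS35, SBS86) are aggregated into a single per-sample contribution and
compared between sample groups with a two-tailed Mann-Whitney test, exact
when both groups are small and tie-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .core import CONTEXTS_96, VariantCall, context_bin

logger = logging.getLogger(__name__)

__all__ = [
    "CHEMOTHERAPY_SIGNATURES",
    "MutationalCatalog",
    "SignatureRefit",
    "build_catalog",
    "refit_exposures",
    "cosine_similarity",
    "chemo_contribution_compare",
    "synthetic_reference_signatures",
]

#: Chemotherapy-associated single-base-substitution signatures.
CHEMOTHERAPY_SIGNATURES = ("SBS11", "SBS17b", "SBS28", "SBS31", "SBS35", "SBS86")


@dataclass
class MutationalCatalog:
    """96-context SNV counts for one sample."""

    sample_id: str
    counts: np.ndarray  # shape (96,), non-negative integers
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("catalog must have 96 bins")
        if (self.counts < 0).any():
            raise ValueError("negative catalog counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SignatureRefit:
    sample_id: str
    signatures: tuple[str, ...]
    exposures: np.ndarray  # non-negative, catalog scale
    cosine: float

    @property
    def contributions(self) -> np.ndarray:
        """Exposures normalized to sum 1 (all zero for an empty catalog)."""
        total = self.exposures.sum()
        if total == 0:
            return np.zeros_like(self.exposures)
        return self.exposures / total

    @property
    def chemo_contribution(self) -> float:
        contrib = self.contributions
        return float(
            sum(
                contrib[i]
                for i, s in enumerate(self.signatures)
                if s in CHEMOTHERAPY_SIGNATURES
            )
        )


def build_catalog(sample_id: str, snvs: list[VariantCall]) -> MutationalCatalog:
    """Bin SNVs into the 96 mutation types after pyrimidine-strand folding.

    Indels and records without a usable trinucleotide context are skipped
    and counted in ``n_skipped``.
    """
    counts = np.zeros(96)
    index = {c: i for i, c in enumerate(CONTEXTS_96)}
    skipped = 0
    for call in snvs:
        if not call.is_snv or call.context is None:
            skipped += 1
            continue
        try:
            label = context_bin(call.key.ref, call.key.alt, call.context)
        except ValueError as exc:
            logger.warning("skipping %s: %s", call.key, exc)
            skipped += 1
            continue
        counts[index[label]] += 1
    return MutationalCatalog(sample_id=sample_id, counts=counts, n_skipped=skipped)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two non-negative 96-vectors; 0 if either is zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if (u < 0).any() or (v < 0).any():
        raise ValueError("cosine_similarity requires non-negative vectors")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        logger.warning("zero vector in cosine similarity; returning 0")
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def refit_exposures(catalog: MutationalCatalog, reference: pd.DataFrame) -> SignatureRefit:
    """Refit a catalog against reference signatures by NNLS on raw counts."""
    ref = reference.reindex(list(CONTEXTS_96))
    if ref.isna().any().any():
        raise ValueError("reference matrix not indexed by the 96 COSMIC contexts")
    sums = ref.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("reference signature columns must sum to 1")
    signatures = tuple(ref.columns)
    if catalog.total == 0:
        logger.warning("%s: empty catalog; zero exposures", catalog.sample_id)
        return SignatureRefit(catalog.sample_id, signatures, np.zeros(len(signatures)), 0.0)
    exposures, _ = nnls(ref.values, catalog.counts)
    reconstruction = ref.values @ exposures
    cos = cosine_similarity(reconstruction, catalog.counts) if reconstruction.sum() else 0.0
    return SignatureRefit(catalog.sample_id, signatures, exposures, cos)


def chemo_contribution_compare(
    refits_a: list[SignatureRefit], refits_b: list[SignatureRefit]
) -> tuple[float, float, float]:
    """Two-tailed Mann-Whitney comparison of chemotherapy-signature burden.

    Returns (p, mean_A, mean_B).  The exact null distribution is used when
    both groups have at most 8 samples and the pooled values are tie-free;
    otherwise the tie-corrected normal approximation.
    """
    if not refits_a or not refits_b:
        raise ValueError("both groups must be nonempty")
    a = np.array([r.chemo_contribution for r in refits_a])
    b = np.array([r.chemo_contribution for r in refits_b])
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # identical constant groups carry no ordering information
        return 1.0, float(a.mean()), float(b.mean())
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    return min(p, 1.0), float(a.mean()), float(b.mean())


def synthetic_reference_signatures(n_flat: int = 0) -> pd.DataFrame:
    """A deterministic synthetic reference signature matrix.

    Synthetic stand-in for a COSMIC v3.2 signature file: same layout
    (96 contexts x signatures, columns summing to 1) and the same column
    names for nine signatures including the six chemotherapy-related ones,
    but the profiles themselves are generated sparse-random and are NOT the
    COSMIC profiles.  A genuine COSMIC TSV can be supplied to the pipeline
    by path instead.
    """
    names = ["SBS1", "SBS5", "SBS13"] + list(CHEMOTHERAPY_SIGNATURES)
    rng = np.random.default_rng(np.random.SeedSequence(892174))
    cols = {}
    # SBS1-flavoured column: mass on N[C>T]G bins, like the deamination clock
    sbs1 = np.zeros(96)
    for i, ctx in enumerate(CONTEXTS_96):
        if "[C>T]" in ctx and ctx.endswith("G"):
            sbs1[i] = 1.0
    sbs1 += rng.dirichlet(np.ones(96)) * 0.4
    cols["SBS1"] = sbs1 / sbs1.sum()
    for name in names[1:]:
        profile = np.zeros(96)
        active = rng.choice(96, size=12, replace=False)
        profile[active] = rng.dirichlet(np.ones(12))
        cols[name] = profile
    for k in range(n_flat):
        cols[f"SBSflat{k}"] = np.full(96, 1.0 / 96)
    return pd.DataFrame(cols, index=list(CONTEXTS_96))
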