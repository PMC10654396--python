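"""Cross-sample and cross-cohort statistics.

Covers: shared/unique variant partitioning between paired samples of one
patient; the gene x sample alteration matrix (non-silent mutation OR
amplification OR deep deletion); driver-gene selection by recurrence in
curated gene lists; alteration-rate comparison against an external cohort
rate table; pairwise mutual-exclusivity Fisher tests; construction of
enriched-gene lists (frequently altered in cfDNA, rarely in matched
tissue); and Fisher overrepresentation of those lists in GMT annotation
sets with Benjamini-Hochberg control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cna import CNState, two_proportion_test
from .core import VariantKey

logger = logging.getLogger(__name__)

__all__ = [
    "PairPartition",
    "EnrichmentResult",
    "partition_variants",
    "cohort_partition_summary",
    "build_alteration_matrix",
    "select_driver_genes",
    "compare_alteration_rates",
    "mutual_exclusivity",
    "enrichment_gene_list",
    "overrepresentation_test",
]

#: alteration-matrix copy-number events: high-level changes only
HIGH_LEVEL_STATES = {CNState.AMPLIFICATION, CNState.DELETION}

RETAIN_MIN_SET_SIZE = 10
RETAIN_NEGLOG10P = 3.0
RETAIN_FDR = 0.05


@dataclass(frozen=True)
class PairPartition:
    """Shared/unique variant partition of one sample pair."""

    patient: str
    sample_a: str
    sample_b: str
    n_unique_a: int
    n_unique_b: int
    n_shared: int

    @property
    def n_union(self) -> int:
        return self.n_unique_a + self.n_unique_b + self.n_shared

    @property
    def frac_unique_a(self) -> float:
        return self.n_unique_a / self.n_union

    @property
    def frac_unique_b(self) -> float:
        return self.n_unique_b / self.n_union

    @property
    def frac_shared(self) -> float:
        return self.n_shared / self.n_union


def partition_variants(
    set_a: set[VariantKey],
    set_b: set[VariantKey],
    patient: str = "",
    sample_a: str = "A",
    sample_b: str = "B",
) -> PairPartition:
    """Partition the union of two samples' variants into unique/shared counts."""
    if not set_a and not set_b:
        raise ValueError("both variant sets are empty; fractions undefined")
    shared = set_a & set_b
    return PairPartition(
        patient=patient,
        sample_a=sample_a,
        sample_b=sample_b,
        n_unique_a=len(set_a - set_b),
        n_unique_b=len(set_b - set_a),
        n_shared=len(shared),
    )


def cohort_partition_summary(partitions: list[PairPartition]) -> pd.DataFrame:
    """Median and IQR of each partition fraction across sample pairs."""
    if not partitions:
        raise ValueError("no partitions to summarize")
    rows = {}
    for name, values in (
        ("unique_a", [p.frac_unique_a for p in partitions]),
        ("unique_b", [p.frac_unique_b for p in partitions]),
        ("shared", [p.frac_shared for p in partitions]),
    ):
        arr = np.array(values)
        rows[name] = {
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
        }
    return pd.DataFrame(rows).T


def build_alteration_matrix(
    nonsilent_genes: dict[str, set[str]],
    gene_states: dict[str, dict[str, CNState]],
) -> pd.DataFrame:
    """Boolean gene x sample matrix of "altered".

    A gene is altered in a sample iff the sample carries a non-silent
    mutation in it OR its copy-number state is amplification or deletion
    (gain and shallow loss do not count).  ``nonsilent_genes`` maps
    sample_id -> genes with a non-silent mutation; ``gene_states`` maps
    sample_id -> gene -> state.
    """
    samples = sorted(set(nonsilent_genes) | set(gene_states))
    genes: set[str] = set()
    for g in nonsilent_genes.values():
        genes |= g
    for states in gene_states.values():
        genes |= set(states)
    for sample_id, mut_genes in nonsilent_genes.items():
        unknown = mut_genes - set(gene_states.get(sample_id, {}))
        if unknown and gene_states.get(sample_id):
            logger.info(
                "%s: %d mutated genes outside the CN gene model", sample_id, len(unknown)
            )
    matrix = pd.DataFrame(False, index=sorted(genes), columns=samples)
    for sample_id in samples:
        for g in nonsilent_genes.get(sample_id, set()):
            matrix.loc[g, sample_id] = True
        for g, state in gene_states.get(sample_id, {}).items():
            if state in HIGH_LEVEL_STATES:
                matrix.loc[g, sample_id] = True
    return matrix


def select_driver_genes(
    matrix: pd.DataFrame,
    cgc: set[str],
    bc_drivers: set[str],
    min_cgc_cases: int = 4,
    min_bc_cases: int = 3,
) -> list[str]:
    """Recurrently altered driver genes.

    Union of curated cancer genes altered in at least ``min_cgc_cases``
    samples and breast-cancer driver genes altered in at least
    ``min_bc_cases`` samples of the matrix.
    """
    if not cgc and not bc_drivers:
        logger.warning("empty driver gene lists; no genes selectable")
    counts = matrix.sum(axis=1)
    selected = {
        g for g in matrix.index if g in cgc and counts[g] >= min_cgc_cases
    } | {g for g in matrix.index if g in bc_drivers and counts[g] >= min_bc_cases}
    return sorted(selected, key=lambda g: (-counts[g], g))


def compare_alteration_rates(
    matrix: pd.DataFrame,
    external_rates: dict[str, tuple[int, int]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene alteration-rate comparison against an external cohort.

    ``external_rates`` maps gene -> (altered count, cohort size).  Each gene
    is tested with a two-sided two-proportion chi-square (Fisher fallback at
    small expected counts); genes absent from the external table are
    skipped.
    """
    n_internal = matrix.shape[1]
    rows = []
    for gene in matrix.index:
        if gene not in external_rates:
            logger.info("%s: no external rate; skipped", gene)
            continue
        k_int = int(matrix.loc[gene].sum())
        k_ext, n_ext = external_rates[gene]
        p = two_proportion_test(k_int, n_internal, k_ext, n_ext)
        rows.append(
            {
                "gene": gene,
                "rate_internal": k_int / n_internal,
                "rate_external": k_ext / n_ext,
                "p_value": p,
                "significant": p <= alpha,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "rate_internal", "rate_external", "p_value", "significant"])


def mutual_exclusivity(
    matrix: pd.DataFrame, gene_a: str, gene_b: str
) -> tuple[float, tuple[int, int, int, int]]:
    """Two-sided Fisher exact test of co-alteration between two genes.

    Returns (p, (both, A-only, B-only, neither)).  The two-sided p-value
    sums hypergeometric probabilities of all tables (at fixed margins) no
    more likely than the observed one.  Degenerate margins (a gene altered
    in no or all samples) return p = 1 with a warning.
    """
    a = matrix.loc[gene_a].astype(bool)
    b = matrix.loc[gene_b].astype(bool)
    both = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    n = both + a_only + b_only + neither
    table = (both, a_only, b_only, neither)
    if a.sum() in (0, n) or b.sum() in (0, n):
        logger.warning("degenerate margins for %s/%s; p = 1", gene_a, gene_b)
        return 1.0, table
    p = float(stats.fisher_exact([[both, a_only], [b_only, neither]], alternative="two-sided")[1])
    return p, table


def enrichment_gene_list(
    focal_matrix: pd.DataFrame,
    tissue_matrix: pd.DataFrame,
    min_focal: int,
    max_tissue: int,
) -> list[str]:
    """Genes frequently altered in the focal (cfDNA) group, rarely in tissue.

    A gene qualifies when altered in at least ``min_focal`` focal samples
    and at most ``max_tissue`` tissue samples.  Genes absent from the
    tissue matrix count as unaltered there.
    """
    focal_counts = focal_matrix.sum(axis=1)
    tissue_counts = tissue_matrix.sum(axis=1)
    out = []
    for gene in focal_matrix.index:
        if focal_counts[gene] >= min_focal and tissue_counts.get(gene, 0) <= max_tissue:
            out.append(gene)
    return sorted(out)


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    overlap: int
    set_size: int
    p_value: float
    q_value: float
    retained: bool


def overrepresentation_test(
    gene_list: list[str] | set[str],
    annotation_sets: dict[str, set[str]],
    background: set[str],
) -> list[EnrichmentResult]:
    """One-sided Fisher overrepresentation of a gene list in annotation sets.

    Each set is restricted to the background universe before testing.
    Benjamini-Hochberg q-values are computed across all tested sets; a set
    is retained when its (background-restricted) size is >= 10, -log10 p
    >= 3.0 and q < 0.05.
    """
    gene_set = set(gene_list)
    if not gene_set:
        raise ValueError("empty gene list")
    if not gene_set <= background:
        raise ValueError("gene list must be a subset of the background universe")

    tested = []
    for set_id, members in annotation_sets.items():
        members_bg = members & background
        if not members_bg:
            logger.info("%s: no overlap with background; skipped", set_id)
            continue
        overlap = len(gene_set & members_bg)
        in_list_out_set = len(gene_set - members_bg)
        out_list_in_set = len(members_bg - gene_set)
        rest = len(background) - overlap - in_list_out_set - out_list_in_set
        p = float(
            stats.fisher_exact(
                [[overlap, in_list_out_set], [out_list_in_set, rest]],
                alternative="greater",
            )[1]
        )
        tested.append((set_id, overlap, len(members_bg), p))

    if not tested:
        return []
    pvals = [t[3] for t in tested]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = []
    for (set_id, overlap, size, p), q in zip(tested, qvals):
        retained = (
            size >= RETAIN_MIN_SET_SIZE
            and -math.log10(max(p, 1e-300)) >= RETAIN_NEGLOG10P
            and q < RETAIN_FDR
        )
        results.append(EnrichmentResult(set_id, overlap, size, p, float(q), retained))
    return sorted(results, key=lambda r: r.p_value)
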