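"""Partitioning, alteration matrices, exclusivity and overrepresentation."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmexome.cna import CNState
from lmexome.cohort import (
    build_alteration_matrix,
    cohort_partition_summary,
    compare_alteration_rates,
    enrichment_gene_list,
    mutual_exclusivity,
    overrepresentation_test,
    partition_variants,
    select_driver_genes,
)
from lmexome.core import VariantKey

import oracles


def keys(*positions):
    return {VariantKey("chr1", p, "C", "T") for p in positions}


def matrix_from_counts(n_samples: int, altered: dict[str, list[int]]) -> pd.DataFrame:
    samples = [f"s{i}" for i in range(n_samples)]
    m = pd.DataFrame(False, index=sorted(altered), columns=samples)
    for gene, idx in altered.items():
        m.loc[gene, [samples[i] for i in idx]] = True
    return m


class TestPartition:
    def test_basic_partition(self):
        p = partition_variants(keys(1, 2, 3), keys(2, 3, 4))
        assert (p.n_unique_a, p.n_unique_b, p.n_shared) == (1, 1, 2)
        assert p.frac_unique_a == pytest.approx(0.25)
        assert p.frac_shared == pytest.approx(0.50)

    def test_identical_sets_fully_shared(self):
        p = partition_variants(keys(1, 2), keys(1, 2))
        assert p.frac_shared == 1.0

    def test_disjoint_sets(self):
        p = partition_variants(keys(1, 2, 3), keys(9))
        assert p.frac_unique_a == pytest.approx(0.75)
        assert p.frac_unique_b == pytest.approx(0.25)
        assert p.frac_shared == 0.0

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            partition_variants(set(), set())

    @given(
        a=st.sets(st.integers(1, 40), min_size=0, max_size=20),
        b=st.sets(st.integers(1, 40), min_size=1, max_size=20),
    )
    @settings(max_examples=100)
    def test_fractions_sum_to_one_and_swap_symmetry(self, a, b):
        ka, kb = keys(*a), keys(*b)
        p = partition_variants(ka, kb)
        assert p.frac_unique_a + p.frac_unique_b + p.frac_shared == pytest.approx(1.0)
        q = partition_variants(kb, ka)
        assert (q.n_unique_a, q.n_unique_b, q.n_shared) == (p.n_unique_b, p.n_unique_a, p.n_shared)

    def test_summary_recovers_planted_medians(self):
        """17 pairs with planted unique-A fractions: the summary median is
        the planted median."""
        planted = np.linspace(0.1, 0.9, 17)
        partitions = []
        for frac in planted:
            n_a = int(round(frac * 100))
            partitions.append(
                partition_variants(
                    keys(*range(1, 1 + n_a)) | keys(*range(1000, 1040)),
                    keys(*range(1000, 1040)) | keys(*range(2000, 2000 + 100 - n_a - 40)),
                )
            )
        summary = cohort_partition_summary(partitions)
        expected = np.median([p.frac_unique_a for p in partitions])
        assert summary.loc["unique_a", "median"] == pytest.approx(expected)
        assert summary.loc["unique_a", "median"] == pytest.approx(np.median(planted), abs=0.01)

    def test_summary_median_small(self):
        parts = [
            partition_variants(keys(*range(1, 1 + u)), keys(*range(100, 110)))
            for u in (1, 2, 3)
        ]
        summary = cohort_partition_summary(parts)
        assert summary.loc["unique_a", "median"] == pytest.approx(2 / 12)


class TestAlterationMatrix:
    def test_alteration_definition(self):
        m = build_alteration_matrix(
            nonsilent_genes={"s1": {"MUT"}, "s2": set()},
            gene_states={
                "s1": {"MUT": CNState.NEUTRAL, "GAINED": CNState.GAIN, "DEL": CNState.DELETION},
                "s2": {"MUT": CNState.NEUTRAL, "GAINED": CNState.AMPLIFICATION, "DEL": CNState.LOSS},
            },
        )
        assert bool(m.loc["MUT", "s1"]) and not m.loc["MUT", "s2"]
        assert not m.loc["GAINED", "s1"]  # gain is not high-level
        assert bool(m.loc["GAINED", "s2"])  # amplification is
        assert bool(m.loc["DEL", "s1"]) and not m.loc["DEL", "s2"]  # shallow loss is not

    def test_unknown_mutated_gene_added(self):
        m = build_alteration_matrix(
            nonsilent_genes={"s1": {"NOVEL"}},
            gene_states={"s1": {"KNOWN": CNState.NEUTRAL}},
        )
        assert bool(m.loc["NOVEL", "s1"])


class TestDriverSelection:
    def test_threshold_rules(self):
        m = matrix_from_counts(
            21,
            {
                "CGC4": list(range(4)),
                "CGC3": list(range(3)),
                "BC3": list(range(3)),
                "BC2": list(range(2)),
                "NEITHER9": list(range(9)),
            },
        )
        selected = select_driver_genes(
            m, cgc={"CGC4", "CGC3", "NEITHER_ABSENT"}, bc_drivers={"BC3", "BC2"}
        )
        assert set(selected) == {"CGC4", "BC3"}

    def test_monotone_in_count_thresholds(self):
        m = matrix_from_counts(21, {f"G{i}": list(range(i)) for i in range(1, 10)})
        cgc = {f"G{i}" for i in range(1, 10)}
        prev = None
        for min_cases in range(1, 8):
            sel = set(select_driver_genes(m, cgc, set(), min_cgc_cases=min_cases))
            if prev is not None:
                assert sel <= prev
            prev = sel


class TestExternalRates:
    def test_rate_comparison_against_fisher_oracle(self):
        m = matrix_from_counts(21, {"CDH1": list(range(11))})
        df = compare_alteration_rates(m, {"CDH1": (11, 216)})
        # small expected counts: Fisher branch
        expected = oracles.fisher_two_sided((11, 10, 11, 205))
        assert df.iloc[0]["p_value"] == pytest.approx(expected, rel=1e-9)
        assert bool(df.iloc[0]["significant"]) == (expected <= 0.05)

    def test_zero_rates_not_significant(self):
        m = matrix_from_counts(21, {"G": []})
        df = compare_alteration_rates(m, {"G": (0, 216)})
        assert df.iloc[0]["p_value"] == 1.0
        assert not df.iloc[0]["significant"]

    def test_missing_external_gene_skipped(self):
        m = matrix_from_counts(5, {"A": [0], "B": [1]})
        df = compare_alteration_rates(m, {"A": (1, 100)})
        assert list(df["gene"]) == ["A"]


class TestMutualExclusivity:
    def test_zero_overlap_closed_form(self):
        """Disjoint alteration sets of sizes 11 and 4 in 21 samples: the
        two-sided p is the closed-form hypergeometric value 210/5985."""
        m = matrix_from_counts(21, {"A": list(range(11)), "B": list(range(11, 15))})
        p, table = mutual_exclusivity(m, "A", "B")
        assert table == (0, 11, 4, 6)
        assert p == pytest.approx(210 / 5985, rel=1e-9)

    def test_full_cooccurrence_table(self):
        m = matrix_from_counts(21, {"A": list(range(4)), "B": list(range(4))})
        p, table = mutual_exclusivity(m, "A", "B")
        assert table == (4, 0, 0, 17)
        assert p == pytest.approx(oracles.fisher_two_sided((4, 0, 0, 17)), rel=1e-9)

    def test_degenerate_margin_p_one(self, caplog):
        m = matrix_from_counts(10, {"A": list(range(10)), "B": [0, 1]})
        with caplog.at_level("WARNING"):
            p, _ = mutual_exclusivity(m, "A", "B")
        assert p == 1.0

    @pytest.mark.parametrize("n", [8, 13, 21])
    def test_matches_enumeration_oracle_all_margins(self, n):
        """Fisher two-sided p equals brute-force enumeration for every
        margin combination at cohort size n."""
        for ka, kb in itertools.product(range(1, n), repeat=2):
            for both in range(max(0, ka + kb - n), min(ka, kb) + 1):
                m = matrix_from_counts(
                    n,
                    {
                        "A": list(range(ka)),
                        "B": list(range(both)) + list(range(ka, ka + kb - both)),
                    },
                )
                p, table = mutual_exclusivity(m, "A", "B")
                assert p == pytest.approx(oracles.fisher_two_sided(table), rel=1e-8), table


class TestEnrichmentList:
    def test_threshold_rules(self):
        focal = matrix_from_counts(21, {"IN": range(4), "TOO_FEW": range(3), "TISSUE_HOT": range(5)})
        tissue = matrix_from_counts(21, {"IN": range(2), "TOO_FEW": [], "TISSUE_HOT": range(3)})
        out = enrichment_gene_list(focal, tissue, min_focal=4, max_tissue=2)
        assert out == ["IN"]

    def test_gene_absent_from_tissue_counts_zero(self):
        focal = matrix_from_counts(11, {"ONLY_FOCAL": range(3)})
        tissue = matrix_from_counts(21, {"OTHER": range(5)})
        assert enrichment_gene_list(focal, tissue, 3, 2) == ["ONLY_FOCAL"]

    def test_monotone_in_thresholds(self):
        focal = matrix_from_counts(21, {f"G{i}": range(i) for i in range(8)})
        tissue = matrix_from_counts(21, {f"G{i}": range(i // 2) for i in range(8)})
        prev = None
        for min_focal in range(1, 6):
            sel = set(enrichment_gene_list(focal, tissue, min_focal, 2))
            if prev is not None:
                assert sel <= prev
            prev = sel


class TestOverrepresentation:
    background = {f"G{i}" for i in range(1000)}

    def test_perfect_overlap_tiny_p_retained(self):
        gene_list = [f"G{i}" for i in range(10)]
        sets = {"HIT": set(gene_list), "COLD": {f"G{i}" for i in range(500, 520)}}
        results = overrepresentation_test(gene_list, sets, self.background)
        hit = next(r for r in results if r.set_id == "HIT")
        assert hit.p_value == pytest.approx(1 / comb(1000, 10), rel=1e-6)
        assert hit.p_value == pytest.approx(
            oracles.fisher_greater((10, 0, 0, 990)), rel=1e-6
        )
        assert hit.retained

    def test_small_set_never_retained(self):
        gene_list = [f"G{i}" for i in range(9)]
        sets = {"SMALL": set(gene_list)}  # size 9 < 10
        (r,) = overrepresentation_test(gene_list, sets, self.background)
        assert r.p_value < 1e-10 and not r.retained

    def test_bh_properties(self):
        rng = np.random.default_rng(5)
        gene_list = [f"G{i}" for i in range(30)]
        sets = {
            f"S{j}": set(rng.choice(sorted(self.background), size=40, replace=False))
            for j in range(20)
        }
        results = overrepresentation_test(gene_list, sets, self.background)
        by_p = sorted(results, key=lambda r: r.p_value)
        for r in results:
            assert r.q_value >= r.p_value - 1e-12
        qs = [r.q_value for r in by_p]
        assert qs == sorted(qs)

    def test_null_retention_rate_controlled(self):
        """Random gene lists almost never clear the -log10 p >= 3 bar."""
        rng = np.random.default_rng(9)
        universe = sorted(self.background)
        sets = {
            f"S{j}": set(rng.choice(universe, size=30, replace=False)) for j in range(15)
        }
        retained = total = 0
        for _ in range(200):
            gene_list = rng.choice(universe, size=25, replace=False)
            for r in overrepresentation_test(list(gene_list), sets, self.background):
                total += 1
                retained += r.retained
        assert retained / total <= 0.05

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation_test([], {"S": {"G1"}}, self.background)

    def test_list_outside_background_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation_test(["NOT_THERE"], {"S": {"G1"}}, self.background)
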