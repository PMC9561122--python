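"""Instrument selection, clumping, regions, proxies, pooling, strength."""

import numpy as np
import pandas as pd
import pytest

from mrtri import (DEFAULT_EXCLUSION_REGIONS, LDLookup, Region,
                   classify_bmi_whr_groups, clump, exclude_regions,
                   f_statistic, find_proxy, pool_mvmr_instruments,
                   select_instruments, variance_explained)
from mrtri.instruments import load_regions

from conftest import make_table


def brute_force_clump(snps, table, ld, r2_max, window_bp):
    """Independent greedy oracle, written directly from the rule statement."""
    info = {r.SNP: (str(r.CHR), int(r.BP), float(r.P))
            for r in table.itertuples()}
    remaining = sorted(snps, key=lambda s: (info[s][2], info[s][0], info[s][1]))
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for s in remaining:
            same_chrom = info[s][0] == info[index][0]
            close = abs(info[s][1] - info[index][1]) <= window_bp
            if same_chrom and close and ld.r2(index, s) >= r2_max:
                continue
            survivors.append(s)
        remaining = survivors
    return sorted(kept, key=lambda s: (info[s][0], info[s][1]))


class TestSelect:
    def test_strict_inequality_at_threshold(self):
        t = make_table(["rs1", "rs2", "rs3"], p=[1e-9, 5e-8, 1e-7])
        assert select_instruments(t, 5e-8) == ["rs1"]

    def test_threshold_one_returns_all(self):
        t = make_table(["rs1", "rs2"], p=[0.4, 0.9])
        assert set(select_instruments(t, 1.0)) == {"rs1", "rs2"}

    def test_empty_result_allowed(self):
        t = make_table(["rs1"], p=[0.5])
        assert select_instruments(t, 5e-8) == []

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            select_instruments(make_table([]))


class TestClump:
    def test_two_snps_in_ld_keep_lower_p(self, ld_from_pairs):
        t = make_table(["rs1", "rs2"], pos=[1_000_000, 1_001_000],
                       p=[1e-10, 1e-9])
        ld = ld_from_pairs([("rs1", "rs2", 0.5)])
        assert clump(["rs1", "rs2"], t, ld) == ["rs1"]

    def test_no_ld_keeps_all(self, ld_from_pairs):
        t = make_table(["rs1", "rs2", "rs3"], p=[1e-10, 1e-9, 1e-8])
        assert clump(["rs1", "rs2", "rs3"], t, ld_from_pairs([])) == \
            ["rs1", "rs2", "rs3"]

    def test_outside_window_not_claimed(self, ld_from_pairs):
        t = make_table(["rs1", "rs2"], pos=[1_000_000, 12_000_000],
                       p=[1e-10, 1e-9])
        ld = ld_from_pairs([("rs1", "rs2", 0.9)])
        assert clump(["rs1", "rs2"], t, ld) == ["rs1", "rs2"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_instances(
            self, seed, ld_from_pairs):
        rng = np.random.default_rng(seed)
        k = 10
        snps = [f"rs{i}" for i in range(k)]
        t = make_table(snps,
                       chrom=[str(c) for c in rng.integers(1, 3, k)],
                       pos=[int(p) for p in
                            rng.integers(1, 30_000_000, k)],
                       p=list(rng.uniform(1e-12, 1e-6, k)))
        pairs = [(snps[i], snps[j], float(rng.uniform(0, 1)))
                 for i in range(k) for j in range(i + 1, k)
                 if rng.uniform() < 0.4]
        ld = ld_from_pairs(pairs)
        assert clump(snps, t, ld, 0.1, 5_000_000) == \
            brute_force_clump(snps, t, ld, 0.1, 5_000_000)

    def test_row_order_invariance(self, ld_from_pairs):
        t = make_table(["rs1", "rs2", "rs3"], pos=[1, 1000, 2000],
                       p=[1e-9, 1e-10, 1e-8])
        ld = ld_from_pairs([("rs1", "rs2", 0.9), ("rs2", "rs3", 0.9)])
        a = clump(["rs1", "rs2", "rs3"], t, ld, 0.1)
        b = clump(["rs3", "rs1", "rs2"], t, ld, 0.1)
        assert a == b == ["rs2"]


class TestRegions:
    def test_snp_inside_hla_removed(self):
        t = make_table(["rs1"], chrom=["6"], pos=[29_000_000])
        assert exclude_regions(["rs1"], t) == []

    def test_boundary_one_below_start_retained(self):
        t = make_table(["rs1"], chrom=["6"], pos=[28_909_036])
        assert exclude_regions(["rs1"], t) == ["rs1"]

    def test_boundary_endpoints_inclusive(self):
        t = make_table(["rs1", "rs2"], chrom=["19", "19"],
                       pos=[44_409_011, 46_412_650])
        assert exclude_regions(["rs1", "rs2"], t) == []

    def test_empty_region_list_is_identity(self):
        t = make_table(["rs1"], chrom=["6"], pos=[29_000_000])
        assert exclude_regions(["rs1"], t, regions=()) == ["rs1"]

    def test_shipped_default_file_matches_constants(self):
        assert load_regions() == DEFAULT_EXCLUSION_REGIONS

    def test_commutes_with_clump_when_no_ld(self, ld_from_pairs):
        snps = ["rs1", "rs2", "rs3"]
        t = make_table(snps, chrom=["6", "2", "9"],
                       pos=[29_000_000, 5_000, 136_000_000],
                       p=[1e-9, 1e-10, 1e-8])
        ld = ld_from_pairs([])
        a = exclude_regions(clump(snps, t, ld), t)
        b = clump(exclude_regions(snps, t), t, ld)
        assert a == b == ["rs2"]

    def test_region_start_after_end_rejected(self):
        with pytest.raises(ValueError):
            Region("1", 10, 5)


class TestProxy:
    def test_highest_r2_wins(self, ld_from_pairs):
        target = make_table(["rs2", "rs3"])
        ld = ld_from_pairs([("rs1", "rs2", 0.7), ("rs1", "rs3", 0.9)])
        assert find_proxy("rs1", target, ld) == "rs3"

    def test_boundary_r2_exactly_at_threshold_excluded(self, ld_from_pairs):
        target = make_table(["rs2"])
        ld = ld_from_pairs([("rs1", "rs2", 0.6)])
        assert find_proxy("rs1", target, ld) is None

    def test_no_ld_records_gives_none(self, ld_from_pairs):
        assert find_proxy("rs1", make_table(["rs2"]), ld_from_pairs([])) is None


class TestPooling:
    def test_disjoint_sets_no_ld_union(self, ld_from_pairs):
        t1 = make_table(["rs1", "rs2", "rs3"], trait="e1",
                        p=[1e-10, 1e-9, 0.5])
        t2 = make_table(["rs1", "rs2", "rs3"], trait="e2",
                        p=[0.5, 0.5, 1e-12])
        out = pool_mvmr_instruments([t1, t2], ld_from_pairs([]))
        assert set(out) == {"rs1", "rs2", "rs3"}

    def test_min_p_across_prefers_other_exposures_best_snp(self, ld_from_pairs):
        # a and b in LD; a is best for exposure 2, b best for exposure 1
        t1 = make_table(["a", "b"], trait="e1", pos=[100, 200],
                        p=[1e-6, 1e-10])
        t2 = make_table(["a", "b"], trait="e2", pos=[100, 200],
                        p=[1e-20, 1e-5])
        ld = ld_from_pairs([("a", "b", 0.9)])
        out = pool_mvmr_instruments([t1, t2], ld, p_threshold=1e-7)
        assert out == ["a"]

    def test_fixed_exposure_priority_flips_retained_snp(self, ld_from_pairs):
        t1 = make_table(["a", "b"], trait="e1", pos=[100, 200],
                        p=[1e-6, 1e-10])
        t2 = make_table(["a", "b"], trait="e2", pos=[100, 200],
                        p=[1e-20, 1e-5])
        ld = ld_from_pairs([("a", "b", 0.9)])
        out = pool_mvmr_instruments([t1, t2], ld, p_threshold=1e-7,
                                    priority="e1")
        assert out == ["b"]

    def test_unknown_fixed_exposure_errors(self, ld_from_pairs):
        t1 = make_table(["a"], trait="e1")
        t2 = make_table(["a"], trait="e2")
        with pytest.raises(ValueError, match="priority"):
            pool_mvmr_instruments([t1, t2], ld_from_pairs([]), priority="zz")


class TestClassifyGroups:
    def test_three_way_classification(self):
        snps = ["rs1", "rs2", "rs3"]
        bmi = make_table(snps, trait="bmi", beta=[0.1, 0.1, 0.1],
                         p=[1e-4, 1e-4, 1e-4])
        whr = make_table(snps, trait="whr", beta=[0.05, -0.05, 0.02],
                         p=[0.01, 0.01, 0.5])
        g = classify_bmi_whr_groups(snps, bmi, whr)
        assert g == {"bmi+whr+": ["rs1"], "bmi+whr-": ["rs2"],
                     "bmi_only": ["rs3"]}

    def test_negative_bmi_beta_reorients_whr(self):
        bmi = make_table(["rs1"], trait="bmi", beta=[-0.1])
        whr = make_table(["rs1"], trait="whr", beta=[0.05], p=[0.01])
        g = classify_bmi_whr_groups(["rs1"], bmi, whr)
        assert g["bmi+whr-"] == ["rs1"]

    def test_groups_partition_input(self):
        rng = np.random.default_rng(0)
        snps = [f"rs{i}" for i in range(30)]
        bmi = make_table(snps, trait="bmi",
                         beta=list(rng.normal(size=30)))
        whr = make_table(snps, trait="whr",
                         beta=list(rng.normal(size=30)),
                         p=list(rng.uniform(size=30)))
        g = classify_bmi_whr_groups(snps, bmi, whr)
        combined = g["bmi+whr+"] + g["bmi+whr-"] + g["bmi_only"]
        assert sorted(combined) == sorted(snps)

    def test_missing_snp_errors(self):
        bmi = make_table(["rs1"], trait="bmi")
        whr = make_table(["rs2"], trait="whr")
        with pytest.raises(ValueError, match="missing"):
            classify_bmi_whr_groups(["rs1"], bmi, whr)


class TestStrength:
    def test_continuous_r2_direct_arithmetic(self):
        assert variance_explained(0.1, 0.5) == pytest.approx(0.005)

    def test_zero_beta_zero_r2(self):
        assert variance_explained(0.0, 0.3) == 0.0

    def test_binary_r2_monotone_in_log_or(self):
        vals = [variance_explained(b, 0.3, "binary", prevalence=0.1)
                for b in (0.1, 0.2, 0.4)]
        assert vals[0] < vals[1] < vals[2]
        assert variance_explained(0.0, 0.3, "binary", prevalence=0.1) == 0.0

    def test_binary_requires_prevalence(self):
        with pytest.raises(ValueError, match="prevalence"):
            variance_explained(0.1, 0.3, "binary")

    def test_f_formula_collapses_at_r2_half(self):
        assert f_statistic(102, 1, 0.5) == pytest.approx(100.0)

    def test_f_zero_r2(self):
        assert f_statistic(1000, 10, 0.0) == 0.0

    def test_f_at_study_scale_inputs(self):
        # ((462166-370-1)/370) * (0.05/0.95)
        assert f_statistic(462_166, 370, 0.05) == pytest.approx(65.689,
                                                                abs=0.01)

    def test_f_requires_n_above_k_plus_one(self):
        with pytest.raises(ValueError):
            f_statistic(10, 9, 0.1)

    def test_f_monotone_in_r2_and_n(self):
        assert f_statistic(1000, 10, 0.2) > f_statistic(1000, 10, 0.1)
        assert f_statistic(2000, 10, 0.1) > f_statistic(1000, 10, 0.1)
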