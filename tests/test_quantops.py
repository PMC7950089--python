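"""Quantitative filters, normalization, partitioning and differential ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prosal import quantops, syndata
from prosal.formats import GROUP_NEGATIVE, GROUP_POSITIVE
from prosal.quantops import (
    differential_anova,
    exclusivity_partition,
    filter_quality,
    filter_valid_values,
    mean_log2_shift,
    normalize_intensities,
    proteomics_clean,
)

from conftest import make_quant, random_quant


class TestFilters:
    def test_quality_boundary_keeps_at_threshold(self, two_group_map):
        table = make_quant(
            {f"p{i}": {s: 1.0 for s in two_group_map} for i in range(3)},
            two_group_map, quality={"p0": 7.9, "p1": 8.0, "p2": 12.0})
        out = filter_quality(table, 8.0)
        assert list(out.data.index) == ["p1", "p2"]

    def test_quality_threshold_zero_is_identity(self, two_group_map):
        table = random_quant(40, two_group_map, seed=1)
        assert filter_quality(table, 0.0).data.equals(table.data)

    def test_all_missing_in_one_group_removed(self, two_group_map):
        rows = {"gone": {s: (None if g == GROUP_NEGATIVE else 1.0)
                         for s, g in two_group_map.items()},
                "kept": {"A1": 1.0, "B1": 1.0,
                         **{s: None for s in two_group_map
                            if s not in ("A1", "B1")}}}
        out = filter_valid_values(make_quant(rows, two_group_map), 1)
        assert list(out.data.index) == ["kept"]

    def test_filter_decisions_match_brute_force_recount(self, two_group_map):
        table = random_quant(500, two_group_map, seed=7, missing_rate=0.4)
        out = filter_valid_values(table, 2)
        for pid, row in table.data.iterrows():
            counts = {GROUP_NEGATIVE: 0, GROUP_POSITIVE: 0}
            for s, g in two_group_map.items():
                if not pd.isna(row[s]):
                    counts[g] += 1
            expected = all(c >= 2 for c in counts.values())
            assert (pid in out.data.index) == expected

    def test_filters_commute_and_are_idempotent(self, two_group_map):
        table = random_quant(200, two_group_map, seed=3, missing_rate=0.5)
        qv = filter_valid_values(filter_quality(table, 8), 1)
        vq = filter_quality(filter_valid_values(table, 1), 8)
        assert qv.data.equals(vq.data)
        assert filter_quality(qv, 8).data.equals(qv.data)
        assert filter_valid_values(qv, 1).data.equals(qv.data)

    def test_planted_low_quality_fraction_survives(self):
        cfg = syndata.SyntheticConfig(frac_low_quality=0.3, seed=12)
        peptides = [syndata.PlantedPeptide(f"p{i}", "AAAAK", "X", 1, 5, None)
                    for i in range(1000)]
        quant, _, _ = syndata.simulate_quant(peptides, cfg)
        kept = len(filter_quality(quant, 8.0)) / 1000
        assert abs(kept - 0.7) < 3 * np.sqrt(0.3 * 0.7 / 1000)


class TestNormalization:
    def test_single_sample_identity_up_to_scale(self):
        gm = {"A1": GROUP_NEGATIVE, "A2": GROUP_NEGATIVE}
        table = make_quant({f"p{i}": {"A1": float(i + 1), "A2": float(i + 1)}
                            for i in range(5)}, gm)
        out = normalize_intensities(table)
        ratio = out.data["A1"] / table.data["A1"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_medians_equal_after_normalization(self, two_group_map):
        table = random_quant(80, two_group_map, seed=5)
        out = normalize_intensities(table, "median")
        medians = out.intensities.median(axis=0, skipna=True)
        assert np.allclose(medians, medians.iloc[0])

    def test_doubled_sample_gets_half_the_scale(self):
        gm = {"S1": GROUP_NEGATIVE, "S2": GROUP_POSITIVE}
        base = {f"p{i}": {"S1": float(i + 1), "S2": 2.0 * (i + 1)}
                for i in range(9)}
        out = normalize_intensities(make_quant(base, gm))
        f1 = out.data["S1"].iloc[0] / base["p0"]["S1"]
        f2 = out.data["S2"].iloc[0] / base["p0"]["S2"]
        assert f2 / f1 == pytest.approx(0.5)

    def test_sample_without_values_rejected(self):
        gm = {"S1": GROUP_NEGATIVE, "S2": GROUP_POSITIVE}
        table = make_quant({"p0": {"S1": 1.0, "S2": None}}, gm)
        with pytest.raises(ValueError, match="S2"):
            normalize_intensities(table)

    def test_missing_cells_stay_missing(self, two_group_map):
        table = random_quant(50, two_group_map, seed=8, missing_rate=0.3)
        out = normalize_intensities(table)
        assert out.intensities.isna().equals(table.intensities.isna())


class TestExclusivity:
    def test_small_hand_partition(self, two_group_map):
        rows = {}
        for i in range(2):
            rows[f"a{i}"] = {s: (1.0 if g == GROUP_NEGATIVE else None)
                             for s, g in two_group_map.items()}
        rows["b0"] = {s: (1.0 if g == GROUP_POSITIVE else None)
                      for s, g in two_group_map.items()}
        for i in range(3):
            rows[f"s{i}"] = {s: 1.0 for s in two_group_map}
        part = exclusivity_partition(make_quant(rows, two_group_map))
        counts = part.counts()
        assert (counts["exclusive_pN0"], counts["exclusive_pN+"],
                counts["shared"], counts["total"]) == (2, 1, 3, 6)

    def test_partition_matches_per_row_scan(self, two_group_map):
        table = random_quant(200, two_group_map, seed=9, missing_rate=0.6)
        part = exclusivity_partition(table)
        neg_cols = table.samples_in(GROUP_NEGATIVE)
        pos_cols = table.samples_in(GROUP_POSITIVE)
        scan = {"neg": set(), "pos": set(), "shared": set()}
        for pid, row in table.data.iterrows():
            has_neg = row[neg_cols].notna().any()
            has_pos = row[pos_cols].notna().any()
            if has_neg and has_pos:
                scan["shared"].add(pid)
            elif has_neg:
                scan["neg"].add(pid)
            elif has_pos:
                scan["pos"].add(pid)
        assert set(part.exclusive_negative) == scan["neg"]
        assert set(part.exclusive_positive) == scan["pos"]
        assert set(part.shared) == scan["shared"]
        n_detected = sum(len(v) for v in scan.values())
        assert part.total == n_detected


class TestDifferentialAnova:
    def test_identical_groups_give_p_one_and_zero_fc(self, two_group_map):
        table = make_quant({"p0": {s: 100.0 for s in two_group_map}},
                           two_group_map)
        out = differential_anova(table)
        assert out.at["p0", "p_value"] == 1.0
        assert out.at["p0", "log2fc"] == 0.0
        assert bool(out.at["p0", "degenerate"])

    def test_f_equals_squared_t_on_random_rows(self, two_group_map):
        table = random_quant(50, two_group_map, seed=10, missing_rate=0.0)
        out = differential_anova(table, log_transform=True)
        log2 = np.log2(table.intensities + 1.0)
        neg = table.samples_in(GROUP_NEGATIVE)
        pos = table.samples_in(GROUP_POSITIVE)
        for pid in table.data.index:
            t = stats.ttest_ind(log2.loc[pid, neg], log2.loc[pid, pos])
            f_from_t = t.statistic ** 2
            f = stats.f_oneway(log2.loc[pid, neg], log2.loc[pid, pos]).statistic
            assert f == pytest.approx(f_from_t, rel=1e-9)
            assert out.at[pid, "p_value"] == pytest.approx(t.pvalue, rel=1e-9)

    def test_insufficient_rows_reported_untested(self, two_group_map):
        rows = {"thin": {"A1": 1.0, "B1": 2.0, "B2": 3.0,
                         **{s: None for s in two_group_map
                            if s not in ("A1", "B1", "B2")}}}
        out = differential_anova(make_quant(rows, two_group_map))
        assert not out.at["thin", "tested"]
        assert not out.at["thin", "significant"]

    def test_p_values_invariant_to_per_sample_scaling(self, two_group_map):
        table = random_quant(40, two_group_map, seed=11, missing_rate=0.0)
        rng = np.random.default_rng(0)
        scaled_data = table.data.copy()
        for s in table.samples:
            scaled_data[s] = scaled_data[s] * rng.uniform(0.5, 2.0)
        scaled = table.with_data(scaled_data)
        p_ref = differential_anova(normalize_intensities(table))["p_value"]
        p_scaled = differential_anova(normalize_intensities(scaled))["p_value"]
        assert np.allclose(p_ref, p_scaled, rtol=1e-3)

    def test_bh_adjustment_is_optional_extra(self, two_group_map):
        table = random_quant(30, two_group_map, seed=13, missing_rate=0.0)
        plain = differential_anova(table)
        adjusted = differential_anova(table, adjust="bh")
        assert "q_value" not in plain.columns
        assert (adjusted["q_value"] >= adjusted["p_value"] - 1e-12).all()


class TestProteinOps:
    def test_reverse_and_site_only_rows_removed(self):
        table = syndata.simulate_protein_table(seed=1)
        clean = proteomics_clean(table)
        flagged = table.data["is_reverse"] | table.data["only_by_site"]
        assert len(clean) == int((~flagged).sum())
        assert not (clean.data["is_reverse"] | clean.data["only_by_site"]).any()

    def test_class_of_halved_ratios_has_minus_one_shift(self):
        gm = {"N1": GROUP_NEGATIVE, "N2": GROUP_NEGATIVE,
              "P1": GROUP_POSITIVE, "P2": GROUP_POSITIVE}
        rows = []
        for i in range(4):
            base = 1000.0 * (i + 1)
            rows.append([False, False, "protease_inhibitor",
                         base, base, base / 2, base / 2])
        data = pd.DataFrame(
            rows, columns=["is_reverse", "only_by_site", "class_tag",
                           "N1", "N2", "P1", "P2"],
            index=pd.Index([f"I{i}" for i in range(4)], name="accession"))
        table = quantops.ProteinQuantTable(data=data, group_map=gm)
        mean_shift, per_protein = mean_log2_shift(table, "protease_inhibitor")
        assert mean_shift == pytest.approx(-1.0, abs=2e-3)  # log2 pseudocount

    def test_planted_inhibitor_shift_recovered(self):
        table = syndata.simulate_protein_table(
            n_inhibitors=32, inhibitor_shift=-0.8, seed=21)
        clean = proteomics_clean(table)
        mean_shift, per_protein = mean_log2_shift(clean, "protease_inhibitor")
        assert len(per_protein) == 32
        assert mean_shift == pytest.approx(-0.8, abs=0.15)

    def test_empty_class_rejected(self):
        table = syndata.simulate_protein_table(n_other=0, n_reverse=0,
                                               n_only_by_site=0, seed=2)
        with pytest.raises(ValueError, match="other"):
            mean_log2_shift(table, "other")
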