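"""Clinical association cascade and ROC classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from prosal import clinstats, syndata
from prosal.clinstats import (
    correlate_clinical,
    delong_ci,
    detection_rate_filter,
    permutation_auc,
    roc_panel,
    roc_single,
)
from prosal.formats import ClinicalTable, GROUP_NEGATIVE, GROUP_POSITIVE

from conftest import make_quant, random_quant


def clinical_for(group_map: dict, **features) -> ClinicalTable:
    data = pd.DataFrame({"group": pd.Series(group_map)})
    data.index.name = "sample_id"
    for name, values in features.items():
        data[name] = pd.Series(values)
    return ClinicalTable(data=data)


class TestCorrelateClinical:
    def test_exact_linear_relation_passes_both_filters(self):
        gm = {f"A{i}": GROUP_NEGATIVE for i in range(6)}
        gm.update({f"B{i}": GROUP_POSITIVE for i in range(6)})
        samples = list(gm)
        x = {s: float(i % 4) for i, s in enumerate(samples)}
        # log2 intensity exactly 2x + 5 -> R = 1 on the log scale
        rows = {"p1": {s: 2.0 ** (2.0 * x[s] + 5.0) - 1.0 for s in samples}}
        quant = make_quant(rows, gm)
        clin = clinical_for(gm, stage=x)
        out = correlate_clinical(quant, clin)
        rec = out.iloc[0]
        assert rec["pearson_r"] == pytest.approx(1.0)
        assert rec["r_squared"] == pytest.approx(rec["pearson_r"] ** 2, abs=1e-12)
        assert rec["passes_default"] and rec["passes_stringent"]

    def test_zero_variance_covariate_reported_untestable(self):
        gm = {f"S{i}": (GROUP_NEGATIVE if i < 3 else GROUP_POSITIVE)
              for i in range(6)}
        quant = random_quant(3, gm, seed=0, missing_rate=0.0)
        clin = clinical_for(gm, flat={s: 1.0 for s in gm})
        out = correlate_clinical(quant, clin)
        assert (~out["testable"]).all()

    def test_null_covariate_yields_no_passes(self):
        cfg = syndata.SyntheticConfig(
            seed=41, frac_differential=0.0, missing_rate=0.0,
            clinical_features=[syndata.ClinicalFeatureSpec(
                "noise", "binary", 0, 0.0)])
        peptides = [syndata.PlantedPeptide(f"p{i}", "AAAAK", "X", 1, 5, None)
                    for i in range(200)]
        quant, clin, _ = syndata.simulate_quant(peptides, cfg)
        out = correlate_clinical(quant, clin)
        assert out["passes_default"].sum() == 0

    def test_planted_correlation_flagged_stringent_in_most_seeds(self):
        """Latent-linked covariate at target R=0.9 is recovered reliably."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = syndata.SyntheticConfig(
                seed=seed, frac_differential=0.0,
                clinical_features=[syndata.ClinicalFeatureSpec(
                    "perineural_invasion", "binary", 1, 0.9)])
            peptides = [syndata.PlantedPeptide(f"p{i}", "AAAAK", "X", 1, 5,
                                               None) for i in range(40)]
            quant, clin, truth = syndata.simulate_quant(peptides, cfg)
            out = correlate_clinical(quant, clin)
            linked = truth.clinical_links["perineural_invasion"]
            sub = out[out["feature_id"].isin(linked)
                      & (out["clinical_feature"] == "perineural_invasion")]
            hits += int(sub["passes_stringent"].any())
        assert hits >= 0.8 * n_seeds


class TestDetectionRateFilter:
    def test_fully_detected_feature_retained(self):
        gm = {f"A{i}": GROUP_NEGATIVE for i in range(12)}
        gm.update({f"B{i}": GROUP_POSITIVE for i in range(13)})
        quant = make_quant({"p1": {s: 1.0 for s in gm}}, gm)
        assert detection_rate_filter(quant) == ["p1"]

    def test_83_percent_in_one_group_removed(self):
        gm = {f"A{i}": GROUP_NEGATIVE for i in range(12)}
        gm.update({f"B{i}": GROUP_POSITIVE for i in range(13)})
        rows = {"p1": {s: (None if s in ("A0", "A1") else 1.0) for s in gm}}
        assert detection_rate_filter(make_quant(rows, gm)) == []

    def test_recount_oracle_agrees(self):
        gm = {f"A{i}": GROUP_NEGATIVE for i in range(8)}
        gm.update({f"B{i}": GROUP_POSITIVE for i in range(8)})
        quant = random_quant(300, gm, seed=3, missing_rate=0.15)
        kept = set(detection_rate_filter(quant, 0.85))
        for pid, row in quant.data.iterrows():
            rates = []
            for g in (GROUP_NEGATIVE, GROUP_POSITIVE):
                cols = quant.samples_in(g)
                rates.append(sum(not pd.isna(row[s]) for s in cols) / len(cols))
            assert (pid in kept) == all(r >= 0.85 for r in rates)


class TestRocSingle:
    def test_perfect_separation_gives_auc_one(self):
        x = np.array([1, 2, 3, 10, 11, 12], float)
        y = np.array([0, 0, 0, 1, 1, 1])
        rec = roc_single(x, y)
        assert rec.auc == pytest.approx(1.0)

    def test_hand_counted_pairwise_concordance(self):
        x = np.array([1, 3, 2, 4], float)
        y = np.array([0, 0, 1, 1])
        rec = roc_single(x, y)
        assert rec.auc == pytest.approx(0.75)  # 3 of 4 concordant pairs

    def test_logistic_auc_equals_rank_statistic(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            x = rng.normal(size=24)
            y = rng.integers(0, 2, size=24)
            if len(np.unique(y)) < 2:
                continue
            rec = roc_single(x, y, method="logistic")
            u = stats.mannwhitneyu(x[y == 1], x[y == 0]).statistic
            auc_rank = u / ((y == 1).sum() * (y == 0).sum())
            slope = rec.coefficients["feature"]
            expected = auc_rank if slope >= 0 else 1.0 - auc_rank
            assert rec.auc == pytest.approx(expected, abs=1e-9)

    def test_constant_feature_is_degenerate(self):
        rec = roc_single(np.ones(10), np.array([0] * 5 + [1] * 5))
        assert rec.degenerate and rec.auc == 0.5

    def test_random_forest_recovers_strong_signal(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 15), rng.normal(3, 1, 15)])
        y = np.array([0] * 15 + [1] * 15)
        rec = roc_single(x, y, method="random_forest", seed=1,
                         n_bootstrap=200)
        assert rec.auc > 0.85
        assert rec.ci_low <= rec.auc <= rec.ci_high

    def test_cutoff_respects_specificity_floor(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(1.5, 1, 20)])
        y = np.array([0] * 20 + [1] * 20)
        rec = roc_single(x, y)
        assert rec.specificity >= 0.70

    def test_delong_interval_contains_auc(self):
        rng = np.random.default_rng(13)
        scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        labels = np.array([0] * 30 + [1] * 30)
        auc, lo, hi = delong_ci(scores, labels)
        assert lo <= auc <= hi
        assert auc == pytest.approx(roc_auc_score(labels, scores))


class TestRocPanel:
    def test_duplicated_feature_panel_equals_single(self):
        rng = np.random.default_rng(17)
        x = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 15)])
        y = np.array([0] * 15 + [1] * 15)
        single = roc_single(x, y)
        panel = roc_panel(pd.DataFrame({"f1": x, "f2": x}), y)
        assert panel.auc == pytest.approx(single.auc, abs=1e-6)

    def test_panel_improves_on_complementary_features(self):
        """Two features informative on complementary halves of the cohort:
        the panel fit dominates each nested single-feature model in
        likelihood and beats both single AUCs."""
        rng = np.random.default_rng(19)
        n = 40
        y = np.array([0, 1] * (n // 2))
        half = np.arange(n) < n // 2
        f1 = np.where(half, y * 2.0, 0.0) + rng.normal(0, 0.7, n)
        f2 = np.where(~half, y * 2.0, 0.0) + rng.normal(0, 0.7, n)
        frame = pd.DataFrame({"f1": f1, "f2": f2})
        panel = roc_panel(frame, y)
        singles = [roc_single(f, y).auc for f in (f1, f2)]
        assert panel.auc > max(singles)

        def loglik(X):
            prob, _, _ = clinstats._fit_logistic(X, y)
            prob = np.clip(prob, 1e-12, 1 - 1e-12)
            return float(np.sum(y * np.log(prob)
                                + (1 - y) * np.log(1 - prob)))

        ll_panel = loglik(frame.to_numpy())
        for f in (f1, f2):
            assert ll_panel >= loglik(f.reshape(-1, 1)) - 1e-6

    def test_complete_case_rows_dropped(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        f1 = np.array([0, 1, 2, np.nan, 5, 6, 7, 8])
        f2 = np.arange(8, dtype=float)
        panel = roc_panel(pd.DataFrame({"f1": f1, "f2": f2}), y)
        assert panel.n_used == 7

    def test_separation_triggers_flagged_fallback(self):
        y = np.array([0] * 6 + [1] * 6)
        x = np.arange(12, dtype=float)  # perfectly separable
        panel = roc_panel(pd.DataFrame({"f1": x, "f2": x[::-1] * 0 + x}), y)
        assert panel.separation
        assert panel.auc == pytest.approx(1.0)

    def test_calibrated_panel_reaches_target_auc(self):
        X, y = syndata.simulate_panel(target_auc=0.86, seed=0)
        frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        panel = roc_panel(frame, y, seed=0)
        assert panel.auc == pytest.approx(0.86, abs=0.05)


class TestPermutationAuc:
    def test_null_distribution_centered_at_half(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=30)
        y = np.array([0] * 15 + [1] * 15)
        aucs = permutation_auc(x, y, n_permutations=200, seed=0)
        se = aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 3 * se + 1e-3
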