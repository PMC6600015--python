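"""Tests of multi-omic integration and cross-tissue transfer."""

import numpy as np
import pandas as pd
import pytest

from drugsense import (
    CVConfig,
    FeatureMatrix,
    PanelConfig,
    TissuePanel,
    cross_fair_benchmark,
    cross_tissue_transfer,
    early_integration_fit,
    exclude_duplicate_patients,
    generate_panel,
    late_integration_cv,
    late_integration_predict,
    repeated_nested_cv,
    tissue_mean_predictor,
)


@pytest.fixture(scope="module")
def tissue_panel():
    cfg = PanelConfig(
        n_cell_lines=36, n_tissues=2, n_transcripts=60, n_proteins=20,
        n_mutations=15, n_drugs=4, drug_classes=(), n_null_drugs=1,
        n_duplicate_patients=2, tissue_effect_sd=0.05, seed=21,
    )
    return TissuePanel.from_synthetic(generate_panel(cfg))


class TestLateIntegrationFormula:
    def test_equal_rms_is_simple_average(self):
        a = np.array([1.0, 2.0])
        b = np.array([3.0, 4.0])
        out = late_integration_predict([a, b], [0.5, 0.5])
        assert np.allclose(out, [2.0, 3.0])

    def test_inverse_rms_weights(self):
        a = np.array([0.0])
        b = np.array([3.0])
        out = late_integration_predict([a, b], [1.0, 2.0])  # weights 2/3, 1/3
        assert out[0] == pytest.approx(1.0)

    def test_convex_combination_bounds(self, rng):
        preds = [rng.standard_normal(10) for _ in range(3)]
        out = late_integration_predict(preds, [0.3, 0.7, 1.1])
        stacked = np.vstack(preds)
        assert (out >= stacked.min(axis=0) - 1e-12).all()
        assert (out <= stacked.max(axis=0) + 1e-12).all()

    def test_zero_rms_takes_all_weight(self):
        a = np.array([1.0])
        b = np.array([9.0])
        out = late_integration_predict([a, b], [0.0, 1.0])
        assert out[0] == pytest.approx(1.0)

    def test_negative_rms_rejected(self):
        with pytest.raises(ValueError):
            late_integration_predict([np.ones(2)], [-1.0])


class TestEarlyIntegration:
    def test_single_block_reduces_to_plain_cv(self, tissue_panel):
        cv = CVConfig(n_repeats=2, seed=5)
        drug = tissue_panel.auc.columns[0]
        fm = tissue_panel.features["protein"]
        a = early_integration_fit([fm], tissue_panel.auc[drug], "pls", cv, rng_key=3)
        b = repeated_nested_cv(fm, tissue_panel.auc[drug], "pls", cv, rng_key=3)
        pd.testing.assert_series_equal(a.predicted, b.predicted)

    def test_duplicated_block_leaves_predictions_unchanged(self, tissue_panel):
        cv = CVConfig(n_repeats=1, seed=5)
        drug = tissue_panel.auc.columns[0]
        fm = tissue_panel.features["protein"]
        a = early_integration_fit([fm], tissue_panel.auc[drug], "pls", cv, rng_key=3)
        b = early_integration_fit([fm, fm], tissue_panel.auc[drug], "pls", cv,
                                  rng_key=3)
        assert np.allclose(a.predicted, b.predicted, atol=1e-8)

    def test_mismatched_blocks_rejected(self, tissue_panel):
        fm = tissue_panel.features["protein"]
        short = FeatureMatrix(fm.values.iloc[:-2], "protein")
        with pytest.raises(ValueError):
            early_integration_fit([fm, short], tissue_panel.auc.iloc[:, 0], "pls",
                                  CVConfig(n_repeats=1))

    def test_noise_block_does_not_destroy_strong_signal(self, tissue_panel):
        cv = CVConfig(n_repeats=2, seed=5)
        gt_drugs = [c for c in tissue_panel.auc.columns]
        drug = gt_drugs[0]
        fm = tissue_panel.features["protein"]
        rng = np.random.default_rng(0)
        noise = FeatureMatrix(
            pd.DataFrame(
                2.0 ** rng.normal(3, 1, size=(len(fm.values), 10)),
                index=fm.values.index,
                columns=[f"N{i}" for i in range(10)],
            ),
            "protein",
        )
        single = early_integration_fit([fm], tissue_panel.auc[drug], "pls", cv)
        combo = early_integration_fit([fm, noise], tissue_panel.auc[drug], "pls", cv)
        assert combo.rho > single.rho - 0.3


class TestLateIntegrationCV:
    def test_combined_prediction_bounded_by_blocks(self, tissue_panel):
        cv = CVConfig(n_repeats=1, seed=2)
        drug = tissue_panel.auc.columns[0]
        blocks = [tissue_panel.features["protein"], tissue_panel.features["transcript"]]
        res = late_integration_cv(blocks, tissue_panel.auc[drug], "pls", cv)
        assert len(res.predicted) == len(tissue_panel.auc)
        assert np.isfinite(res.rho)


class TestTissueMean:
    def test_leave_one_out_mean(self):
        auc = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        tissues = pd.Series(["t1"] * 3, index=list("abc"))
        pred = tissue_mean_predictor(auc, tissues)
        assert pred["a"] == pytest.approx(2.5)
        assert pred["b"] == pytest.approx(2.0)

    def test_constant_panel(self):
        auc = pd.Series([0.7] * 5, index=list("abcde"))
        tissues = pd.Series(["t1"] * 5, index=list("abcde"))
        assert np.allclose(tissue_mean_predictor(auc, tissues), 0.7)

    def test_two_separated_tissues_rank_perfectly(self):
        auc = pd.Series([0.2, 0.2, 0.2, 0.8, 0.8, 0.8], index=list("abcdef"))
        tissues = pd.Series(["lo"] * 3 + ["hi"] * 3, index=list("abcdef"))
        pred = tissue_mean_predictor(auc, tissues)
        from drugsense import spearman_rho
        assert spearman_rho(auc.to_numpy(), pred.to_numpy()) == pytest.approx(1.0)

    def test_singleton_tissue_flagged_missing(self):
        auc = pd.Series([0.2, 0.4, 0.9], index=list("abc"))
        tissues = pd.Series(["t1", "t1", "solo"], index=list("abc"))
        pred = tissue_mean_predictor(auc, tissues)
        assert np.isnan(pred["c"])

    def test_exact_loo_shift_property(self, rng):
        auc = pd.Series(rng.uniform(0.2, 1.0, 8), index=[f"c{i}" for i in range(8)])
        tissues = pd.Series(["t1"] * 4 + ["t2"] * 4, index=auc.index)
        base = tissue_mean_predictor(auc, tissues)
        shifted = auc.copy()
        shifted.loc[tissues == "t1"] += 0.25
        pred = tissue_mean_predictor(shifted, tissues)
        assert np.allclose(pred[tissues == "t1"], base[tissues == "t1"] + 0.25)
        assert np.allclose(pred[tissues == "t2"], base[tissues == "t2"])


class TestCrossTissueTransfer:
    def test_unknown_or_degenerate_targets_rejected(self, tissue_panel):
        cv = CVConfig(n_repeats=1, seed=0)
        with pytest.raises(ValueError):
            cross_tissue_transfer(tissue_panel, "absent", "pls", cv)

    def test_transfer_runs_and_reports(self, tissue_panel):
        cv = CVConfig(n_repeats=1, seed=0)
        res = cross_tissue_transfer(tissue_panel, "tissue1", "pls", cv,
                                    cv_filter_threshold=None)
        assert set(res.per_drug["drug"]) <= set(tissue_panel.auc.columns)
        assert (res.per_drug["n_test"] >= 3).all()

    def test_cv_filter_drops_low_variability_drugs(self, tissue_panel):
        cv = CVConfig(n_repeats=1, seed=0)
        strict = cross_tissue_transfer(tissue_panel, "tissue1", "pls", cv,
                                       cv_filter_threshold=5.0)
        assert len(strict.per_drug) == 0


class TestCrossFair:
    def test_resamples_deterministic(self, tissue_panel):
        cv = CVConfig(n_repeats=1, seed=0)
        a = cross_fair_benchmark(tissue_panel, "tissue1", "pls", cv, n_resamples=2,
                                 cv_filter_threshold=None)
        b = cross_fair_benchmark(tissue_panel, "tissue1", "pls", cv, n_resamples=2,
                                 cv_filter_threshold=None)
        pd.testing.assert_frame_equal(a, b)

    def test_full_complement_resample_reduces_to_plain_transfer(self):
        # two equal-size tissues: the only possible resample is the entire
        # complement, so cross-fair equals the plain cross-tissue run
        cfg = PanelConfig(
            n_cell_lines=32, n_tissues=2, n_transcripts=40, n_proteins=15,
            n_mutations=10, n_drugs=2, drug_classes=(), n_null_drugs=0,
            n_duplicate_patients=0, seed=13,
        )
        panel = TissuePanel.from_synthetic(generate_panel(cfg))
        sizes = panel.tissues.value_counts()
        assert sizes["tissue1"] == sizes["tissue2"]
        cv = CVConfig(n_repeats=1, seed=0)
        plain = cross_tissue_transfer(panel, "tissue1", "pls", cv,
                                      cv_filter_threshold=None)
        fair = cross_fair_benchmark(panel, "tissue1", "pls", cv, n_resamples=1,
                                    cv_filter_threshold=None)
        merged = plain.per_drug.merge(fair, on="drug")
        assert np.allclose(merged["rho"], merged["mean_rho"], atol=1e-10)

    def test_complement_too_small_rejected(self):
        cfg = PanelConfig(
            n_cell_lines=20, n_tissues=2, n_transcripts=40, n_proteins=15,
            n_mutations=10, n_drugs=2, drug_classes=(), n_null_drugs=0,
            n_duplicate_patients=0, seed=13,
        )
        panel = TissuePanel.from_synthetic(generate_panel(cfg))
        # shrink the complement below the target size
        small = TissuePanel(
            features={
                k: FeatureMatrix(
                    fm.values.drop(fm.values.index[:8]), fm.data_type
                )
                for k, fm in panel.features.items()
            },
            auc=panel.auc.drop(panel.auc.index[:8]),
            tissues=panel.tissues.drop(panel.tissues.index[:8]),
            patients=panel.patients.drop(panel.patients.index[:8]),
        )
        target = small.tissues.value_counts().idxmax()
        with pytest.raises(ValueError):
            cross_fair_benchmark(small, target, "pls", CVConfig(n_repeats=1),
                                 n_resamples=1, cv_filter_threshold=None)


class TestExcludeDuplicates:
    def test_all_distinct_is_identity(self, tissue_panel):
        unique = exclude_duplicate_patients(exclude_duplicate_patients(tissue_panel))
        again = exclude_duplicate_patients(unique)
        assert list(again.auc.index) == list(unique.auc.index)

    def test_one_line_kept_per_patient(self, tissue_panel):
        out = exclude_duplicate_patients(tissue_panel)
        assert not out.patients.duplicated().any()
        # the fixture panel plants 2 duplicate patients
        assert len(out.auc) == len(tissue_panel.auc) - 2

    def test_first_line_kept(self, tissue_panel):
        out = exclude_duplicate_patients(tissue_panel)
        dup_patients = tissue_panel.patients[tissue_panel.patients.duplicated()]
        for pat in dup_patients:
            first = tissue_panel.patients[tissue_panel.patients == pat].index[0]
            assert first in out.auc.index
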