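import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lscat import (
    ExperimentConfig,
    base_rate_benchmark,
    compute_metrics,
    match_efficiency,
    run_experiment,
)
from lscat.evaluation import kappa_label


def _vectors(tp, fn, fp, tn):
    true = np.r_[np.ones(tp + fn, bool), np.zeros(fp + tn, bool)]
    pred = np.r_[np.ones(tp, bool), np.zeros(fn, bool),
                 np.ones(fp, bool), np.zeros(tn, bool)]
    return true, pred


class TestComputeMetrics:
    def test_perfect_agreement(self):
        true, pred = _vectors(10, 0, 0, 20)
        rep = compute_metrics(true, pred)
        assert (rep.type_i_error, rep.type_ii_error) == (0.0, 0.0)
        assert (rep.accuracy, rep.kappa) == (1.0, 1.0)

    def test_hand_arithmetic_example(self):
        rep = compute_metrics(*_vectors(40, 10, 5, 45))
        assert rep.type_i_error == pytest.approx(0.100)
        assert rep.type_ii_error == pytest.approx(0.200)
        assert rep.accuracy == pytest.approx(0.850)

    def test_hand_kappa_example(self):
        rep = compute_metrics(*_vectors(9, 1, 2, 88))
        assert rep.accuracy == pytest.approx(0.97)
        assert rep.kappa == pytest.approx((0.97 - 0.812) / (1 - 0.812), abs=1e-12)
        assert rep.kappa == pytest.approx(0.840, abs=0.001)

    def test_undefined_denominators_flagged_not_zeroed(self):
        rep = compute_metrics(np.ones(5, bool), np.ones(5, bool))
        assert np.isnan(rep.type_i_error)
        assert "type_i_error" in rep.undefined
        rep = compute_metrics(np.zeros(5, bool), np.zeros(5, bool))
        assert np.isnan(rep.type_ii_error) and np.isnan(rep.kappa)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_metrics(np.ones(3, bool), np.ones(4, bool))

    @settings(deadline=None, max_examples=60)
    @given(tp=st.integers(0, 30), fn=st.integers(0, 30),
           fp=st.integers(0, 30), tn=st.integers(0, 30))
    def test_accuracy_identity_with_weighted_errors(self, tp, fn, fp, tn):
        """Accuracy = 1 - (TypeI * w_neg + TypeII * w_pos), weights = actual
        status proportions."""
        n = tp + fn + fp + tn
        if n == 0:
            return
        rep = compute_metrics(*_vectors(tp, fn, fp, tn))
        assert rep.n == n
        w_pos = (tp + fn) / n
        w_neg = (fp + tn) / n
        t1 = rep.type_i_error if not np.isnan(rep.type_i_error) else 0.0
        t2 = rep.type_ii_error if not np.isnan(rep.type_ii_error) else 0.0
        assert rep.accuracy == pytest.approx(1 - (t1 * w_neg + t2 * w_pos), abs=1e-12)
        if not np.isnan(rep.kappa):
            assert -1.0 - 1e-9 <= rep.kappa <= 1.0 + 1e-9

    def test_kappa_bands_for_reporting(self):
        assert kappa_label(0.9) == "almost perfect"
        assert kappa_label(0.5) == "moderate"
        assert kappa_label(float("nan")) == "undefined"


class TestBaseRate:
    def test_rate_zero_predicts_all_negative(self):
        true = np.r_[np.ones(4, bool), np.zeros(6, bool)]
        rep = base_rate_benchmark(0.0, true, seed=1)
        assert rep.type_i_error == 0.0 and rep.type_ii_error == 1.0

    def test_rate_one_predicts_all_positive(self):
        true = np.r_[np.ones(4, bool), np.zeros(6, bool)]
        rep = base_rate_benchmark(1.0, true, seed=1)
        assert rep.type_i_error == 1.0 and rep.type_ii_error == 0.0

    def test_kappa_near_zero_under_independence(self):
        rng = np.random.default_rng(5)
        true = rng.random(10_000) < 0.24
        rep = base_rate_benchmark(0.24, true, seed=9)
        assert abs(rep.kappa) < 0.03


class TestMatchEfficiency:
    def test_exact_grid_point_chosen_with_zero_gap(self, phq9_data_medium):
        _, achieved, gap, trace = match_efficiency(
            2.0, "DTCAT", phq9_data_medium, 10, [0.0, 0.001, 0.01, 0.3]
        )
        row = trace.loc[trace["gap"].idxmin()]
        assert achieved == row["avg_items"]
        assert abs(gap) == trace["gap"].min()

    def test_tie_goes_to_fewer_items(self, phq9_data_medium):
        # duplicate grid points -> exact tie; the cheaper one must win
        eng, achieved, _, trace = match_efficiency(
            3.5, "SC", phq9_data_medium, 5, [0.9, 0.9]
        )
        assert achieved == trace["avg_items"].min()

    def test_sc_grid_averages_monotone_in_gamma(self, phq9_data_medium):
        grid = [0.7, 0.8, 0.9, 0.95]
        _, _, _, trace = match_efficiency(4.0, "SC", phq9_data_medium, 5, grid)
        avgs = trace["avg_items"].to_numpy()
        assert all(a <= b + 1e-9 for a, b in zip(avgs, avgs[1:]))

    def test_empty_grid_rejected(self, phq9_data_medium):
        with pytest.raises(ValueError, match="non-empty"):
            match_efficiency(3.0, "SC", phq9_data_medium, 5, [])


@pytest.fixture(scope="module")
def small_result(phq9_data_medium):
    cfg = ExperimentConfig(cutoffs=(5,), criteria=(0.95,), seed=3,
                           n_classes=3, n_starts=3)
    return run_experiment(phq9_data_medium, cfg), phq9_data_medium


class TestRunExperiment:
    def test_single_cell_layout(self, small_result):
        res, _ = small_result
        assert len(res.efficiency_table) == 3
        # 3 method rows + 1 base-rate row
        assert len(res.validity_table) == 4

    def test_confusion_counts_sum_to_validation_n(self, small_result):
        res, data = small_result
        n_val = data.n_respondents - int(np.ceil(0.5 * data.n_respondents))
        methods = res.validity_table[res.validity_table["method"] != "base rate"]
        for _, row in methods.iterrows():
            assert row["tp"] + row["fp"] + row["tn"] + row["fn"] == n_val

    def test_full_design_layout(self, phq9_data_small):
        cfg = ExperimentConfig(seed=1, n_classes=2, n_starts=2,
                               gamma_grid=(0.8, 0.9, 0.99),
                               complexity_grid=(0.0, 0.01), min_leaf=20)
        res = run_experiment(phq9_data_small, cfg)
        # 2 cutoffs x 2 criteria x 3 methods validity rows + 2 base-rate rows
        assert len(res.validity_table) == 14
        assert (res.validity_table["method"] == "base rate").sum() == 2
        assert not res.fig_data.empty

    def test_rerun_same_seed_identical_tables(self, phq9_data_small):
        cfg = ExperimentConfig(cutoffs=(5,), criteria=(0.95,), seed=8,
                               n_classes=2, n_starts=2,
                               gamma_grid=(0.8, 0.9), complexity_grid=(0.01,),
                               min_leaf=20)
        a = run_experiment(phq9_data_small, cfg)
        b = run_experiment(phq9_data_small, cfg)
        assert a.validity_table.to_csv() == b.validity_table.to_csv()
        assert a.efficiency_table.to_csv() == b.efficiency_table.to_csv()

    def test_misclassifications_concentrate_near_cutoff(self, small_result):
        """For adaptive sum-score methods, errors sit close to the cutoff."""
        res, _ = small_result
        tr = res.traces
        for method in ("LSCAT", "SC"):
            sub = tr[tr["method"] == method]
            mis = sub["predicted_status"] != sub["true_status"]
            if mis.sum() == 0:
                continue
            d_mis = (sub.loc[mis, "full_sum"] - 5).abs().mean()
            d_ok = (sub.loc[~mis, "full_sum"] - 5).abs().mean()
            assert d_mis <= d_ok
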