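"""The background-removal filter cascade and its accounting."""

import numpy as np
import pytest

import cellogram as cg
from cellogram.filters import DEFAULT_ORDER
from conftest import random_table


class TestFoldChange:
    def test_formula(self):
        assert cg.fold_change([100, 300, 200], [90, 100, 110]) == pytest.approx(3.0)

    def test_zero_background_uses_noise_floor(self):
        assert cg.fold_change([500.0], np.zeros(10)) == pytest.approx(500.0)

    def test_only_last_n_background_scans_count(self):
        bg = np.concatenate([np.full(5, 1e6), np.full(10, 100.0)])
        assert cg.fold_change([300.0], bg, n_background=10) == pytest.approx(3.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            peak = rng.uniform(0, 1000, rng.integers(1, 30))
            bg = rng.uniform(1, 100, rng.integers(1, 20))
            expected = peak.max() / bg[-10:].mean()
            assert cg.fold_change(peak, bg) == pytest.approx(expected)


class TestFcDfFilters:
    def test_fc_threshold_is_inclusive(self):
        table = random_table(np.random.default_rng(0), n_cells=4, n_features=2)
        table.fold_change[:, 0] = 3.0
        table.fold_change[:, 1] = 2.999
        cfg = cg.FilterConfig(fc_threshold=3.0)
        filtered, mask = cg.fc_filter(table, cfg)
        assert filtered.n_features == 1
        assert mask.all()

    def test_df_boundaries(self):
        cfg = cg.FilterConfig(df_threshold=0.33)
        mask = np.zeros((100, 2), dtype=bool)
        mask[:40, 0] = True   # 40% of cells
        mask[:32, 1] = True   # 32% of cells
        keep = cg.df_filter(mask, cfg)
        assert list(keep) == [True, False]

    def test_df_matches_counting_oracle(self):
        rng = np.random.default_rng(4)
        cfg = cg.FilterConfig(df_threshold=0.4)
        for _ in range(20):
            mask = rng.random((15, 25)) < 0.4
            keep = cg.df_filter(mask, cfg)
            expected = [sum(mask[:, j]) / 15 >= 0.4 for j in range(25)]
            assert list(keep) == expected


def table_with_mz(mzs, intensity, fc=None):
    intensity = np.asarray(intensity, dtype=float)
    features = [cg.FeatureGroup(rep_mz=float(m), members=[], ppm_tol=5.0)
                for m in mzs]
    if fc is None:
        fc = np.where(intensity > 0, 10.0, 0.0)
    return cg.CellFeatureTable(cell_ids=list(range(intensity.shape[0])),
                               features=features, intensity=intensity,
                               fold_change=np.asarray(fc, dtype=float))


class TestDeisotope:
    def test_choline_m1_is_dropped(self):
        # choline has 5 carbons: expected M+1/M around 5 x 0.011 = 0.055
        table = table_with_mz(
            [104.1070, 105.1104],
            np.column_stack([np.full(10, 1000.0), np.full(10, 55.0)]))
        keep = cg.deisotope(table.features, table, cg.FilterConfig())
        assert list(keep) == [True, False]

    def test_delta_outside_tolerance_is_retained(self):
        table = table_with_mz(
            [104.1070, 105.1170],  # delta 1.0100, ~60 ppm off
            np.column_stack([np.full(10, 1000.0), np.full(10, 55.0)]))
        keep = cg.deisotope(table.features, table, cg.FilterConfig())
        assert list(keep) == [True, True]

    def test_high_ratio_is_retained_as_distinct_species(self):
        table = table_with_mz(
            [104.1070, 105.1104],
            np.column_stack([np.full(10, 1000.0), np.full(10, 1200.0)]))
        keep = cg.deisotope(table.features, table, cg.FilterConfig())
        assert list(keep) == [True, True]


class TestExclusionAndMdf:
    def test_listed_mz_is_dropped_within_tolerance(self):
        table = table_with_mz([760.5850, 400.0], np.ones((3, 2)))
        keep = cg.exclusion_filter(table.features, [760.586], 5.0)
        assert list(keep) == [False, True]

    def test_empty_list_is_identity(self):
        table = table_with_mz([100.0, 200.0], np.ones((2, 2)))
        assert cg.exclusion_filter(table.features, [], 5.0).all()

    def test_exclusion_matches_brute_force(self):
        rng = np.random.default_rng(6)
        mzs = np.sort(rng.uniform(100, 900, 40))
        table = table_with_mz(mzs, np.ones((2, 40)))
        targets = rng.uniform(100, 900, 10)
        keep = cg.exclusion_filter(table.features, targets, 20.0)
        expected = [all(abs(m - t) > t * 20e-6 for t in targets) for m in mzs]
        assert list(keep) == expected

    def test_mdf_examples(self):
        table = table_with_mz([760.586, 445.120], np.ones((2, 2)))
        keep = cg.mass_defect_filter(table.features, [(0.90, 1.00)])
        assert list(keep) == [True, True]
        keep = cg.mass_defect_filter(table.features, [(0.10, 0.15)])
        assert list(keep) == [True, False]

    def test_mdf_wrapping_range(self):
        table = table_with_mz([500.95, 500.05, 500.50], np.ones((1, 3)))
        keep = cg.mass_defect_filter(table.features, [(0.90, 0.10)])
        assert list(keep) == [False, False, True]

    def test_overlapping_ranges_merge_with_warning(self):
        table = table_with_mz([500.12], np.ones((1, 1)))
        with pytest.warns(UserWarning, match="merged"):
            keep = cg.mass_defect_filter(table.features,
                                         [(0.10, 0.20), (0.15, 0.30)])
        assert list(keep) == [False]

    def test_mdf_matches_membership_oracle(self):
        rng = np.random.default_rng(11)
        mzs = np.sort(rng.uniform(100, 900, 50))
        table = table_with_mz(mzs, np.ones((1, 50)))
        ranges = [(0.05, 0.15), (0.4, 0.55), (0.95, 0.02)]
        keep = cg.mass_defect_filter(table.features, ranges)
        def in_range(frac, lo, hi):
            return (lo <= frac < hi) if lo <= hi else (frac >= lo or frac < hi)
        expected = [not any(in_range(m % 1.0, lo, hi) for lo, hi in ranges)
                    for m in mzs]
        assert list(keep) == expected


class TestCascade:
    def test_empty_order_is_identity(self):
        table = random_table(np.random.default_rng(2))
        out, report = cg.run_cascade(table, cg.FilterConfig(), order=())
        assert out.n_features == table.n_features
        assert report.steps == []

    def test_unknown_step_raises(self):
        table = random_table(np.random.default_rng(2))
        with pytest.raises(ValueError, match="unknown"):
            cg.run_cascade(table, cg.FilterConfig(), order=("fc", "bogus"))

    def test_counts_non_increasing_and_consistent(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            table = random_table(rng)
            _out, report = cg.run_cascade(table, cg.FilterConfig())
            counts = [table.n_features] + [s.features_out for s in report.steps]
            assert all(b <= a for a, b in zip(counts, counts[1:]))
            for s, n_in in zip(report.steps, counts):
                assert s.features_in == n_in

    def test_each_step_is_idempotent(self):
        rng = np.random.default_rng(13)
        cfg = cg.FilterConfig(mdf_ranges=((0.2, 0.3),),
                              is_list=(300.0,), blank_list=(500.0,))
        for step in DEFAULT_ORDER:
            table = random_table(rng)
            once, _ = cg.run_cascade(table, cfg, order=(step,))
            twice, rep2 = cg.run_cascade(once, cfg, order=(step,))
            assert twice.n_features == once.n_features
            assert rep2.steps[0].features_in == rep2.steps[0].features_out

    def test_retention_accounting_matches_truth_masks(self):
        rng = np.random.default_rng(23)
        table = random_table(rng, n_cells=30, n_features=40)
        truth = np.where(rng.random(40) < 0.4, "endogenous", "background")
        cfg = cg.FilterConfig()
        out, report = cg.run_cascade(table, cfg, truth=truth)
        kept_mz = set(np.round(out.feature_mz, 6))
        kept = np.array([round(f.rep_mz, 6) in kept_mz for f in table.features])
        endo = truth == "endogenous"
        assert report.retained_endogenous == pytest.approx(
            100.0 * (kept & endo).sum() / endo.sum())
        assert report.retained_background == pytest.approx(
            100.0 * (kept & ~endo).sum() / (~endo).sum())

    def test_well_separated_classes_retained(self):
        # endogenous: FC >= 10 in >= 60% of cells; background: FC < 2
        rng = np.random.default_rng(31)
        n_cells, n_endo, n_bg = 50, 40, 60
        fc = np.zeros((n_cells, n_endo + n_bg))
        fc[:, :n_endo] = np.where(rng.random((n_cells, n_endo)) < 0.7,
                                  rng.uniform(10, 50, (n_cells, n_endo)),
                                  rng.uniform(0.5, 2, (n_cells, n_endo)))
        fc[:, n_endo:] = rng.uniform(0.2, 1.99, (n_cells, n_bg))
        mzs = np.sort(rng.uniform(100, 900, n_endo + n_bg))
        perm = rng.permutation(n_endo + n_bg)
        truth = np.where(perm < n_endo, "endogenous", "background")
        table = table_with_mz(mzs, np.where(fc[:, perm] > 0, 1000.0, 0.0),
                              fc=fc[:, perm])
        _out, report = cg.run_cascade(table, cg.FilterConfig(),
                                      order=("fc", "df"), truth=truth)
        assert report.retained_endogenous >= 95.0
        assert report.retained_background == 0.0

    def test_raising_thresholds_never_raises_retention(self):
        rng = np.random.default_rng(37)
        table = random_table(rng, n_cells=40, n_features=60)
        truth = np.where(rng.random(60) < 0.5, "endogenous", "background")
        last = np.inf
        for fc_thr in (1.5, 3.0, 5.0, 9.0):
            _o, rep = cg.run_cascade(table, cg.FilterConfig(fc_threshold=fc_thr),
                                     order=("fc", "df"), truth=truth)
            assert rep.retained_endogenous <= last + 1e-9
            last = rep.retained_endogenous
        last = np.inf
        for df_thr in (0.1, 0.33, 0.5, 0.75):
            _o, rep = cg.run_cascade(table, cg.FilterConfig(df_threshold=df_thr),
                                     order=("fc", "df"), truth=truth)
            assert rep.retained_endogenous <= last + 1e-9
            last = rep.retained_endogenous


class TestBinaryMetrics:
    def test_arithmetic(self):
        pred = np.array([True] * 95 + [False] * 5 + [False] * 98 + [True] * 2)
        truth = np.array(["endogenous"] * 100 + ["background"] * 100)
        m = cg.binary_metrics(pred, truth)
        assert (m.tp, m.fn, m.tn, m.fp) == (95, 5, 98, 2)
        assert m.sensitivity == pytest.approx(0.95)
        assert m.specificity == pytest.approx(0.98)
        assert m.accuracy == pytest.approx(0.965)

    def test_perfect_prediction(self):
        truth = np.array(["endogenous", "background", "endogenous"])
        m = cg.binary_metrics(truth == "endogenous", truth)
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)

    def test_empty_class_reports_none(self):
        truth = np.array(["endogenous", "endogenous"])
        m = cg.binary_metrics(np.array([True, False]), truth)
        assert m.specificity is None
        assert m.sensitivity == pytest.approx(0.5)

    def test_random_predictions_match_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            truth = np.where(rng.random(50) < 0.5, "endogenous", "background")
            pred = rng.random(50) < 0.5
            m = cg.binary_metrics(pred, truth)
            tp = int(sum(p and t == "endogenous" for p, t in zip(pred, truth)))
            fn = int(sum((not p) and t == "endogenous"
                         for p, t in zip(pred, truth)))
            assert (m.tp, m.fn) == (tp, fn)
            assert m.tp + m.fp + m.tn + m.fn == 50
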