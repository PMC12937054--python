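"""Greedy ppm grouping and the two-stage alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster, linkage

import cellogram as cg
from cellogram.detection import _build_events


def single_linkage_groups(mzs, ppm_tol):
    """Independent oracle: single-linkage clustering cut at the ppm tolerance."""
    mzs = np.asarray(mzs, dtype=float)
    if mzs.size == 1:
        return np.zeros(1, dtype=int)
    z = linkage(np.log(mzs)[:, None], method="single")
    return fcluster(z, t=np.log1p(ppm_tol * 1e-6), criterion="distance")


class TestGroupMz:
    def test_within_tolerance_merges(self):
        groups = cg.group_mz([(0, 200.0000, 1.0), (1, 200.0008, 1.0)], 5.0)
        assert len(groups) == 1
        assert 200.0 <= groups[0].rep_mz <= 200.0008

    def test_beyond_tolerance_splits(self):
        groups = cg.group_mz([(0, 200.0000, 1.0), (1, 200.0030, 1.0)], 5.0)
        assert len(groups) == 2

    def test_matches_single_linkage_on_separated_centers(self):
        rng = np.random.default_rng(12)
        tol = 5.0
        centers = 200.0 * (1 + np.arange(10) * 20 * tol * 1e-6)
        mzs = np.concatenate(
            [c * (1 + rng.normal(0, tol / 4 * 1e-6, 10)) for c in centers])
        obs = [(i, m, 1.0) for i, m in enumerate(mzs)]
        groups = cg.group_mz(obs, tol)
        assert len(groups) == 10
        oracle = single_linkage_groups(mzs, tol)
        assert len(np.unique(oracle)) == 10
        # identical partitions: members grouped together iff oracle says so
        by_group = {id_: gi for gi, g in enumerate(groups)
                    for id_, _m, _i in g.members}
        for i in range(len(mzs)):
            for j in range(i + 1, len(mzs)):
                assert (by_group[i] == by_group[j]) == (oracle[i] == oracle[j])

    def test_partitions_input(self):
        rng = np.random.default_rng(1)
        obs = [(i, m, float(w)) for i, (m, w) in enumerate(
            zip(rng.uniform(100, 105, 200), rng.uniform(0, 10, 200)))]
        groups = cg.group_mz(obs, 8.0)
        seen = sorted(id_ for g in groups for id_, _m, _i in g.members)
        assert seen == list(range(200))
        for g in groups:
            assert min(m for _i, m, _w in g.members) <= g.rep_mz \
                <= max(m for _i, m, _w in g.members)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        mzs = rng.uniform(100, 101, 30)
        obs = [(i, m, 1.0 + i % 3) for i, m in enumerate(mzs)]
        shuffled = [obs[i] for i in rng.permutation(30)]
        g1 = cg.group_mz(obs, 6.0)
        g2 = cg.group_mz(shuffled, 6.0)
        p1 = [sorted(id_ for id_, _m, _w in g.members) for g in g1]
        p2 = [sorted(id_ for id_, _m, _w in g.members) for g in g2]
        assert p1 == p2

    def test_non_positive_mz_raises(self):
        with pytest.raises(ValueError):
            cg.group_mz([(0, -5.0, 1.0)], 5.0)


def run_from_matrix(values, mz_per_species, jitter_ppm=0.0, seed=0):
    """Assemble a Run from a (species x scans) intensity matrix."""
    rng = np.random.default_rng(seed)
    n_species, n_scans = values.shape
    mz = np.asarray(mz_per_species, dtype=float)
    spectra = []
    for i in range(n_scans):
        present = np.flatnonzero(values[:, i] > 0)
        mzs = mz[present] * (1 + rng.normal(0, jitter_ppm * 1e-6, present.size))
        order = np.argsort(mzs)
        spectra.append(cg.Spectrum(i, i / 120.0, mzs[order],
                                   values[present, i][order]))
    return cg.Run(spectra=spectra, mz_range=(50.0, 2000.0))


class TestAlignWithinEvent:
    def _event(self, n_scans=40):
        return _build_events([10], n_scans, cg.DetectionParams(
            sn_threshold=1.0, background_scans=10))[0]

    def test_single_species_sums_peak_window(self):
        values = np.zeros((1, 40))
        values[0, 10:20] = 7.0
        values[0, 2:10] = 1.0  # background-window signal, flagged not summed
        run = run_from_matrix(values, [300.0])
        groups = cg.align_within_event(run, self._event(), 5.0)
        assert len(groups) == 1
        assert groups[0].total_intensity == pytest.approx(70.0)
        assert all(s in groups[0].background_scan_set
                   for s in range(2, 10))

    def test_scan_jitter_within_tolerance_stays_one_group(self):
        values = np.full((1, 40), 5.0)
        run = run_from_matrix(values, [500.0], jitter_ppm=1.0, seed=3)
        groups = cg.align_within_event(run, self._event(), 5.0)
        assert len(groups) == 1

    def test_twenty_separated_species_give_twenty_groups(self):
        rng = np.random.default_rng(9)
        mzs = 200.0 * (1 + np.arange(20) * 25e-6)  # 25 ppm apart
        values = rng.uniform(1, 10, (20, 40))
        run = run_from_matrix(values, mzs, jitter_ppm=0.5, seed=4)
        groups = cg.align_within_event(run, self._event(), 5.0)
        assert len(groups) == 20


class TestAlignAcrossEvents:
    def _pipeline(self, values, mzs, n_events, scans_per_event=40, **kw):
        run = run_from_matrix(values, mzs, **kw)
        triggers = [10 + k * scans_per_event for k in range(n_events)]
        events = _build_events(triggers, values.shape[1],
                               cg.DetectionParams(sn_threshold=1.0))
        per_event = [(e.cell_id, cg.align_within_event(run, e, 5.0))
                     for e in events]
        return cg.align_across_events(per_event, 5.0, events=events), events

    def test_shared_species_single_feature(self):
        values = np.zeros((1, 80))
        values[0, 12:20] = 3.0
        values[0, 52:60] = 4.0
        table, _ = self._pipeline(values, [400.0], 2)
        assert table.n_features == 1
        assert np.all(table.intensity > 0)

    def test_species_in_one_cell_only_is_sparse(self):
        values = np.zeros((2, 80))
        values[0, 12:20] = 3.0
        values[0, 52:60] = 4.0
        values[1, 14:18] = 9.0  # cell 1 only
        table, _ = self._pipeline(values, [400.0, 500.0], 2)
        assert table.n_features == 2
        col = table.intensity[:, 1]
        assert col[0] > 0 and col[1] == 0

    def test_duplicate_cell_ids_raise(self):
        groups = cg.group_mz([(0, 100.0, 1.0)], 5.0)
        with pytest.raises(ValueError, match="duplicate"):
            cg.align_across_events([(1, groups), (1, groups)], 5.0)

    def test_simulated_counts_and_conservation(self):
        # 50 cells x 30 well-separated species with low jitter: the
        # two-stage alignment recovers exactly the true species and
        # conserves every cell's integrated intensity.
        cfg = cg.SimConfig(seed=21, n_cells=50, n_high_sn=15, n_low_sn=15,
                           n_background_static=0, n_background_drift=0,
                           n_background_spike=0, n_internal_standards=0,
                           n_blanks=0, isotopologue_fraction=0.0,
                           mass_jitter_ppm=0.4, low_sn_presence=(1.0, 1.0))
        run, gt = cg.simulate_run(cfg)
        events = _build_events([e.trigger_scan for e in gt.events],
                               run.n_scans, cg.DetectionParams(sn_threshold=1.0))
        table = cg.align_from_run(run, events, 5.0)
        assert table.n_features == 30
        order = np.argsort(gt.species["mz"].to_numpy())
        np.testing.assert_allclose(
            table.feature_mz, gt.species["mz"].to_numpy()[order], rtol=1e-5)
        np.testing.assert_allclose(
            table.intensity, gt.cell_intensity[order].T, rtol=1e-9)

    def test_total_intensity_is_conserved(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 5, (5, 120))
        values[values < 1] = 0.0
        mzs = 300.0 * (1 + np.arange(5) * 30e-6)
        table, events = self._pipeline(values, mzs, 3)
        in_peak = sum(
            float(values[:, e.peak_window[0]:e.peak_window[1]].sum())
            for e in events)
        assert table.intensity.sum() == pytest.approx(in_peak, rel=1e-9)


class TestAlignAcrossFiles:
    def _table(self, mz, n_cells=3, value=10.0, polarity="positive", source=""):
        features = [cg.FeatureGroup(rep_mz=mz, members=[(c, mz, value)
                                                        for c in range(n_cells)],
                                    ppm_tol=5.0)]
        return cg.CellFeatureTable(
            cell_ids=list(range(1, n_cells + 1)), features=features,
            intensity=np.full((n_cells, 1), value),
            fold_change=np.full((n_cells, 1), 5.0),
            polarity=polarity, source=source)

    def test_identical_tables_merge_to_one_feature(self):
        merged = cg.align_across_files(
            [self._table(400.0, source="a"), self._table(400.0, source="b")], 5.0)
        assert merged.n_features == 1
        assert merged.n_cells == 6
        assert merged.cell_ids[0].startswith("a:")

    def test_features_three_ppm_apart_merge_at_five(self):
        t2 = self._table(400.0 * (1 + 3e-6))
        merged = cg.align_across_files([self._table(400.0), t2], 5.0)
        assert merged.n_features == 1

    def test_mixed_polarity_raises(self):
        with pytest.raises(ValueError, match="polarity"):
            cg.align_across_files(
                [self._table(400.0), self._table(400.0, polarity="negative")], 5.0)

    def test_partially_overlapping_species_union(self):
        tables = []
        for k, mz_set in enumerate([(300.0, 400.0), (400.0, 500.0),
                                    (300.0, 500.0)]):
            features = [cg.FeatureGroup(rep_mz=m, members=[(1, m, 1.0)],
                                        ppm_tol=5.0) for m in mz_set]
            tables.append(cg.CellFeatureTable(
                cell_ids=[1], features=features,
                intensity=np.ones((1, 2)), fold_change=np.ones((1, 2)),
                source=f"f{k}"))
        merged = cg.align_across_files(tables, 5.0)
        assert [round(m) for m in merged.feature_mz] == [300, 400, 500]
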