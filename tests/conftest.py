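"""Shared fixtures: simulated runs reused across test modules."""

import numpy as np
import pytest

import cellogram as cg


def detect_marker(run, gt, sn_threshold=20.0, refractory=0.15):
    """Standard marker detection settings for simulated runs."""
    cfg = gt.config
    params = cg.DetectionParams(
        marker_mz=cfg.marker_mz, ppm_tol=5.0, sn_threshold=sn_threshold,
        refractory_period=refractory,
    )
    eic = cg.extract_eic(run, cfg.marker_mz, params.ppm_tol)
    return eic, params, cg.detect_cell_events(eic, params)


def truth_labels_for(table, gt, ppm_tol=5.0):
    """Per-feature endogenous/background truth by nearest true species."""
    sp = gt.species
    true_mz = sp["mz"].to_numpy()
    labels = []
    for m in table.feature_mz:
        ppm = np.abs(true_mz - m) / m * 1e6
        k = int(np.argmin(ppm))
        endo = ppm[k] <= ppm_tol and sp["cls"][k] in ("high_sn", "low_sn")
        labels.append("endogenous" if endo else "background")
    return labels


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated run (100 cells, 3 cells/min)."""
    cfg = cg.SimConfig(seed=1)
    run, gt = cg.simulate_run(cfg)
    return run, gt


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Detection + two-stage alignment on the default simulated run."""
    run, gt = default_sim
    eic, params, events = detect_marker(run, gt)
    table = cg.align_from_run(run, events, 5.0)
    return run, gt, events, table


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast run for I/O round-trip style tests."""
    cfg = cg.SimConfig(seed=7, n_cells=12, n_high_sn=4, n_low_sn=3,
                       n_background_static=2, n_background_drift=2,
                       n_background_spike=2, n_internal_standards=1,
                       n_blanks=1)
    run, gt = cg.simulate_run(cfg)
    return run, gt


def random_table(rng, n_cells=20, n_features=30):
    """A random feature table with plausible m/z, intensity and FC values."""
    mzs = np.sort(rng.uniform(80, 900, n_features))
    while np.any(np.diff(mzs) <= 1e-6):
        mzs = np.sort(rng.uniform(80, 900, n_features))
    features = [cg.FeatureGroup(rep_mz=float(m), members=[], ppm_tol=5.0)
                for m in mzs]
    intensity = rng.uniform(0, 1e5, (n_cells, n_features))
    intensity[rng.random((n_cells, n_features)) < 0.3] = 0.0
    fc = np.where(intensity > 0, rng.uniform(0.5, 12.0, (n_cells, n_features)), 0.0)
    return cg.CellFeatureTable(cell_ids=list(range(1, n_cells + 1)),
                               features=features, intensity=intensity,
                               fold_change=fc)
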