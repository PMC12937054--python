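"""Synthetic cellogram generator with ground truth.

Emulates a touch-down direct-infusion single-cell acquisition: the
probe parks on each cell until its metabolome is exhaustively
extracted, producing a fast-rising, exponentially decaying transient
per cell; between cells only background is sampled.  Defaults follow
the typical experiment — 100 cells sampled at 3 cells per minute, full
scans at 2 Hz across m/z 75-1000.

Species come in chronogram classes:

* ``high_sn`` — event-locked peaks with a baseline several orders of
  magnitude below the peaks; the first of these is the cell marker,
  pinned to ``marker_mz`` and present in every cell.
* ``low_sn`` — event-locked peaks over an elevated background, less
  than one order of magnitude of separation, present in only a
  fraction of cells.
* ``background_static`` / ``background_drift`` — flat or slowly
  drifting background levels.
* ``background_spike`` — low background that spikes once or twice per
  run, mimicking a cellographic peak.
* internal standards (constant infusion) and solvent blanks (static
  background whose m/z goes on the blank exclusion list).

A fraction of endogenous species carries a carbon-13 M+1 isotopologue
at +1.003355 Th with intensity ratio 0.011 per carbon.  Every
species' m/z is jittered per scan by a Gaussian in ppm, and centroids
below the detection floor are dropped, as a real centroiding step
does.  All randomness flows from the single seed in the config.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import Run, Spectrum

__all__ = ["SimConfig", "TrueEvent", "GroundTruth", "simulate_run", "export_truth"]

ENDOGENOUS_CLASSES = ("high_sn", "low_sn")
BACKGROUND_CLASSES = ("background_static", "background_drift", "background_spike",
                      "internal_standard", "solvent_blank")


@dataclass
class SimConfig:
    n_cells: int = 100
    cell_rate: float = 3.0          # cells / minute
    scan_rate: float = 2.0          # scans / second
    run_margin: float = 0.10        # extra run length beyond n_cells/cell_rate

    n_high_sn: int = 30             # includes the marker species
    n_low_sn: int = 30
    n_background_static: int = 15
    n_background_drift: int = 15
    n_background_spike: int = 10
    n_internal_standards: int = 2
    n_blanks: int = 3

    marker_mz: float = 104.107      # choline-like, always-present cell marker
    mz_range: tuple = (75.0, 1000.0)
    min_separation_ppm: float = 30.0
    mass_jitter_ppm: float = 1.5

    rise_scans: int = 2
    decay_scans: tuple = (3.0, 6.0)            # exponential tau, uniform
    extract_scans: tuple = (10.0, 16.0)        # exhaustion: signal ends here
    cell_time_jitter_min: float = 0.015
    cell_amplitude_sigma: float = 0.5          # lognormal per-cell factor

    high_sn_amplitude: tuple = (1e5, 1e7)      # log-uniform peak amplitude
    high_sn_baseline_decades: tuple = (2.5, 3.5)
    low_sn_amplitude: tuple = (5e3, 2e5)
    low_sn_ratio_decades: tuple = (0.3, 0.9)   # peak/baseline = 10^u
    low_sn_presence: tuple = (0.5, 0.9)        # per-cell presence probability
    background_level: tuple = (1e3, 1e5)
    background_noise_cv: float = 0.10          # endogenous baselines, Gaussian
    background_lognorm_sigma: tuple = (0.2, 0.8)  # background species, per-species
    drift_amplitude: tuple = (0.3, 0.7)
    spike_level: tuple = (3e2, 3e3)
    spike_gain: tuple = (10.0, 100.0)
    is_level: tuple = (1e5, 3e5)

    isotopologue_fraction: float = 0.3
    carbon_range: tuple = (5, 40)

    centroid_floor: float = 50.0
    seed: int = 0

    @property
    def run_length_min(self) -> float:
        return self.n_cells / self.cell_rate * (1.0 + self.run_margin)

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if min(self.cell_rate, self.scan_rate) <= 0:
            raise ValueError("rates must be > 0")
        if self.n_high_sn < 1:
            raise ValueError("n_high_sn must be >= 1 (the marker species)")
        if self.run_margin < 0:
            raise ValueError(
                "infeasible config: cells x rate exceed the run length"
            )


@dataclass
class TrueEvent:
    cell_id: int
    time: float                       # minutes, rise onset
    trigger_scan: int
    background_window: tuple[int, int]
    peak_window: tuple[int, int]
    extended_window: tuple[int, int]


@dataclass
class GroundTruth:
    config: SimConfig
    events: list[TrueEvent]
    species: "object"                 # pandas DataFrame, one row per species
    cell_intensity: np.ndarray        # species x cells, emitted sums over peak windows
    times: np.ndarray

    @property
    def is_list(self) -> list[float]:
        df = self.species
        return list(df.loc[df["cls"] == "internal_standard", "mz"])

    @property
    def blank_list(self) -> list[float]:
        df = self.species
        return list(df.loc[df["cls"] == "solvent_blank", "mz"])


def _place_mz(rng: np.random.Generator, cfg: SimConfig, taken: list[float]) -> float:
    lo, hi = cfg.mz_range
    arr = np.asarray(taken) if taken else np.empty(0)
    for _ in range(10000):
        # leave headroom so an M+1 companion also stays inside the range
        x = rng.uniform(lo + 1.0, hi - 2.0)
        if arr.size == 0:
            return x
        sep = np.abs(arr - x) / x * 1e6
        sep_iso = np.abs(arr - (x + 1.003355)) / x * 1e6
        if sep.min() > cfg.min_separation_ppm and sep_iso.min() > cfg.min_separation_ppm:
            return x
    raise RuntimeError("could not place species m/z with required separation")


def _event_kernel(offsets: np.ndarray, rise: int, tau: float,
                  n_extract: float = np.inf) -> np.ndarray:
    """Peak shape by scan offset from the trigger.

    Linear rise over ``rise`` scans, exponential decay with time
    constant ``tau``, tapering to zero by ``n_extract`` scans — the
    point at which the touched-down cell is exhaustively extracted and
    the trace returns to baseline.
    """
    out = np.where(
        offsets < rise,
        (offsets + 1) / rise,
        np.exp(-(offsets - rise + 1) / tau),
    )
    if np.isfinite(n_extract):
        out = out * np.clip((n_extract - offsets) / 4.0, 0.0, 1.0)
    out[offsets < 0] = 0.0
    return out


def simulate_run(cfg: SimConfig) -> tuple[Run, GroundTruth]:
    """Generate a run and its ground truth from ``cfg`` (seeded, reproducible)."""
    import pandas as pd

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_scans = int(round(cfg.run_length_min * 60 * cfg.scan_rate))
    times = np.arange(n_scans) / (cfg.scan_rate * 60.0)  # minutes

    # --- cell event placement -------------------------------------------
    base = (np.arange(cfg.n_cells) + 0.6) / cfg.cell_rate
    t_cells = base + rng.normal(0.0, cfg.cell_time_jitter_min, cfg.n_cells)
    t_cells = np.sort(np.clip(t_cells, 0.0, times[-1]))
    trigger_scans = np.searchsorted(times, t_cells, side="left")
    if np.any(np.diff(trigger_scans) < 1):
        raise ValueError("infeasible config: cell events collide at this scan rate")

    bg_starts = np.maximum(0, trigger_scans - 10)
    events = []
    for k in range(cfg.n_cells):
        ext_end = int(bg_starts[k + 1]) if k + 1 < cfg.n_cells else n_scans
        events.append(
            TrueEvent(
                cell_id=k + 1,
                time=float(times[trigger_scans[k]]),
                trigger_scan=int(trigger_scans[k]),
                background_window=(int(bg_starts[k]), int(trigger_scans[k])),
                peak_window=(int(trigger_scans[k]), ext_end),
                extended_window=(int(bg_starts[k]), ext_end),
            )
        )

    # scan -> owning cell and offset from that cell's trigger
    owner = np.full(n_scans, -1, dtype=np.int64)
    offset = np.full(n_scans, -1, dtype=np.int64)
    for k, e in enumerate(events):
        p0, p1 = e.peak_window
        owner[p0:p1] = k
        offset[p0:p1] = np.arange(p1 - p0)

    # --- species table ---------------------------------------------------
    rows = []
    taken: list[float] = []

    def add_species(cls: str, mz: float | None = None, parent: int = -1,
                    carbon: int = 0) -> int:
        nonlocal taken
        if mz is None:
            mz = _place_mz(rng, cfg, taken)
        taken.append(mz)
        sid = len(rows)
        rows.append({"species_id": sid, "mz": float(mz), "cls": cls,
                     "carbon_count": carbon, "parent_id": parent})
        return sid

    add_species("high_sn", mz=cfg.marker_mz)  # the cell marker
    for _ in range(cfg.n_high_sn - 1):
        add_species("high_sn")
    for _ in range(cfg.n_low_sn):
        add_species("low_sn")
    for _ in range(cfg.n_background_static):
        add_species("background_static")
    for _ in range(cfg.n_background_drift):
        add_species("background_drift")
    for _ in range(cfg.n_background_spike):
        add_species("background_spike")
    for _ in range(cfg.n_internal_standards):
        add_species("internal_standard")
    for _ in range(cfg.n_blanks):
        add_species("solvent_blank")

    endo_ids = [r["species_id"] for r in rows if r["cls"] in ENDOGENOUS_CLASSES]
    for sid in endo_ids:
        if rng.random() < cfg.isotopologue_fraction:
            carbon = int(rng.integers(cfg.carbon_range[0], cfg.carbon_range[1] + 1))
            add_species("isotopologue", mz=rows[sid]["mz"] + 1.003355,
                        parent=sid, carbon=carbon)

    n_species = len(rows)
    species = pd.DataFrame(rows)

    # --- signal synthesis ------------------------------------------------
    def log_uniform(bounds):
        return float(np.exp(rng.uniform(np.log(bounds[0]), np.log(bounds[1]))))

    def bg_noise():
        """Heavy-tailed scan-to-scan fluctuation of background species.

        Solvent and contaminant ions fluctuate far more than shot noise
        (spray instability, clusters); a per-species lognormal spread
        makes some background species occasionally mimic real fold
        changes — the borderline cases statistical filtering struggles
        with.
        """
        sigma = rng.uniform(*cfg.background_lognorm_sigma)
        return rng.lognormal(-sigma * sigma / 2.0, sigma, n_scans)

    signal = np.zeros((n_species, n_scans))
    in_peak = owner >= 0
    for sid, row in enumerate(rows):
        cls = row["cls"]
        if cls == "isotopologue":
            continue  # filled from the parent below
        if cls in ENDOGENOUS_CLASSES:
            amp = log_uniform(
                cfg.high_sn_amplitude if cls == "high_sn" else cfg.low_sn_amplitude
            )
            if cls == "high_sn":
                baseline = amp / 10 ** rng.uniform(*cfg.high_sn_baseline_decades)
                presence = np.ones(cfg.n_cells, dtype=bool)
            else:
                baseline = amp / 10 ** rng.uniform(*cfg.low_sn_ratio_decades)
                p = rng.uniform(*cfg.low_sn_presence)
                presence = rng.random(cfg.n_cells) < p
            if sid == 0:
                presence[:] = True  # marker in every cell
            tau = rng.uniform(*cfg.decay_scans)
            n_extract = rng.uniform(*cfg.extract_scans)
            cell_amp = amp * rng.lognormal(0.0, cfg.cell_amplitude_sigma, cfg.n_cells)
            cell_amp[~presence] = 0.0
            kernel = _event_kernel(offset.astype(np.float64), cfg.rise_scans,
                                   tau, n_extract)
            v = np.zeros(n_scans)
            v[in_peak] = cell_amp[owner[in_peak]] * kernel[in_peak]
            v += baseline * np.clip(
                1.0 + cfg.background_noise_cv * rng.standard_normal(n_scans), 0.0, None
            )
        elif cls in ("background_static", "solvent_blank"):
            level = log_uniform(cfg.background_level)
            v = level * bg_noise()
        elif cls == "background_drift":
            level = log_uniform(cfg.background_level)
            a = rng.uniform(*cfg.drift_amplitude)
            period = rng.uniform(10.0, 40.0)
            phase = rng.uniform(0, 2 * np.pi)
            slope = rng.uniform(-0.3, 0.3)
            shape = 1.0 + a * np.sin(2 * np.pi * times / period + phase) \
                + slope * times / times[-1]
            v = level * np.clip(shape, 0.05, None) * bg_noise()
        elif cls == "background_spike":
            level = log_uniform(cfg.spike_level)
            v = level * bg_noise()
            for _ in range(int(rng.integers(1, 3))):  # one or two spikes
                at = int(rng.integers(0, n_scans))
                gain = rng.uniform(*cfg.spike_gain)
                tau = rng.uniform(*cfg.decay_scans)
                n_extract = rng.uniform(*cfg.extract_scans)
                span = np.arange(at, min(n_scans, at + int(np.ceil(n_extract)) + 1))
                v[span] += level * gain * _event_kernel(
                    (span - at).astype(np.float64), cfg.rise_scans, tau, n_extract
                )
        elif cls == "internal_standard":
            level = log_uniform(cfg.is_level)
            v = level * bg_noise()
        signal[sid] = v

    for sid, row in enumerate(rows):
        if row["cls"] == "isotopologue":
            ratio = 0.011 * row["carbon_count"]
            signal[sid] = ratio * signal[row["parent_id"]]

    emitted = np.where(signal >= cfg.centroid_floor, signal, 0.0)

    # --- ground-truth per-cell sums over the true peak windows ----------
    cell_intensity = np.zeros((n_species, cfg.n_cells))
    for k, e in enumerate(events):
        p0, p1 = e.peak_window
        cell_intensity[:, k] = emitted[:, p0:p1].sum(axis=1)

    # --- assemble centroided spectra -------------------------------------
    true_mz = species["mz"].to_numpy()
    jitter = rng.standard_normal((n_species, n_scans)) * cfg.mass_jitter_ppm
    mz_obs = true_mz[:, None] * (1.0 + jitter * 1e-6)

    spectra = []
    for i in range(n_scans):
        present = np.flatnonzero(emitted[:, i] > 0)
        mzs = mz_obs[present, i]
        ints = emitted[present, i]
        order = np.argsort(mzs, kind="stable")
        mzs, ints = mzs[order], ints[order]
        if mzs.size > 1:  # merge exact ties to keep m/z strictly ascending
            dup = np.diff(mzs) == 0
            if dup.any():
                keep = np.concatenate([[True], ~dup])
                grp = np.cumsum(keep) - 1
                merged_int = np.zeros(int(keep.sum()))
                np.add.at(merged_int, grp, ints)
                mzs, ints = mzs[keep], merged_int
        spectra.append(
            Spectrum(scan_index=i, retention_time=float(times[i]),
                     mz=mzs, intensity=ints)
        )

    run = Run(spectra=spectra, source_path="<simulated>", polarity="positive",
              mz_range=(cfg.mz_range[0] - 1.0, cfg.mz_range[1] + 2.0))
    gt = GroundTruth(config=cfg, events=events, species=species,
                     cell_intensity=cell_intensity, times=times)
    return run, gt


def score_detection(detected, gt: GroundTruth, pre_slack: int = 3):
    """Compare detected cell events against the simulated truth.

    A detected trigger matches the (unique) true event whose peak
    window contains it, allowing ``pre_slack`` scans of early
    triggering.  Returns ``(recall, n_false)``: the fraction of true
    events matched and the number of detections matching no true event
    (a true event matched twice counts the surplus as false —
    the peak-splitting failure mode).
    """
    matched = np.zeros(len(gt.events), dtype=bool)
    n_false = 0
    for d in detected:
        hit = False
        for k, e in enumerate(gt.events):
            if e.trigger_scan - pre_slack <= d.trigger_scan < e.peak_window[1]:
                if matched[k]:
                    n_false += 1
                matched[k] = True
                hit = True
                break
        if not hit:
            n_false += 1
    recall = matched.sum() / len(gt.events) if gt.events else 0.0
    return float(recall), int(n_false)


_TAG_BY_CLASS = {"internal_standard": "internal_standard",
                 "solvent_blank": "solvent_blank"}


def export_truth(gt: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write the ground truth as CSV files matching the consumer formats.

    * ``events.csv`` — start/end times (minutes) of each extended
      window, readable by :func:`cellogram.io.read_peak_list_csv`.
    * ``species.csv`` — m/z, name, class tag (readable by
      :func:`cellogram.io.read_mz_list_csv`), plus the true chronogram
      class, carbon count and isotopologue parent link.
    * ``cell_intensity.csv`` — true per-cell summed intensity,
      one row per species.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["events"] = out_dir / "events.csv"
    with open(paths["events"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_time_min", "end_time_min"])
        for e in gt.events:
            e0, e1 = e.extended_window
            end = gt.times[e1 - 1] if e1 - 1 < gt.times.size else gt.times[-1]
            w.writerow([f"{gt.times[e0]:.6f}", f"{end:.6f}"])

    paths["species"] = out_dir / "species.csv"
    with open(paths["species"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mz", "name", "class_tag", "true_class",
                    "carbon_count", "parent_id"])
        for row in gt.species.itertuples(index=False):
            tag = _TAG_BY_CLASS.get(row.cls, "target")
            parent = "" if row.parent_id < 0 else str(row.parent_id)
            w.writerow([f"{row.mz:.6f}", f"species_{row.species_id}", tag,
                        row.cls, row.carbon_count or "", parent])

    paths["cell_intensity"] = out_dir / "cell_intensity.csv"
    with open(paths["cell_intensity"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species_id"] + [f"cell_{k + 1}" for k in
                                     range(gt.cell_intensity.shape[1])])
        for sid in range(gt.cell_intensity.shape[0]):
            w.writerow([sid] + [f"{v:.6f}" for v in gt.cell_intensity[sid]])
    return paths
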