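"""Cellographic peak detection on extracted ion chronograms.

A direct-infusion single-cell run is a *cellogram*: a continuous
acquisition in which every sampled cell produces a transient rise in
the chronogram of an abundant endogenous marker ion.  Detection scans
the marker EIC left to right; a cell event triggers at the first scan
whose S/N (or absolute intensity) reaches the threshold, after which a
refractory period suppresses re-triggering on the decaying tail of the
same cell.

Window conventions (per event, half-open scan ranges):

* ``background_window`` — the ``background_scans`` scans immediately
  before the trigger, used as the per-cell background reference.
* ``extended_window`` — from this event's background start (optionally
  pre-extended) up to the next event's background start (run end for
  the last event).  Extended windows tile the run without overlap.
* ``peak_window`` — trigger to extended-window end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Run

__all__ = [
    "EICProfile",
    "CellEvent",
    "DetectionParams",
    "extract_eic",
    "extract_eics",
    "estimate_noise",
    "detect_cell_events",
    "edit_events",
    "success_rate",
]


@dataclass
class EICProfile:
    """Per-scan summed intensity of one m/z species across a run."""

    mz_center: float
    ppm_tol: float
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class CellEvent:
    """One cellographic peak: the data window of a single sampled cell."""

    cell_id: int
    trigger_scan: int
    background_window: tuple[int, int]
    peak_window: tuple[int, int]
    extended_window: tuple[int, int]


@dataclass
class DetectionParams:
    """Automatic detection settings.

    ``sn_threshold`` is a unitless S/N in the default ``"sn"`` mode, or
    an absolute intensity when ``threshold_mode="intensity"``.  The
    refractory period (minutes) is the minimum spacing between
    triggers; it is measured from the previous trigger time.
    """

    marker_mz: float = 0.0
    ppm_tol: float = 5.0
    sn_threshold: float = 10.0
    refractory_period: float = 0.2
    threshold_mode: str = "sn"
    background_scans: int = 10
    pre_extension_scans: int = 0

    def __post_init__(self) -> None:
        if self.sn_threshold <= 0:
            raise ValueError("sn_threshold must be > 0")
        if self.refractory_period <= 0:
            raise ValueError("refractory_period must be > 0")
        if self.background_scans < 1:
            raise ValueError("background_scans must be >= 1")
        if self.threshold_mode not in ("sn", "intensity"):
            raise ValueError("threshold_mode must be 'sn' or 'intensity'")


def extract_eic(run: Run, mz_center: float, ppm_tol: float) -> EICProfile:
    """Extract the ion chronogram of ``mz_center`` ± ``ppm_tol``.

    Each scan contributes the sum of centroid intensities with
    ``|mz - mz_center| / mz_center * 1e6 <= ppm_tol`` (binary search on
    the sorted m/z array); scans with no matching centroid contribute 0.
    """
    lo, hi = run.mz_range
    if not lo <= mz_center <= hi:
        raise ValueError(
            f"mz_center {mz_center} outside run mz_range [{lo}, {hi}]"
        )
    delta = mz_center * ppm_tol * 1e-6
    low, high = mz_center - delta, mz_center + delta
    values = np.zeros(run.n_scans)
    for i, s in enumerate(run.spectra):
        a = np.searchsorted(s.mz, low, side="left")
        b = np.searchsorted(s.mz, high, side="right")
        if b > a:
            values[i] = s.intensity[a:b].sum()
    return EICProfile(mz_center=mz_center, ppm_tol=ppm_tol,
                      times=run.times, values=values)


def extract_eics(run: Run, mz_centers, ppm_tol: float) -> np.ndarray:
    """Bulk EIC extraction: one row per center, one column per scan.

    Equivalent to calling :func:`extract_eic` per center but pools all
    centroids once, which is much faster for hundreds of species.
    """
    mz_centers = np.asarray(mz_centers, dtype=np.float64)
    n_scans = run.n_scans
    all_mz = np.concatenate([s.mz for s in run.spectra]) if n_scans else np.empty(0)
    all_int = np.concatenate([s.intensity for s in run.spectra]) if n_scans else np.empty(0)
    scan_ids = np.concatenate(
        [np.full(s.mz.size, i, dtype=np.int64) for i, s in enumerate(run.spectra)]
    ) if n_scans else np.empty(0, dtype=np.int64)
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int, scan_ids = all_mz[order], all_int[order], scan_ids[order]

    out = np.zeros((mz_centers.size, n_scans))
    for j, c in enumerate(mz_centers):
        delta = c * ppm_tol * 1e-6
        a = np.searchsorted(all_mz, c - delta, side="left")
        b = np.searchsorted(all_mz, c + delta, side="right")
        if b > a:
            np.add.at(out[j], scan_ids[a:b], all_int[a:b])
    return out


def estimate_noise(eic) -> float:
    """Robust noise scale of an EIC baseline.

    ``1.4826 x median(|v - median(v)|)`` over the values below the EIC
    median — i.e. the spread of the baseline side of the trace, which
    for a Gaussian baseline recovers its standard deviation while
    ignoring the cell peaks above.  Degenerate traces fall back to the
    smallest positive value observed (1.0 for an all-zero trace), so
    the estimate is always positive and S/N always finite.
    """
    values = np.asarray(getattr(eic, "values", eic), dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty EIC")
    positive = values[values > 0]
    if positive.size == 0:
        return 1.0
    med = np.median(values)
    below = values[values < med]
    noise = 1.4826 * float(np.median(np.abs(below - med))) if below.size else 0.0
    if noise <= 0:
        noise = float(positive.min())
    return noise


def _build_events(trigger_scans, n_scans: int, params: DetectionParams) -> list[CellEvent]:
    """Window construction shared by automatic detection and manual edits."""
    triggers = sorted(int(t) for t in trigger_scans)
    bg_starts = [max(0, t - params.background_scans) for t in triggers]
    ext_starts = [max(0, b - params.pre_extension_scans) for b in bg_starts]
    events = []
    for k, t in enumerate(triggers):
        # each extended window ends where the next event's begins, so the
        # windows tile the run without overlap even when pre-extended
        ext_end = ext_starts[k + 1] if k + 1 < len(triggers) else n_scans
        events.append(
            CellEvent(
                cell_id=k + 1,
                trigger_scan=t,
                background_window=(bg_starts[k], t),
                peak_window=(t, ext_end),
                extended_window=(ext_starts[k], ext_end),
            )
        )
    return events


def detect_cell_events(eic: EICProfile, params: DetectionParams) -> list[CellEvent]:
    """Automatically identify cellographic peaks in a marker EIC.

    A trigger fires at the first scan with score >= threshold
    (inclusive) outside the refractory span of the previous trigger.
    Score is ``value / noise`` in S/N mode (noise from
    :func:`estimate_noise`) or the raw value in intensity mode.
    """
    times, values = eic.times, eic.values
    if times.size and times[-1] - times[0] < params.refractory_period:
        warnings.warn(
            "refractory period exceeds run duration; at most one event"
        )
    if params.threshold_mode == "sn":
        scores = values / estimate_noise(eic)
    else:
        scores = values
    above = scores >= params.sn_threshold
    triggers = []
    last_time = -np.inf
    for i in np.flatnonzero(above):
        if times[i] - last_time >= params.refractory_period - 1e-12:
            triggers.append(i)
            last_time = times[i]
    return _build_events(triggers, values.size, params)


def edit_events(
    eic: EICProfile,
    params: DetectionParams,
    events: list[CellEvent],
    add: list[float] = (),
    remove: list[int] = (),
) -> list[CellEvent]:
    """Manually add (by trigger time, minutes) or delete (by id) events.

    The remaining triggers are re-windowed and renumbered 1..n exactly
    as in :func:`detect_cell_events`.  An added trigger falling within
    the refractory span of another trigger is rejected with a warning,
    keeping the edited list consistent with the detection rule.
    """
    known = {e.cell_id for e in events}
    for cid in remove:
        if cid not in known:
            raise ValueError(f"unknown cell_id: {cid}")
    kept = [e.trigger_scan for e in events if e.cell_id not in set(remove)]
    times = eic.times
    trigger_times = sorted(times[t] for t in kept)
    for t_add in add:
        if times.size and not (times[0] <= t_add <= times[-1]):
            raise ValueError(f"added trigger time {t_add} outside run duration")
        if any(abs(t_add - t) < params.refractory_period for t in trigger_times):
            warnings.warn(
                f"added trigger at {t_add:.3f} min is within the refractory "
                "span of an existing event; rejected"
            )
            continue
        scan = int(np.searchsorted(times, t_add, side="left"))
        scan = min(scan, times.size - 1)
        kept.append(scan)
        trigger_times.append(t_add)
        trigger_times.sort()
    return _build_events(sorted(set(kept)), times.size, params)


def success_rate(identified: int, known_total: int) -> int:
    """Percent of known cells identified, rounded to the nearest integer.

    Half-up rounding, matching how the published success-rate column is
    reported (e.g. 84 of 93 -> 90, 98 of 99 -> 99).
    """
    if known_total <= 0:
        raise ValueError("known_total must be > 0")
    if not 0 <= identified <= known_total:
        raise ValueError("identified must be within [0, known_total]")
    return int(math.floor(100.0 * identified / known_total + 0.5))
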