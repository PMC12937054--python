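"""ppm-tolerance m/z alignment into feature groups.

High-resolution FTMS m/z values drift slightly between scans, so
features are aligned by relative (ppm) tolerance rather than static
bins.  Grouping is greedy over the sorted m/z values: a new group
starts when the next value deviates from the current group's running
intensity-weighted mean by more than the tolerance.  Sorting first
makes the partition deterministic and invariant to input order.

Alignment runs in two stages to keep the problem small: first within
each cellographic peak (producing one integrated m/z per species per
cell), then across the per-cell representatives of all peaks.  A third
stage merges the feature tables of multiple processed files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import CellEvent
from .io import Run

__all__ = [
    "FeatureGroup",
    "CellFeatureTable",
    "group_mz",
    "align_within_event",
    "align_across_events",
    "align_across_files",
]


@dataclass
class FeatureGroup:
    """An aligned m/z species.

    ``members`` are ``(id, mz, intensity)`` tuples; the id is a scan
    index at event level, a cell id at run level, or a file-qualified
    cell id at experiment level.  Event-level groups additionally carry
    a per-scan intensity ``trace`` with the background-window subset
    flagged in ``background_scan_set`` so per-cell fold changes are
    computable downstream.
    """

    rep_mz: float
    members: list
    ppm_tol: float
    trace: dict | None = None
    background_scan_set: frozenset | None = None
    total_intensity: float = 0.0
    fold_change: float = 0.0


@dataclass
class CellFeatureTable:
    """Cells x features matrix of summed intensities and fold changes."""

    cell_ids: list
    features: list[FeatureGroup]
    intensity: np.ndarray
    fold_change: np.ndarray
    polarity: str = "positive"
    source: str = ""

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_mz(self) -> np.ndarray:
        return np.array([f.rep_mz for f in self.features])

    def select_features(self, keep) -> "CellFeatureTable":
        """Return a copy restricted to the given feature indices/mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CellFeatureTable(
            cell_ids=list(self.cell_ids),
            features=[self.features[i] for i in keep],
            intensity=self.intensity[:, keep].copy(),
            fold_change=self.fold_change[:, keep].copy(),
            polarity=self.polarity,
            source=self.source,
        )

    def to_dataframe(self):
        """Feature table as a DataFrame: one row per cell, columns by m/z."""
        import pandas as pd

        cols = [f"{f.rep_mz:.4f}" for f in self.features]
        df = pd.DataFrame(self.intensity, columns=cols)
        df.insert(0, "cell_id", self.cell_ids)
        return df

    def validate(self) -> None:
        if self.intensity.shape != (self.n_cells, self.n_features):
            raise ValueError("intensity matrix dimensions inconsistent")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        mzs = self.feature_mz
        if mzs.size > 1 and not np.all(np.diff(mzs) > 0):
            raise ValueError("feature rep_mz not strictly ascending")


def group_mz(observations, ppm_tol: float, weighted: bool = True) -> list[FeatureGroup]:
    """Group ``(id, mz, intensity)`` observations within a ppm tolerance.

    Observations are sorted by m/z and grouped greedily left to right;
    a new group starts when the candidate deviates from the running
    intensity-weighted mean (plain mean with ``weighted=False`` or when
    all member intensities are zero) by more than ``ppm_tol``.  The
    result partitions the input and is sorted by representative m/z.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("observations must be non-empty")
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be > 0")
    ids = [o[0] for o in obs]
    mzs = np.array([float(o[1]) for o in obs])
    ints = np.array([float(o[2]) for o in obs])
    if np.any(mzs <= 0):
        raise ValueError("non-positive m/z value")
    order = np.argsort(mzs, kind="stable")

    groups: list[FeatureGroup] = []
    cur: list[int] = []
    wsum = msum = csum = 0.0

    def mean() -> float:
        return wsum and msum / wsum or csum / len(cur)

    def flush() -> None:
        # clamp against 1-ulp drift of the weighted mean on tiny groups
        rep = min(max(mean(), float(mzs[cur[0]])), float(mzs[cur[-1]]))
        groups.append(
            FeatureGroup(
                rep_mz=rep,
                members=[(ids[i], float(mzs[i]), float(ints[i])) for i in cur],
                ppm_tol=ppm_tol,
            )
        )

    for i in order:
        x = mzs[i]
        if cur:
            m = mean()
            if (x - m) / m * 1e6 > ppm_tol:
                flush()
                cur, wsum, msum, csum = [], 0.0, 0.0, 0.0
        cur.append(i)
        w = ints[i] if weighted else 1.0
        wsum += w
        msum += w * x
        csum += x
    flush()
    return groups


def align_within_event(run: Run, event: CellEvent, ppm_tol: float,
                       weighted: bool = True) -> list[FeatureGroup]:
    """First alignment stage: group all centroids inside one cell event.

    Every centroid in the event's extended window enters the grouping;
    members from the background window are flagged rather than dropped,
    so each group exposes both its per-scan trace and the background
    subset needed for the fold-change computation.  The group's
    ``total_intensity`` integrates the peak window (trigger to extended
    end).
    """
    e0, e1 = event.extended_window
    b0, b1 = event.background_window
    p0, _p1 = event.peak_window
    obs = []
    for scan in range(e0, min(e1, run.n_scans)):
        s = run.spectra[scan]
        for mz, inten in zip(s.mz, s.intensity):
            obs.append((scan, mz, inten))
    if not obs:
        return []
    groups = group_mz(obs, ppm_tol, weighted=weighted)
    bg_set = frozenset(range(b0, b1))
    for g in groups:
        trace: dict[int, float] = {}
        for scan, _mz, inten in g.members:
            trace[scan] = trace.get(scan, 0.0) + inten
        g.trace = trace
        g.background_scan_set = bg_set
        g.total_intensity = float(
            sum(v for scan, v in trace.items() if scan >= p0)
        )
    return groups


def _event_fold_change(group: FeatureGroup, event: CellEvent,
                       n_background: int) -> float:
    from .filters import fold_change  # deferred: filters imports this module

    b0, b1 = event.background_window
    p0, p1 = event.peak_window
    bg = [group.trace.get(s, 0.0) for s in range(b0, b1)]
    peak = [group.trace.get(s, 0.0) for s in range(p0, p1)]
    if not peak:
        return 0.0
    return fold_change(peak, bg, n_background=n_background)


def align_across_events(per_event, ppm_tol: float,
                        n_background: int = 10,
                        events: list[CellEvent] | None = None,
                        polarity: str = "positive") -> CellFeatureTable:
    """Second alignment stage: merge per-cell integrated m/z values.

    ``per_event`` is a list of ``(cell_id, groups)`` pairs from
    :func:`align_within_event`.  Event-level representative m/z values
    are grouped again at the same tolerance; the matrix entry
    (cell, feature) is that cell's integrated intensity, zero when the
    species was not observed in the cell.  When ``events`` are given,
    per-cell fold changes are computed from each group's trace.
    """
    if not per_event:
        raise ValueError("at least one event required")
    cell_ids = [cid for cid, _ in per_event]
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("duplicate cell_ids")
    event_by_cell = {}
    if events is not None:
        by_id = {e.cell_id: e for e in events}
        event_by_cell = {cid: by_id[cid] for cid, _ in per_event if cid in by_id}

    obs = []
    meta = []  # parallel to obs: (cell_index, group)
    for ci, (cid, groups) in enumerate(per_event):
        for g in groups:
            obs.append(((ci, len(meta)), g.rep_mz, g.total_intensity))
            meta.append((ci, cid, g))
    if not obs:
        raise ValueError("no feature groups in any event")
    merged = group_mz(obs, ppm_tol)

    n_cells, n_feat = len(per_event), len(merged)
    intensity = np.zeros((n_cells, n_feat))
    fc = np.zeros((n_cells, n_feat))
    features = []
    for j, g in enumerate(merged):
        members = []
        for (ci, mi), mz, inten in g.members:
            _ci, cid, src = meta[mi]
            intensity[ci, j] += src.total_intensity
            if src.trace is not None and cid in event_by_cell:
                f = _event_fold_change(src, event_by_cell[cid], n_background)
            else:
                f = src.fold_change
            fc[ci, j] = max(fc[ci, j], f)
            members.append((cid, mz, src.total_intensity))
        features.append(
            FeatureGroup(rep_mz=g.rep_mz, members=members, ppm_tol=ppm_tol)
        )
    table = CellFeatureTable(
        cell_ids=cell_ids,
        features=features,
        intensity=intensity,
        fold_change=fc,
        polarity=polarity,
    )
    table.validate()
    return table


def align_from_run(run: Run, events: list[CellEvent], ppm_tol: float,
                   n_background: int = 10) -> CellFeatureTable:
    """Convenience: both alignment stages from a run and detected events."""
    per_event = [
        (e.cell_id, align_within_event(run, e, ppm_tol)) for e in events
    ]
    per_event = [(cid, g) for cid, g in per_event if g]
    return align_across_events(per_event, ppm_tol,
                               n_background=n_background, events=events,
                               polarity=run.polarity)


def align_across_files(tables: list[CellFeatureTable], ppm_tol: float) -> CellFeatureTable:
    """Merge the feature tables of several processed files.

    Features are grouped across files by representative m/z; cells are
    concatenated with file-qualified ids so per-file provenance is
    retained.  Mixing polarities is an error.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    polarity = tables[0].polarity
    if any(t.polarity != polarity for t in tables):
        raise ValueError("mixed polarity tables cannot be aligned")

    obs = []
    for ti, t in enumerate(tables):
        weights = t.intensity.sum(axis=0)
        for fi, f in enumerate(t.features):
            obs.append(((ti, fi), f.rep_mz, float(weights[fi])))
    merged = group_mz(obs, ppm_tol)

    labels = [t.source or f"file{ti + 1}" for ti, t in enumerate(tables)]
    cell_ids = [f"{labels[ti]}:{cid}" for ti, t in enumerate(tables)
                for cid in t.cell_ids]
    offsets = np.cumsum([0] + [t.n_cells for t in tables])
    intensity = np.zeros((offsets[-1], len(merged)))
    fc = np.zeros_like(intensity)
    features = []
    for j, g in enumerate(merged):
        members = []
        for (ti, fi), mz, _w in g.members:
            t = tables[ti]
            rows = slice(offsets[ti], offsets[ti + 1])
            intensity[rows, j] += t.intensity[:, fi]
            fc[rows, j] = np.maximum(fc[rows, j], t.fold_change[:, fi])
            members.extend(
                (f"{labels[ti]}:{cid}", mz, inten)
                for cid, _mz, inten in t.features[fi].members
            )
        features.append(FeatureGroup(rep_mz=g.rep_mz, members=members,
                                     ppm_tol=ppm_tol))
    out = CellFeatureTable(cell_ids=cell_ids, features=features,
                           intensity=intensity, fold_change=fc,
                           polarity=polarity)
    out.validate()
    return out
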