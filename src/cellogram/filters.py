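"""Statistical background-removal cascade for cell feature tables.

Direct-infusion spectra carry thousands of background m/z values from
solvent, contaminants and ionisation artifacts.  The cascade removes
them with cumulative filters, ordered so endogenous losses come last:

* **FC** (fold change) — per cell, the highest in-peak intensity
  divided by the mean background intensity before the peak; acts as an
  S/N filter.  Default threshold 3.
* **DF** (detection frequency) — fraction of cells in which a species
  passes the FC filter; sporadic species below the threshold (default
  33%) are dropped.
* **Deisotoping** — removes M+1 carbon-13 isotopologues: a feature
  ~1.003355 Th above another with a consistently small intensity ratio.
* **IS / solvent-blank exclusion** — m/z match against known lists.
* **MDF** (mass-defect filter) — drops features whose fractional mass
  falls in user-chosen ranges; opt-in, since useful ranges are
  data-set specific.

All threshold comparisons are inclusive (>=).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import CellFeatureTable, FeatureGroup
from .detection import estimate_noise

__all__ = [
    "FilterConfig",
    "FilterStep",
    "FilterReport",
    "BinaryMetrics",
    "DEFAULT_ORDER",
    "fold_change",
    "fc_filter",
    "df_filter",
    "deisotope",
    "exclusion_filter",
    "mass_defect_filter",
    "run_cascade",
    "binary_metrics",
]

DEFAULT_ORDER = ("fc", "df", "deisotope", "is_exclusion", "mdf", "blank_exclusion")

ISOTOPE_DELTA = 1.003355  # Th, 13C - 12C


@dataclass
class FilterConfig:
    fc_threshold: float = 3.0
    df_threshold: float = 0.33
    background_scans: int = 10
    isotope_delta: float = ISOTOPE_DELTA
    isotope_ppm_tol: float = 10.0
    isotope_max_ratio: float = 0.6
    exclusion_ppm_tol: float = 5.0
    mdf_ranges: tuple = ()
    is_list: tuple = ()
    blank_list: tuple = ()

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.df_threshold <= 1:
            raise ValueError("df_threshold must be in (0, 1]")
        for lo, hi in self.mdf_ranges:
            if not (0 <= lo < 1 and 0 <= hi <= 1):
                raise ValueError("mdf ranges must lie within [0, 1)")


@dataclass
class FilterStep:
    name: str
    features_in: int
    features_out: int


@dataclass
class FilterReport:
    steps: list[FilterStep] = field(default_factory=list)
    retained_endogenous: float | None = None
    retained_background: float | None = None


@dataclass
class BinaryMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else None


def fold_change(peak_trace, background_trace, n_background: int = 10,
                noise_floor: float | None = None) -> float:
    """Highest in-peak intensity over the mean pre-peak background.

    The background mean uses the last ``n_background`` background
    values.  When that mean is zero (species absent before the peak),
    the noise floor of the trace substitutes for the denominator so the
    fold change stays finite and comparable across species.
    """
    peak = np.asarray(peak_trace, dtype=np.float64)
    bg = np.asarray(background_trace, dtype=np.float64)
    if peak.size == 0:
        raise ValueError("peak_trace must be non-empty")
    denom = float(bg[-n_background:].mean()) if bg.size else 0.0
    if denom <= 0:
        if noise_floor is None:
            noise_floor = estimate_noise(bg) if bg.size else 1.0
        denom = noise_floor
    return float(peak.max()) / denom


def fc_filter(table: CellFeatureTable, cfg: FilterConfig):
    """Apply the fold-change detection filter.

    Returns the table restricted to features passing in at least one
    cell, together with the per-cell pass mask (cells x features,
    aligned with the returned table) marking where FC >= threshold.
    """
    mask = table.fold_change >= cfg.fc_threshold
    keep = mask.any(axis=0)
    return table.select_features(keep), mask[:, keep]


def df_filter(mask: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Detection-frequency filter on an FC pass mask.

    Keeps features passing the FC filter in at least ``df_threshold``
    of the cells (inclusive).  Returns a boolean feature mask.
    """
    n_cells = mask.shape[0]
    if n_cells == 0:
        return np.zeros(mask.shape[1], dtype=bool)
    return mask.sum(axis=0) / n_cells >= cfg.df_threshold


def deisotope(features: list[FeatureGroup], table: CellFeatureTable,
              cfg: FilterConfig) -> np.ndarray:
    """Drop M+1 carbon-13 isotopologues.

    Feature B is dropped when some feature A sits ``isotope_delta``
    below it (within ``isotope_ppm_tol``, relative to B) and the median
    intensity ratio B/A over cells detecting both is at most
    ``isotope_max_ratio``.  The ratio guard keeps distinct species that
    merely land one dalton apart.  Singly charged species are assumed
    (direct-infusion small molecules).
    """
    mzs = np.array([f.rep_mz for f in features])
    keep = np.ones(mzs.size, dtype=bool)
    for b in range(mzs.size):
        target = mzs[b] - cfg.isotope_delta
        tol = mzs[b] * cfg.isotope_ppm_tol * 1e-6
        for a in range(b):
            if abs(mzs[a] - target) > tol:
                continue
            both = (table.intensity[:, a] > 0) & (table.intensity[:, b] > 0)
            if not both.any():
                continue
            ratio = np.median(table.intensity[both, b] / table.intensity[both, a])
            if ratio <= cfg.isotope_max_ratio:
                keep[b] = False
                break
    return keep


def exclusion_filter(features: list[FeatureGroup], mz_list,
                     ppm_tol: float) -> np.ndarray:
    """Drop features matching any listed m/z within ``ppm_tol``."""
    mzs = np.array([f.rep_mz for f in features])
    keep = np.ones(mzs.size, dtype=bool)
    for entry in mz_list:
        target = getattr(entry, "mz", entry)
        keep &= np.abs(mzs - target) > target * ppm_tol * 1e-6
    return keep


def _merge_ranges(ranges) -> list[tuple[float, float]]:
    plain = sorted((lo, hi) for lo, hi in ranges if lo <= hi)
    wrapped = [(lo, hi) for lo, hi in ranges if lo > hi]
    merged: list[list[float]] = []
    for lo, hi in plain:
        if merged and lo < merged[-1][1]:
            warnings.warn("overlapping mass-defect ranges merged")
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(r) for r in merged] + wrapped


def mass_defect_filter(features: list[FeatureGroup], mdf_ranges) -> np.ndarray:
    """Drop features whose fractional mass lies in a half-open range.

    A range with ``low > high`` wraps around 1.0 (e.g. (0.9, 0.1)
    covers [0.9, 1) and [0, 0.1)).
    """
    mzs = np.array([f.rep_mz for f in features])
    frac = mzs - np.floor(mzs)
    keep = np.ones(mzs.size, dtype=bool)
    for lo, hi in _merge_ranges(mdf_ranges):
        if lo <= hi:
            keep &= ~((frac >= lo) & (frac < hi))
        else:
            keep &= ~((frac >= lo) | (frac < hi))
    return keep


def run_cascade(table: CellFeatureTable, cfg: FilterConfig,
                order=DEFAULT_ORDER, truth=None):
    """Apply the filters cumulatively and account for retention.

    ``truth``, when given, is a per-feature label sequence (aligned
    with the input table) with values ``"endogenous"`` or
    ``"background"``; the report then carries the percentage of each
    class retained by the full cascade, the same accounting used to
    evaluate filter capacity against annotated data.
    """
    unknown = set(order) - set(DEFAULT_ORDER)
    if unknown:
        raise ValueError(f"unknown cascade steps: {sorted(unknown)}")
    if truth is not None and len(truth) != table.n_features:
        raise ValueError("truth labels must cover all features")

    current = table
    mask = current.fold_change >= cfg.fc_threshold
    alive = list(range(table.n_features))  # indices into the input table
    report = FilterReport()

    for step in order:
        n_in = current.n_features
        if step == "fc":
            keep = mask.any(axis=0)
        elif step == "df":
            keep = df_filter(mask, cfg)
        elif step == "deisotope":
            keep = deisotope(current.features, current, cfg)
        elif step == "is_exclusion":
            keep = exclusion_filter(current.features, cfg.is_list,
                                    cfg.exclusion_ppm_tol)
        elif step == "mdf":
            keep = mass_defect_filter(current.features, cfg.mdf_ranges)
        elif step == "blank_exclusion":
            keep = exclusion_filter(current.features, cfg.blank_list,
                                    cfg.exclusion_ppm_tol)
        current = current.select_features(keep)
        mask = mask[:, keep]
        alive = [i for i, k in zip(alive, keep) if k]
        report.steps.append(FilterStep(step, n_in, current.n_features))

    if truth is not None:
        labels = np.asarray(truth)
        endo = labels == "endogenous"
        bg = labels == "background"
        kept = np.zeros(table.n_features, dtype=bool)
        kept[alive] = True
        if endo.any():
            report.retained_endogenous = 100.0 * (kept & endo).sum() / endo.sum()
        if bg.any():
            report.retained_background = 100.0 * (kept & bg).sum() / bg.sum()
    return current, report


def binary_metrics(predicted_endogenous, truth) -> BinaryMetrics:
    """Confusion counts for endogenous-vs-background predictions.

    ``predicted_endogenous`` is a boolean sequence (or index set) over
    the features; ``truth`` the matching label sequence.  Sensitivity
    is TP/(TP+FN) over the endogenous class, specificity TN/(TN+FP)
    over the background class; either is ``None`` when its truth class
    is empty.
    """
    labels = np.asarray(truth)
    pred = np.asarray(predicted_endogenous)
    if pred.dtype != bool:
        idx = pred
        pred = np.zeros(labels.size, dtype=bool)
        pred[list(idx)] = True
    if pred.size != labels.size:
        raise ValueError("prediction and truth lengths differ")
    endo = labels == "endogenous"
    return BinaryMetrics(
        tp=int((pred & endo).sum()),
        fn=int((~pred & endo).sum()),
        tn=int((~pred & ~endo).sum()),
        fp=int((pred & ~endo).sum()),
    )
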