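"""Targeted matching, normalization and internal-standard quantification.

The targeted workflow matches a user-supplied m/z list against the
aligned feature table at a ppm tolerance and, when an internal
standard (IS) of known concentration was co-infused, converts per-cell
intensity ratios into concentrations.  Quantification is single-point
with an assumed response factor of 1 (a per-target response factor can
be supplied when one has been measured); being a ratio, it is
invariant to any global intensity calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import CellFeatureTable

__all__ = ["TargetMatch", "match_targets", "quantify", "normalize"]


@dataclass
class TargetMatch:
    """Outcome of matching one target m/z against the feature table."""

    name: str
    target_mz: float
    feature_index: int | None = None
    feature_mz: float | None = None
    ppm_error: float | None = None
    intensities: np.ndarray | None = None  # per-cell, copied from the table

    @property
    def matched(self) -> bool:
        return self.feature_index is not None


def _target_tuple(t):
    if hasattr(t, "mz"):
        return float(t.mz), getattr(t, "name", "") or ""
    if isinstance(t, (int, float)):
        return float(t), ""
    return float(t[0]), (t[1] if len(t) > 1 else "")


def match_targets(table: CellFeatureTable, targets, ppm_tol: float) -> list[TargetMatch]:
    """Match each target to its nearest feature within ``ppm_tol``.

    Matching is one-to-one: when two targets fall within tolerance of
    the same feature, the closer (in ppm) wins and the other is
    reported unmatched.  The result is in input target order and is
    independent of that order.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be > 0")
    parsed = [_target_tuple(t) for t in targets]
    feat_mz = table.feature_mz
    candidates = []  # (|ppm|, target index, feature index, signed ppm)
    for ti, (tmz, _name) in enumerate(parsed):
        if feat_mz.size == 0:
            continue
        ppm = (feat_mz - tmz) / tmz * 1e6
        for fi in np.flatnonzero(np.abs(ppm) <= ppm_tol):
            candidates.append((abs(ppm[fi]), ti, int(fi), float(ppm[fi])))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    matches = [TargetMatch(name=name, target_mz=tmz)
               for tmz, name in parsed]
    used_targets: set[int] = set()
    used_features: set[int] = set()
    for _d, ti, fi, ppm in candidates:
        if ti in used_targets or fi in used_features:
            continue
        used_targets.add(ti)
        used_features.add(fi)
        m = matches[ti]
        m.feature_index = fi
        m.feature_mz = float(feat_mz[fi])
        m.ppm_error = ppm
        m.intensities = table.intensity[:, fi].copy()
    return matches


def quantify(match: TargetMatch, is_match: TargetMatch,
             is_concentration: float, response_factor: float = 1.0) -> np.ndarray:
    """Per-cell concentration of a matched target against a matched IS.

    ``quantity = target_intensity / IS_intensity * IS_concentration /
    response_factor`` per cell; cells where the IS was not detected
    yield NaN (missing).
    """
    if not (match.matched and is_match.matched):
        raise ValueError("both target and internal standard must be matched")
    target = match.intensities.astype(np.float64)
    ref = is_match.intensities.astype(np.float64)
    out = np.full(target.size, np.nan)
    ok = ref > 0
    out[ok] = target[ok] / ref[ok] * is_concentration / response_factor
    return out


def normalize(table: CellFeatureTable, mode: str,
              is_mz: float | None = None, ppm_tol: float = 5.0) -> CellFeatureTable:
    """Normalize each cell's intensity row.

    ``mode="tic"`` divides by the cell's total summed intensity;
    ``mode="is_ratio"`` divides by the cell's intensity of the internal
    standard feature nearest ``is_mz`` (within ``ppm_tol``).  Zeros
    propagate as zeros; a cell with a zero denominator becomes NaN with
    a warning.
    """
    if mode == "tic":
        denom = table.intensity.sum(axis=1)
    elif mode == "is_ratio":
        if is_mz is None:
            raise ValueError("is_ratio mode requires is_mz")
        feat_mz = table.feature_mz
        ppm = np.abs(feat_mz - is_mz) / is_mz * 1e6
        if feat_mz.size == 0 or ppm.min() > ppm_tol:
            raise ValueError(f"no feature within {ppm_tol} ppm of IS m/z {is_mz}")
        denom = table.intensity[:, int(np.argmin(ppm))]
    else:
        raise ValueError("mode must be 'tic' or 'is_ratio'")

    zero = denom <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) with zero denominator; set to NaN")
    scaled = np.where(zero[:, None], np.nan,
                      table.intensity / np.where(zero, 1.0, denom)[:, None])
    out = CellFeatureTable(
        cell_ids=list(table.cell_ids),
        features=list(table.features),
        intensity=scaled,
        fold_change=table.fold_change.copy(),
        polarity=table.polarity,
        source=table.source,
    )
    return out
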