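"""Deterministic rendering of EIC profiles as classifier input images.

The classifier judges a species by the *shape* of its chronogram, not
its absolute intensity, so the renderer normalises the y axis to the
trace maximum and draws an axis-free line plot on a white 224x224
canvas.  Rendering is versioned: a trained model records the renderer
version it was trained with, and classification refuses images from a
different renderer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from ..detection import CellEvent, EICProfile

__all__ = ["RENDERER_VERSION", "EICImage", "render_eic_image",
           "augment_by_event_count"]

RENDERER_VERSION = "1"

_SIZE = 224
_MARGIN = 6
_LINE_WIDTH = 2


@dataclass
class EICImage:
    """A rendered chronogram: fixed-size RGB pixel array plus provenance."""

    pixels: np.ndarray  # (224, 224, 3) uint8
    source_mz: float = 0.0
    renderer_version: str = RENDERER_VERSION


def render_eic_image(eic: EICProfile, source_mz: float | None = None) -> EICImage:
    """Render one EIC as a 224x224 line plot.

    Intensity is scaled linearly to [0, max] (max taken as 1 for an
    all-zero trace), drawn left to right by scan index with a fixed
    line width on a white background — no axes, ticks or text.
    Identical values yield byte-identical pixels, and scaling the trace
    by any positive constant leaves the image unchanged.
    """
    values = np.asarray(eic.values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty EIC")
    vmax = float(values.max())
    if vmax <= 0:
        vmax = 1.0
    norm = values / vmax

    img = Image.new("RGB", (_SIZE, _SIZE), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    span = _SIZE - 1 - 2 * _MARGIN
    n = values.size
    if n == 1:
        xs = np.array([_SIZE // 2], dtype=np.float64)
    else:
        xs = _MARGIN + np.arange(n) * (span / (n - 1))
    ys = (_SIZE - 1 - _MARGIN) - norm * span
    points = [(int(round(x)), int(round(y))) for x, y in zip(xs, ys)]
    if len(points) == 1:
        points = [points[0], points[0]]
    draw.line(points, fill=(0, 0, 0), width=_LINE_WIDTH)
    pixels = np.asarray(img, dtype=np.uint8).copy()
    return EICImage(pixels=pixels,
                    source_mz=eic.mz_center if source_mz is None else source_mz)


def augment_by_event_count(eic: EICProfile, events: list[CellEvent],
                           n_events: int) -> EICProfile:
    """Restrict an EIC to its first ``n_events`` cell windows.

    Concatenating only the leading extended windows changes the
    rendered magnification: few events give broad, Gaussian-looking
    peaks, many events give sharp, centroid-like ones.  Sweeping the
    count (10 up to ~100 in steps of 5) multiplies the training set
    per species.
    """
    if n_events < 5:
        raise ValueError("n_events must be >= 5")
    if n_events > len(events):
        raise ValueError(
            f"n_events={n_events} exceeds available events ({len(events)})"
        )
    ordered = sorted(events, key=lambda e: e.extended_window[0])[:n_events]
    idx = np.concatenate(
        [np.arange(e.extended_window[0], e.extended_window[1]) for e in ordered]
    )
    idx = idx[idx < eic.values.size]
    return EICProfile(mz_center=eic.mz_center, ppm_tol=eic.ppm_tol,
                      times=eic.times[idx], values=eic.values[idx])


def event_count_sweep(eic: EICProfile, events: list[CellEvent],
                      lo: int = 10, hi: int = 100, step: int = 5) -> list[EICProfile]:
    """The standard augmentation sweep, clipped to the available events."""
    hi = min(hi, len(events))
    return [augment_by_event_count(eic, events, n)
            for n in range(lo, hi + 1, step)]
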