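"""Image-derived shape features and per-event quality gates.

The deformation measure is the circularity deficit

.. math:: D = 1 - 2\\sqrt{\\pi A} / P,

where ``A`` is the projected area and ``P`` the perimeter of the imaged
contour; ``D = 0`` for a circle and ``D > 0`` for any other simple shape
(isoperimetric inequality).  Porosity — the ratio of convex-hull area to
contour area — flags non-convex, likely missegmented events (doublets,
misplaced contour lines).

Contours are pixel-coordinate polygons; area is the shoelace polygon area and
the perimeter the vertex-to-vertex Euclidean arc length (both evaluated by
shapely), times the appropriate powers of the pixel size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import InvalidContourError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PIXEL_UM",
    "Contour",
    "Event",
    "GateConfig",
    "deformation",
    "porosity",
    "contour_features",
    "pixelation_correct",
    "GridOffsetCorrection",
    "apply_gates",
]

#: Default camera resolution, um per pixel (340 nm).
DEFAULT_PIXEL_UM = 0.34


def deformation(area: float, perimeter: float) -> float:
    """Deformation D = 1 - 2*sqrt(pi*A)/P (unit-consistent A and P).

    Zero for a perfect circle, positive for every other simple shape, and in
    [0, 1) for any simple contour.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 1.0 - 2.0 * math.sqrt(math.pi * area) / perimeter


@dataclass(frozen=True)
class Contour:
    """A closed polygon in pixel coordinates.

    ``vertices`` is an (N, 2) array of (x, y) pixel positions, N >= 3; the
    first vertex is logically adjacent to the last (no need to repeat it).
    """

    vertices: np.ndarray
    pixel_um: float = DEFAULT_PIXEL_UM

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidContourError("contour needs an (N>=3, 2) vertex array")
        if self.pixel_um <= 0:
            raise InvalidContourError("pixel size must be positive")
        object.__setattr__(self, "vertices", v)

    def polygon(self) -> Polygon:
        poly = Polygon(self.vertices)
        if poly.area == 0:
            raise InvalidContourError("degenerate contour: zero area")
        return poly


@dataclass(frozen=True)
class Event:
    """Shape features of one imaged vesicle."""

    area_um2: float
    deform: float
    perimeter_um: float | None = None
    porosity: float | None = None
    qc_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("event area must be positive")
        if not 0 <= self.deform < 1:
            raise ValueError("deformation must be in [0, 1)")
        if self.porosity is not None and self.porosity < 1:
            raise ValueError("porosity must be >= 1")


def porosity(contour: Contour) -> float:
    """Ratio of convex-hull area to polygon area; >= 1, == 1 for convex input."""
    poly = contour.polygon()
    ratio = poly.convex_hull.area / poly.area
    return max(ratio, 1.0)  # guard against 1 - eps from float round-off


class GridOffsetCorrection:
    """Pixelation correction for the systematic deformation offset.

    Contours sampled on a pixel grid make even a perfect circle appear
    slightly deformed; the offset decreases with object size but is
    non-negligible for small objects.  This strategy subtracts a smooth
    offset model

    .. math:: \\Delta D(A) = c_0 + c_1 e^{-A/\\tau_1} + c_2 e^{-A/\\tau_2},

    with ``A`` the projected area in px^2.  The default coefficients are
    synthetic: they were fitted against this package's own rasterized circles
    (radii 8–60 px, :func:`guvmech.synthetic.rasterize_contour` grid
    sampling), not transcribed from an external source, and should be
    replaced by instrument-specific coefficients where available.
    """

    def __init__(
        self,
        c0: float = 0.0,
        c1: float = 3.507e-3,
        tau1: float = 9.934e3,
        c2: float = 1.337e-2,
        tau2: float = 519.2,
    ) -> None:
        self.coefficients = (c0, c1, tau1, c2, tau2)

    def offset(self, area_px2):
        c0, c1, t1, c2, t2 = self.coefficients
        a = np.asarray(area_px2, dtype=float)
        return c0 + c1 * np.exp(-a / t1) + c2 * np.exp(-a / t2)


_warned_identity = False


def pixelation_correct(deform, area_px2, correction=None):
    """Subtract the pixelation offset from measured deformations.

    ``correction`` is any object with an ``offset(area_px2)`` method (e.g.
    :class:`GridOffsetCorrection`); when None the input is returned unchanged
    with a one-time warning.  Corrected values are clamped at 0 — the
    correction must not produce negative deformation — and the correction
    magnitude vanishes in the large-object limit by construction of the
    offset models.
    """
    global _warned_identity
    deform = np.asarray(deform, dtype=float)
    if np.any(deform < 0) or np.any(np.asarray(area_px2, dtype=float) <= 0):
        raise ValueError("deformation must be >= 0 and area positive")
    if correction is None:
        if not _warned_identity:
            logger.warning(
                "no pixelation-correction coefficients configured; "
                "returning deformation unchanged"
            )
            _warned_identity = True
        return deform if deform.ndim else float(deform)
    out = np.maximum(deform - correction.offset(area_px2), 0.0)
    return out if out.ndim else float(out)


def contour_features(
    contour: Contour, correction=None
) -> Event:
    """Compute (A, P, D, porosity) for a contour; optional pixelation fix."""
    poly = contour.polygon()
    px = contour.pixel_um
    area_px2 = poly.area
    area_um2 = area_px2 * px**2
    perimeter_um = poly.length * px
    d_raw = deformation(area_um2, perimeter_um)
    d = pixelation_correct(d_raw, area_px2, correction) if correction else d_raw
    return Event(
        area_um2=area_um2,
        deform=float(d),
        perimeter_um=perimeter_um,
        porosity=porosity(contour),
    )


@dataclass(frozen=True)
class GateConfig:
    """Per-event quality gates (defaults follow the study's post-processing:
    A in [60, 225] um^2, D <= 0.1, porosity <= 1.03)."""

    area_range: tuple[float, float] = (60.0, 225.0)
    d_max: float = 0.1
    porosity_max: float = 1.03


def apply_gates(
    events: pd.DataFrame,
    gates: GateConfig = GateConfig(),
    calibration=None,
    setup=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an event table into (kept, rejected-with-qc_flags).

    ``events`` needs columns ``area_um`` and ``deform``; ``porosity`` is
    gated only when present.  Rejected rows carry a ``qc_flags`` column
    naming every failing gate.  The operation is idempotent: re-gating the
    kept set returns it unchanged.

    When a ``calibration`` and ``setup`` are supplied, events outside the
    stricter calibration-validity range (D and relative area of the
    simulated domain) are counted in a warning but **not** rejected.
    """
    flags = [[] for _ in range(len(events))]
    a = events["area_um"].to_numpy(dtype=float)
    d = events["deform"].to_numpy(dtype=float)
    lo, hi = gates.area_range
    for i in np.flatnonzero((a < lo) | (a > hi)):
        flags[i].append("area_range")
    for i in np.flatnonzero(d > gates.d_max):
        flags[i].append("deform_max")
    if "porosity" in events.columns:
        p = events["porosity"].to_numpy(dtype=float)
        for i in np.flatnonzero(p > gates.porosity_max):
            flags[i].append("porosity")
    bad = np.array([len(f) > 0 for f in flags], dtype=bool)
    kept = events.loc[~bad].copy()
    rejected = events.loc[bad].copy()
    rejected["qc_flags"] = [",".join(f) for f, b in zip(flags, bad) if b]
    if calibration is not None and setup is not None:
        from .scaling import nondim_area

        ahat = nondim_area(kept["area_um"].to_numpy(dtype=float), setup)
        outside = ~calibration.in_validity(kept["deform"].to_numpy(dtype=float), ahat)
        if outside.any():
            logger.warning(
                "%d of %d kept events lie outside the calibration validity "
                "range (D <= %g, A_hat in [%g, %g])",
                int(outside.sum()),
                len(kept),
                calibration.d_max,
                *calibration.ahat_range,
            )
    if len(kept) == 0:
        logger.warning("all %d events rejected by gates", len(events))
    return kept, rejected
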