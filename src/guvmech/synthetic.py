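"""Synthetic RT-DC-like event populations with known ground truth.

The generator is the forward model of the analysis: areas are drawn from a
population distribution, the noise-free deformation follows from the
calibrated response surface at the population's true modulus, and the
measured deformation is the true one times lognormal multiplicative noise
(measurement error on the non-negative deformation is multiplicative, hence
lognormal, with zero log-mean so the noise-free curve is the median).  A
configurable fraction of events are outliers whose deformation is inflated
by a uniform factor — mimicking vesicle doublets and misplaced contour
lines, which enlarge the apparent contour.

All randomness flows from the spec seed; identical specs give bitwise
identical output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from shapely.geometry import MultiPoint, Point

from .calibration import DEFAULT_CALIBRATION, Calibration
from .errors import GuvmechError
from .geometry import DEFAULT_PIXEL_UM, Contour
from .scaling import ChannelSetup
from .estimators import forward_D

__all__ = [
    "PopulationSpec",
    "MixtureSpec",
    "generate_events",
    "generate_mixture",
    "rasterize_contour",
    "doublet_contour",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Statistical description of one synthetic vesicle population.

    Defaults are the study conditions of the analysis: areas uniform on the
    gated range [60, 225] um^2, multiplicative lognormal deformation noise
    with log-SD 0.15, and 5% outliers with deformation inflated by a factor
    drawn uniformly from [1.5, 3].
    """

    n: int
    K: float  # true area expansion modulus, N/m
    seed: int
    area_range: tuple[float, float] = (60.0, 225.0)
    area_dist: str = "uniform"  # "uniform" | "lognormal" (truncated to range)
    area_ln_sigma: float = 0.35  # log-SD of the lognormal area option
    sigma_d: float = 0.15  # log-SD of the multiplicative deformation noise
    outlier_fraction: float = 0.05
    outlier_factor_range: tuple[float, float] = (1.5, 3.0)
    with_porosity: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.n <= 0 or self.K <= 0:
            raise ValueError("n and K must be positive")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier fraction must be in [0, 1]")
        if self.sigma_d < 0:
            raise ValueError("sigma_d must be >= 0")


@dataclass(frozen=True)
class MixtureSpec:
    """A blend of populations (e.g. 1000 soft + 1000 stiff vesicles)."""

    populations: tuple[PopulationSpec, ...]
    seed: int


def _sample_areas(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.area_range
    if spec.area_dist == "uniform":
        return rng.uniform(lo, hi, size=spec.n)
    if spec.area_dist == "lognormal":
        median = math.sqrt(lo * hi)
        out = np.empty(spec.n)
        filled = 0
        while filled < spec.n:  # rejection sampling onto the gated range
            draw = median * np.exp(rng.normal(0, spec.area_ln_sigma, size=spec.n))
            draw = draw[(draw >= lo) & (draw <= hi)]
            take = min(draw.size, spec.n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out
    raise ValueError(f"unknown area distribution {spec.area_dist!r}")


def generate_events(
    spec: PopulationSpec,
    setup: ChannelSetup,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one population; returns (events, truth) frames of equal length.

    ``events`` has the measured columns (``area_um``, ``deform`` and, when
    requested, ``porosity``); ``truth`` records the noise-free deformation,
    the true modulus, the outlier flag and the population label.
    """
    rng = np.random.default_rng(spec.seed)
    area = _sample_areas(spec, rng)
    d_true = forward_D(spec.K, area, setup, calib)
    d_obs = d_true * np.exp(rng.normal(0.0, spec.sigma_d, size=spec.n))
    is_outlier = rng.random(spec.n) < spec.outlier_fraction
    factors = rng.uniform(*spec.outlier_factor_range, size=spec.n)
    d_obs = np.where(is_outlier, d_obs * factors, d_obs)
    events = pd.DataFrame({"area_um": area, "deform": d_obs})
    if spec.with_porosity:
        por = 1.0 + rng.uniform(0.0, 0.01, size=spec.n)
        por = np.where(is_outlier, rng.uniform(1.035, 1.10, size=spec.n), por)
        events["porosity"] = por
    truth = pd.DataFrame(
        {
            "d_true": d_true,
            "k_true": spec.K,
            "is_outlier": is_outlier,
            "population": spec.label or "0",
        }
    )
    return events, truth


def generate_mixture(
    spec: MixtureSpec,
    setup: ChannelSetup,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge population draws with a seeded shuffle; truth labels retained."""
    frames, truths = [], []
    for i, pop in enumerate(spec.populations):
        if pop.n == 0:
            continue
        pop = pop if pop.label else dataclasses.replace(pop, label=str(i))
        ev, tr = generate_events(pop, setup, calib)
        frames.append(ev)
        truths.append(tr)
    if not frames:
        raise ValueError("mixture spec contains no events")
    events = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(events))
    return (
        events.iloc[order].reset_index(drop=True),
        truth.iloc[order].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# contour synthesis
# ---------------------------------------------------------------------------

def _capsule_aspect_for_deform(deform: float) -> float:
    """Solve the capsule (stadium) family for a requested deformation.

    A capsule of cap radius r and straight length l = t*r has
    A = r^2 (pi + 2 t), P = 2 r (pi + t), hence
    D(t) = 1 - sqrt(pi (pi + 2 t)) / (pi + t), which rises monotonically
    from 0 (circle) towards 1; any D in [0, ~0.9] is representable.
    """
    if deform < 0:
        raise GuvmechError("capsule shape family cannot represent D < 0")
    if deform == 0:
        return 0.0

    def f(t):
        return 1.0 - math.sqrt(math.pi * (math.pi + 2 * t)) / (math.pi + t) - deform

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise GuvmechError(
                f"deformation {deform} outside the capsule shape family"
            )
    return optimize.brentq(f, 0.0, hi, xtol=1e-12)


def _capsule_vertices(r: float, half_l: float, n_arc: int) -> np.ndarray:
    """Smooth boundary of a capsule centred at the origin (pixel units)."""
    th = np.linspace(-0.5 * np.pi, 0.5 * np.pi, n_arc)
    right = np.column_stack([half_l + r * np.cos(th), r * np.sin(th)])
    left = np.column_stack([-half_l - r * np.cos(th), r * np.sin(th)])[::-1]
    n_edge = max(2, int(2 * half_l))
    xs = np.linspace(half_l, -half_l, n_edge + 1)[1:-1]
    top = np.column_stack([xs, np.full(xs.size, r)])
    bottom = np.column_stack([-xs, np.full(xs.size, -r)])
    return np.vstack([right, top, left, bottom])


def _snap_to_grid(vertices: np.ndarray, pixel_um: float) -> Contour:
    snapped = np.round(vertices)
    keep = np.any(np.diff(snapped, axis=0, prepend=snapped[-1:]) != 0, axis=1)
    snapped = snapped[keep]
    if snapped.shape[0] < 3:
        raise GuvmechError("contour collapses below 3 vertices at this pixel size")
    return Contour(vertices=snapped, pixel_um=pixel_um)


def _snap_convex(vertices: np.ndarray, pixel_um: float) -> Contour:
    """Grid-snap then convexify — the contour convention of RT-DC features.

    Snapping a smooth convex boundary to the pixel grid yields a staircase
    whose arc length does not converge to the true perimeter; taking the
    convex hull of the snapped lattice points reproduces how deformation is
    computed from convexified contours in RT-DC, leaving only a small
    pixelation offset that decreases with object size.
    """
    snapped = np.unique(np.round(vertices), axis=0)
    if snapped.shape[0] < 3:
        raise GuvmechError("contour collapses below 3 vertices at this pixel size")
    hull = MultiPoint(snapped).convex_hull
    return Contour(vertices=np.asarray(hull.exterior.coords)[:-1], pixel_um=pixel_um)


def rasterize_contour(
    area_um2: float,
    deform: float,
    pixel_um: float = DEFAULT_PIXEL_UM,
) -> Contour:
    """Pixel-grid polygon of a bullet-like (capsule) shape with requested
    area and deformation.

    Vertices are sampled along the smooth capsule boundary at roughly
    one-pixel spacing and snapped to the integer grid, so the measured
    features carry a pixelation offset: the deformation is overestimated by
    roughly the :class:`~guvmech.geometry.GridOffsetCorrection` offset and
    the area reproduced to a few percent.  A requested deformation outside
    [0, ~0.9] is not representable by this family and raises.
    """
    if area_um2 <= 0:
        raise GuvmechError("area must be positive")
    t = _capsule_aspect_for_deform(deform)
    area_px2 = area_um2 / pixel_um**2
    r = math.sqrt(area_px2 / (math.pi + 2 * t))
    if r < 2.0:
        raise GuvmechError("shape smaller than ~2 px cap radius; not representable")
    half_l = 0.5 * t * r
    n_arc = max(16, int(math.pi * r))
    verts = _capsule_vertices(r, half_l, n_arc)
    return _snap_convex(verts, pixel_um)


def doublet_contour(
    area_um2: float,
    pixel_um: float = DEFAULT_PIXEL_UM,
    separation: float = 1.5,
) -> Contour:
    """Two overlapping rasterized circles — a vesicle doublet.

    ``separation`` is the centre distance in units of the circle radius
    (< 2 so the discs overlap).  The default 1.5 produces a pronounced
    waist with porosity well above the 1.03 gate.
    """
    if not 0 < separation < 2:
        raise GuvmechError("separation must be in (0, 2) radii for an overlap")
    area_px2 = area_um2 / pixel_um**2
    # total union area of two discs radius r at distance s*r:
    # 2 pi r^2 - lens(s); solve r numerically
    def union_area(r):
        d = separation * r
        lens = 2 * r**2 * math.acos(d / (2 * r)) - 0.5 * d * math.sqrt(
            4 * r**2 - d**2
        )
        return 2 * math.pi * r**2 - lens

    r = optimize.brentq(
        lambda r: union_area(r) - area_px2, 1.0, math.sqrt(area_px2)
    )
    d = separation * r
    union = Point(-d / 2, 0).buffer(r, quad_segs=max(16, int(r))) | Point(
        d / 2, 0
    ).buffer(r, quad_segs=max(16, int(r)))
    verts = np.asarray(union.exterior.coords)[:-1]
    return _snap_to_grid(verts, pixel_um)
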