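"""Synthetic IVCM-like images with analytically known ground truth.

The clinical images this package targets (subbasal nerve plexus frames from a
laser-scanning confocal microscope) cannot be redistributed, so this module
generates stand-ins with the properties that matter to the pipeline:

* bright, smooth, predominantly vertical nerve fibers whose exact arc length
  is known (the generating polyline *is* the ground-truth tracing);
* bright dendritic cells of two morphologies — compact ovoid bodies
  ("without dendrites") and bodies with radiating processes ("with
  dendrites") — of known count and class;
* a noisy dark background (Gaussian field + multiplicative speckle + blur).

Cohorts mirror the clinical design: two groups of subjects, two eyes per
subject, a fixed number of frames per eye, with subject-level latent
densities drawn from group distributions and per-image quantities varying
around the subject mean. Default group parameters correspond to manually
graded values in symptomatic vs. control cohorts: CNFL 17.3 +/- 3.8 vs
19.4 +/- 4.0 mm/mm^2; DC with dendrites 11.6 +/- 14.1 vs 6.6 +/- 6.0
cells/mm^2; DC without dendrites 59.8 +/- 53.4 vs 36.0 +/- 42.0 cells/mm^2.

The noise model is deliberately simple: it makes segmentation non-trivial
without attempting photorealism (no oblique sections, no keratocytes, no
other corneal layers).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .io import (
    CellAnnotation,
    CellClass,
    Eye,
    ImageRecord,
    NerveTracing,
)
from .units import DEFAULT_PIXEL_PITCH_UM, image_area_mm2

__all__ = [
    "SynthParams",
    "GroupSpec",
    "SyntheticSample",
    "CohortSample",
    "generate_sample",
    "generate_cohort",
    "DEFAULT_GROUP_SPECS",
]


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic image generator.

    ``nerve_slope_sd`` controls how far fibers deviate from vertical
    (horizontal drift per unit of vertical travel); the default keeps curves
    gently curved and predominantly vertical, matching how frames are
    selected for nerve grading. ``target_length_mm``, when set, overrides
    ``nerves_per_image``: fibers are added (the last one trimmed) until the
    total analytic arc length equals the target exactly.
    """

    image_shape: tuple[int, int] = (384, 384)
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    nerves_per_image: tuple[int, int] = (2, 5)
    nerve_slope_sd: float = 0.12
    nerve_intensity: tuple[float, float] = (120.0, 200.0)
    nerve_width_px: tuple[float, float] = (3.0, 5.0)
    target_length_mm: float | None = None
    dc_with_per_image: float = 0.5
    dc_without_per_image: float = 2.0
    cell_radius_px: tuple[float, float] = (3.0, 6.0)
    cell_intensity: tuple[float, float] = (140.0, 230.0)
    dendrite_process_count: tuple[int, int] = (2, 5)
    dendrite_length_px: tuple[float, float] = (5.0, 12.0)
    background_mean: float = 40.0
    background_noise_sd: float = 9.0
    speckle_sd: float = 0.10
    blur_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        for name in ("nerves_per_image", "nerve_intensity", "nerve_width_px",
                     "cell_radius_px", "cell_intensity",
                     "dendrite_process_count", "dendrite_length_px"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a non-negative (lo, hi) range")
        if self.dc_with_per_image < 0 or self.dc_without_per_image < 0:
            raise ValueError("cell count means must be non-negative")


@dataclass(frozen=True)
class GroupSpec:
    """Subject-level density distribution for one cohort group.

    Means and SDs are on the per-participant scale: CNFL in mm/mm^2, cell
    densities in cells/mm^2. All draws are truncated at zero.
    """

    name: str
    cnfl_mean: float
    cnfl_sd: float
    dc_with_mean: float
    dc_with_sd: float
    dc_without_mean: float
    dc_without_sd: float


DEFAULT_GROUP_SPECS: tuple[GroupSpec, GroupSpec] = (
    GroupSpec("group1", 17.3, 3.8, 11.6, 14.1, 59.8, 53.4),
    GroupSpec("group2", 19.4, 4.0, 6.6, 6.0, 36.0, 42.0),
)


@dataclass
class SyntheticSample:
    """One synthetic frame plus its exact ground truth."""

    image: ImageRecord
    tracing: NerveTracing
    true_nerve_length_mm: float
    annotation: CellAnnotation
    true_counts: tuple[int, int]


@dataclass
class CohortSample:
    """A cohort frame: the sample plus its subject/eye/group bookkeeping."""

    subject_id: str
    eye: Eye
    group: str
    sample: SyntheticSample
    latent_cnfl_density: float
    latent_dc_with_density: float
    latent_dc_without_density: float


# ---------------------------------------------------------------------------
# Nerve curves
# ---------------------------------------------------------------------------

def _nerve_curve(rng: np.random.Generator, params: SynthParams,
                 x_band: tuple[float, float] | None = None) -> np.ndarray:
    """One smooth fiber spanning the full image height, as an (n, 2) polyline.

    x(y) is a cubic spline through knots whose horizontal offsets follow a
    random walk with per-pixel step SD ``nerve_slope_sd``, sampled at 1-px
    steps in y. The polyline itself is the ground truth: its arc length is
    exact by construction. ``x_band`` restricts the starting position so
    that fibers in one image run roughly parallel without crossing, as
    subbasal nerves do in frames selected for grading.
    """
    h, w = params.image_shape
    knot_spacing = max(h // 6, 8)
    knots_y = np.arange(0.0, h + knot_spacing, knot_spacing)
    knots_y[-1] = float(h)
    lo, hi = x_band if x_band is not None else (0.1 * w, 0.9 * w)
    x0 = rng.uniform(lo, hi)
    if params.nerve_slope_sd > 0:
        steps = rng.normal(0.0, params.nerve_slope_sd, size=len(knots_y) - 1)
        offsets = np.concatenate([[0.0], np.cumsum(steps * np.diff(knots_y))])
    else:
        offsets = np.zeros_like(knots_y)
    knots_x = np.clip(x0 + offsets, 0.0, w - 1.0)
    if params.nerve_slope_sd > 0:
        spline = CubicSpline(knots_y, knots_x, bc_type="natural")
    else:
        spline = lambda y: np.full_like(np.asarray(y, dtype=float), x0)  # noqa: E731
    ys = np.arange(0.0, h + 1.0)
    ys[-1] = float(h)
    xs = np.clip(np.asarray(spline(ys), dtype=float), 0.0, w - 1.0)
    return np.column_stack([xs, ys])


def _trim_polyline(poly: np.ndarray, length_px: float) -> np.ndarray:
    """Cut a polyline to an exact arc length from its start."""
    seg = np.hypot(*np.diff(poly, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if length_px >= cum[-1]:
        return poly
    idx = int(np.searchsorted(cum, length_px, side="right"))
    frac = (length_px - cum[idx - 1]) / seg[idx - 1]
    cut = poly[idx - 1] + frac * (poly[idx] - poly[idx - 1])
    out = np.vstack([poly[:idx], cut])
    if len(out) < 2:  # degenerate: keep a 2-point stub
        out = np.vstack([poly[0], cut])
    return out


def _polyline_length(poly: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))


def _x_bands(rng: np.random.Generator, params: SynthParams, n: int) -> list[tuple[float, float]]:
    """Disjoint horizontal bands for fiber starting positions, shuffled."""
    h, w = params.image_shape
    edges = np.linspace(0.05 * w, 0.95 * w, max(n, 1) + 1)
    bands = [(float(edges[i]), float(edges[i + 1])) for i in range(max(n, 1))]
    rng.shuffle(bands)
    return bands


def _generate_nerves(rng: np.random.Generator, params: SynthParams) -> list[np.ndarray]:
    h, _ = params.image_shape
    if params.target_length_mm is not None:
        target_px = params.target_length_mm * 1000.0 / params.pixel_pitch_um
        n_est = max(int(np.ceil(target_px / h)), 1)
        bands = _x_bands(rng, params, n_est)
        polys: list[np.ndarray] = []
        total = 0.0
        while total < target_px - 1e-9:
            band = bands[len(polys)] if len(polys) < len(bands) else None
            poly = _nerve_curve(rng, params, band)
            remaining = target_px - total
            if _polyline_length(poly) > remaining:
                poly = _trim_polyline(poly, remaining)
            if _polyline_length(poly) < 1e-9:
                break
            polys.append(poly)
            total += _polyline_length(poly)
        return polys
    lo, hi = params.nerves_per_image
    n = int(rng.integers(lo, hi + 1))
    bands = _x_bands(rng, params, n)
    return [_nerve_curve(rng, params, bands[i]) for i in range(n)]


# ---------------------------------------------------------------------------
# Cells
# ---------------------------------------------------------------------------

def _cell_polygon(rng: np.random.Generator, centre: np.ndarray,
                  params: SynthParams) -> np.ndarray:
    """Irregular ovoid cell body as a 12-gon around ``centre``."""
    a = rng.uniform(*params.cell_radius_px)
    b = a * rng.uniform(0.6, 1.0)
    theta = rng.uniform(0.0, np.pi)
    angles = np.linspace(0.0, 2.0 * np.pi, 12, endpoint=False)
    jitter = rng.uniform(0.85, 1.15, size=angles.size)
    ex = a * np.cos(angles) * jitter
    ey = b * np.sin(angles) * jitter
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    pts = (rot @ np.vstack([ex, ey])).T + centre
    h, w = params.image_shape
    return np.clip(pts, 0.0, [w - 1.0, h - 1.0])


def _place_cells(rng: np.random.Generator, params: SynthParams,
                 n_with: int, n_without: int) -> list[tuple[np.ndarray, CellClass]]:
    """Place non-overlapping cells; dendrite reach sets the exclusion radius."""
    h, w = params.image_shape
    min_sep = 2.0 * params.cell_radius_px[1] + params.dendrite_length_px[1] + 2.0
    centres: list[np.ndarray] = []
    polygons: list[tuple[np.ndarray, CellClass]] = []
    classes = [CellClass.WITH_DENDRITES] * n_with + [CellClass.WITHOUT_DENDRITES] * n_without
    margin = params.cell_radius_px[1] + 1.0
    for cls in classes:
        for _ in range(200):
            c = rng.uniform([margin, margin], [w - margin, h - margin])
            if all(np.hypot(*(c - o)) >= min_sep for o in centres):
                centres.append(c)
                polygons.append((_cell_polygon(rng, c, params), cls))
                break
        # crowded image: silently place fewer cells than requested? No —
        # fall back to the best-effort position to keep counts exact.
        else:
            c = rng.uniform([margin, margin], [w - margin, h - margin])
            centres.append(c)
            polygons.append((_cell_polygon(rng, c, params), cls))
    return polygons


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_band(canvas: np.ndarray, poly: np.ndarray, width: float,
                 intensity: float) -> None:
    """Paint a smooth stroke of the given width along a polyline."""
    h, w = canvas.shape
    half = width / 2.0
    for i in range(len(poly) - 1):
        p0, p1 = poly[i], poly[i + 1]
        v = p1 - p0
        length = float(np.hypot(*v))
        if length == 0.0:
            continue
        x0 = max(int(np.floor(min(p0[0], p1[0]) - half - 1)), 0)
        x1 = min(int(np.ceil(max(p0[0], p1[0]) + half + 1)), w - 1)
        y0 = max(int(np.floor(min(p0[1], p1[1]) - half - 1)), 0)
        y1 = min(int(np.ceil(max(p0[1], p1[1]) + half + 1)), h - 1)
        if x1 < x0 or y1 < y0:
            continue
        gx, gy = np.meshgrid(np.arange(x0, x1 + 1, dtype=float),
                             np.arange(y0, y1 + 1, dtype=float))
        rx, ry = gx - p0[0], gy - p0[1]
        t = np.clip((rx * v[0] + ry * v[1]) / length**2, 0.0, 1.0)
        dx = rx - t * v[0]
        dy = ry - t * v[1]
        dist = np.hypot(dx, dy)
        profile = intensity * np.exp(-0.5 * (dist / (half / 1.5)) ** 2)
        region = canvas[y0:y1 + 1, x0:x1 + 1]
        np.maximum(region, profile, out=region)


def _fill_polygon_soft(canvas: np.ndarray, verts: np.ndarray, intensity: float) -> None:
    from .io import fill_polygon

    region = fill_polygon(verts, canvas.shape)
    np.maximum(canvas, region * intensity, out=canvas)


def generate_sample(params: SynthParams, seed: int | None = None) -> SyntheticSample:
    """Generate one synthetic IVCM-like frame with exact ground truth.

    Deterministic given ``(params, seed)``; ``seed=None`` falls back to
    ``params.seed``. The returned ``true_nerve_length_mm`` is the analytic
    polyline arc length times the pixel pitch, and ``true_counts`` is the
    number of generated cell polygons per class.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    h, w = params.image_shape

    polys = _generate_nerves(rng, params)
    tracing = NerveTracing(polylines=polys, image_shape=(h, w)) if polys else \
        NerveTracing(polylines=[], image_shape=(h, w))
    length_px = sum(_polyline_length(p) for p in polys)
    true_length_mm = length_px * params.pixel_pitch_um / 1000.0

    n_with = int(rng.poisson(params.dc_with_per_image))
    n_without = int(rng.poisson(params.dc_without_per_image))
    polygons = _place_cells(rng, params, n_with, n_without)
    annotation = CellAnnotation(polygons=polygons, image_shape=(h, w))

    canvas = np.zeros((h, w), dtype=float)
    for poly in polys:
        width = rng.uniform(*params.nerve_width_px)
        intensity = rng.uniform(*params.nerve_intensity)
        _render_band(canvas, poly, width, intensity)
    for verts, cls in polygons:
        intensity = rng.uniform(*params.cell_intensity)
        _fill_polygon_soft(canvas, verts, intensity)
        if cls is CellClass.WITH_DENDRITES:
            centre = verts.mean(axis=0)
            lo, hi = params.dendrite_process_count
            n_proc = int(rng.integers(max(lo, 1), hi + 1))
            for _ in range(n_proc):
                ang = rng.uniform(0.0, 2.0 * np.pi)
                length = rng.uniform(*params.dendrite_length_px)
                tip = centre + length * np.array([np.cos(ang), np.sin(ang)])
                tip = np.clip(tip, 0.0, [w - 1.0, h - 1.0])
                _render_band(canvas, np.vstack([centre, tip]), 1.8, intensity * 0.7)

    img = params.background_mean + gaussian_filter(canvas, params.blur_sigma)
    img = img * (1.0 + params.speckle_sd * rng.standard_normal((h, w)))
    img = img + params.background_noise_sd * rng.standard_normal((h, w))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    record = ImageRecord(pixels=pixels, pixel_pitch_um=params.pixel_pitch_um)
    return SyntheticSample(
        image=record,
        tracing=tracing,
        true_nerve_length_mm=true_length_mm,
        annotation=annotation,
        true_counts=(n_with, n_without),
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero (densities are non-negative)."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= 0.0:
            return float(v)
    return 0.0


def generate_cohort(
    group_specs: Sequence[GroupSpec] = DEFAULT_GROUP_SPECS,
    n_subjects: int | Sequence[int] = 4,
    images_per_eye: int = 5,
    seed: int = 0,
    params: SynthParams | None = None,
    image_noise_frac: float = 0.05,
) -> list[CohortSample]:
    """Generate a two-group cohort of synthetic frames.

    Each subject gets a latent CNFL density and two latent cell densities
    drawn from its group's distribution (truncated at zero); each of the
    ``2 * images_per_eye`` frames then gets a per-image nerve-length target
    (latent density x image area, jittered by ``image_noise_frac``) hit
    exactly by construction, and Poisson cell counts around the subject
    means. Deterministic given ``seed``.
    """
    if images_per_eye < 1:
        raise ValueError("images_per_eye must be >= 1")
    if params is None:
        params = SynthParams()
    if isinstance(n_subjects, int):
        if n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        counts = [n_subjects] * len(group_specs)
    else:
        counts = list(n_subjects)
        if len(counts) != len(group_specs) or any(c < 1 for c in counts):
            raise ValueError("n_subjects must give a positive count per group")

    rng = np.random.default_rng(seed)
    area = image_area_mm2(params.image_shape, params.pixel_pitch_um)
    samples: list[CohortSample] = []
    subj_no = 0
    for spec, n_subj in zip(group_specs, counts):
        for _ in range(n_subj):
            subj_no += 1
            subject_id = f"{spec.name}_s{subj_no:03d}"
            cnfl = _truncated_normal(rng, spec.cnfl_mean, spec.cnfl_sd)
            dc_with = _truncated_normal(rng, spec.dc_with_mean, spec.dc_with_sd)
            dc_without = _truncated_normal(rng, spec.dc_without_mean, spec.dc_without_sd)
            for eye in (Eye.OS, Eye.OD):
                for k in range(images_per_eye):
                    target = cnfl * area * max(
                        0.0, 1.0 + image_noise_frac * rng.standard_normal()
                    )
                    img_params = replace(
                        params,
                        target_length_mm=target,
                        dc_with_per_image=dc_with * area,
                        dc_without_per_image=dc_without * area,
                    )
                    sample = generate_sample(
                        img_params, seed=int(rng.integers(0, 2**31 - 1))
                    )
                    sample.image.subject_id = subject_id
                    sample.image.eye = eye
                    sample.image.image_id = f"{subject_id}_{eye.value}_{k:02d}"
                    samples.append(
                        CohortSample(
                            subject_id=subject_id,
                            eye=eye,
                            group=spec.name,
                            sample=sample,
                            latent_cnfl_density=cnfl,
                            latent_dc_with_density=dc_with,
                            latent_dc_without_density=dc_without,
                        )
                    )
    return samples
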