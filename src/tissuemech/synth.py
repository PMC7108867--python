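"""Seeded generators of microscopy-style test images with known ground truth.

Every generator is a pure function of its arguments (including ``seed``):
identical calls produce bit-identical outputs.  Intensities follow the
8-bit convention (0-255) and the default pixel scale is 17.4 px/um.

Axis conventions: interface images have columns = anterior-posterior and
rows = medial-lateral with the reference side at the maximal row; spot
and ratio images have columns = medial-lateral (lateral = rightmost).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

DEFAULT_PIXELS_PER_UM = 17.4


class SynthesisError(ValueError):
    pass


@dataclass
class LabeledImage:
    """8-bit image with a physical pixel scale."""

    data: np.ndarray
    pixels_per_um: float = DEFAULT_PIXELS_PER_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise SynthesisError("image must be 2D")
        if self.data.dtype != np.uint8:
            if self.data.min() < 0 or self.data.max() > 255:
                raise SynthesisError("intensities must lie in [0, 255]")
            self.data = self.data.astype(np.uint8)
        if self.pixels_per_um <= 0:
            raise SynthesisError("pixels_per_um must be positive")


@dataclass
class MatrixGroundTruth:
    """Per-element truth of a fibrous matrix rendering."""

    label_mask: np.ndarray                  # 0 = background, k = element k
    size_classes: List[str]                 # per element: "small" | "large"
    lengths_um: List[float]                 # programmed max extent
    rendered_lengths_um: List[float]        # Feret extent of the rendered mask
    centers_rc: List[Tuple[float, float]]
    ml_gradient_slope: float = 0.0


@dataclass
class SpotSeries:
    """Time series of a photolabeled spot with programmed deformation."""

    frames: List[LabeledImage]
    ml_extents_px: np.ndarray               # per-frame true half-axis (columns)
    ap_extents_px: np.ndarray               # per-frame true half-axis (rows)
    ml_shrink_fraction: float
    ap_change_fraction: float
    bleach_per_frame: float
    interval_min: float = 15.0
    seed: Optional[int] = None


def _mask_feret_px(mask: np.ndarray) -> float:
    rr, cc = np.nonzero(mask)
    pts = np.column_stack([rr, cc]).astype(float)
    if len(pts) < 2:
        return 1.0
    from scipy.spatial import ConvexHull
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def _random_curve(rng: np.random.Generator, n_steps: int = 60,
                  wiggle: float = 0.35) -> np.ndarray:
    """Smooth open random walk with unit steps, centered at the origin."""
    angles = np.cumsum(rng.normal(0.0, wiggle, n_steps))
    steps = np.column_stack([np.cos(angles), np.sin(angles)])
    path = np.cumsum(steps, axis=0)
    return path - path.mean(axis=0)


def _scaled_curve_mask(rng: np.random.Generator, target_feret_px: float,
                       thickness_px: int, shape: Tuple[int, int],
                       center_rc: Tuple[float, float]):
    """Render one curvilinear element into a local window.

    Returns ``(local_mask, (row0, col0))`` or None if it does not fit.
    """
    from skimage.draw import line
    from skimage.morphology import dilation, disk
    path = _random_curve(rng)
    span = np.sqrt(((path[:, None, :] - path[None, :, :]) ** 2).sum(axis=2)).max()
    if span <= 0:
        return None
    pad = 2 * thickness_px + 3
    skel_target = max(target_feret_px - 2.0 * thickness_px, 2.0)
    footprint = disk(thickness_px)

    def render(scaled_path):
        lo = scaled_path.min(axis=0)
        hi = scaled_path.max(axis=0)
        local_shape = (int(np.ceil(hi[0] - lo[0])) + 2 * pad + 1,
                       int(np.ceil(hi[1] - lo[1])) + 2 * pad + 1)
        pts = np.round(scaled_path - lo + pad).astype(int)
        mask = np.zeros(local_shape, dtype=bool)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = line(r0, c0, r1, c1)
            mask[rr, cc] = True
        origin = (int(round(center_rc[0] + lo[0] - pad)),
                  int(round(center_rc[1] + lo[1] - pad)))
        return dilation(mask, footprint), origin

    # refine the scale so the rendered Feret extent hits the target
    mask, origin = None, None
    for _ in range(4):
        mask, origin = render(path * (skel_target / span))
        err = _mask_feret_px(mask) - target_feret_px
        if abs(err) <= 0.8:
            break
        skel_target = max(skel_target - err, 2.0)
    r0, c0 = origin
    if r0 < 0 or c0 < 0 or r0 + mask.shape[0] > shape[0] \
            or c0 + mask.shape[1] > shape[1]:
        return None
    return mask, origin


def gen_matrix_image(width_um: float = 300.0, height_um: float = 60.0,
                     n_small: int = 20, n_large: int = 3,
                     ml_gradient_slope: float = 0.0, seed: int = 0,
                     pixels_per_um: float = DEFAULT_PIXELS_PER_UM,
                     thickness_px: int = 2, max_attempts: int = 400,
                     small_range_um: Tuple[float, float] = (4.0, 40.0),
                     large_range_um: Tuple[float, float] = (40.0, 150.0),
                     ) -> Tuple[LabeledImage, MatrixGroundTruth]:
    """Fibrous bright-on-dark image of curvilinear matrix elements.

    "Small" elements have true maximum extent drawn uniformly from
    ``small_range_um``, "large" from ``large_range_um``.  Element centers
    along the ML axis (rows) follow a linear density with
    ``ml_gradient_slope`` (0 = uniform; positive = denser toward the
    reference side at relative position 0, i.e. the maximal row).
    Elements never overlap; if the canvas cannot host the requested
    counts a :class:`SynthesisError` is raised.
    """
    if n_small < 0 or n_large < 0:
        raise SynthesisError("element counts must be non-negative")
    if abs(ml_gradient_slope) > 2:
        raise SynthesisError("|ml_gradient_slope| must be <= 2")
    rng = np.random.default_rng(seed)
    shape = (int(round(height_um * pixels_per_um)),
             int(round(width_um * pixels_per_um)))
    occupied = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int32)
    classes: List[str] = []
    lengths: List[float] = []
    rendered: List[float] = []
    centers: List[Tuple[float, float]] = []
    specs = (["large"] * n_large) + (["small"] * n_small)  # big ones first
    from skimage.morphology import dilation, disk
    margin_kernel = disk(2 * thickness_px)
    for k, cls in enumerate(specs, start=1):
        lo, hi = large_range_um if cls == "large" else small_range_um
        length_um = float(rng.uniform(lo, hi))
        target_px = length_um * pixels_per_um
        placed = False
        for _ in range(max_attempts):
            # rejection-sample the ML (row) position from the linear density
            while True:
                u = rng.uniform(0.0, 1.0)
                accept = 1.0 + ml_gradient_slope * (0.5 - u)
                if rng.uniform(0.0, 2.0) < accept:
                    break
            row = (1.0 - u) * (shape[0] - 1)   # u = 0 at the max row
            col = rng.uniform(0, shape[1] - 1)
            res = _scaled_curve_mask(rng, target_px, thickness_px, shape,
                                     (row, col))
            if res is None:
                continue
            mask, (r0, c0) = res
            window = (slice(r0, r0 + mask.shape[0]),
                      slice(c0, c0 + mask.shape[1]))
            if (dilation(mask, margin_kernel) & occupied[window]).any():
                continue
            occupied[window] |= mask
            labels[window][mask] = k
            classes.append(cls)
            lengths.append(length_um)
            rendered.append(_mask_feret_px(mask) / pixels_per_um)
            centers.append((row, col))
            placed = True
            break
        if not placed:
            raise SynthesisError(
                f"could not place element {k} ({cls}, {length_um:.1f} um): "
                "density cap exceeded")
    signal = ndimage.gaussian_filter(occupied.astype(float) * 200.0, 0.7)
    noise = rng.normal(18.0, 5.0, shape)
    img = np.clip(signal + noise, 0, 255).astype(np.uint8)
    truth = MatrixGroundTruth(label_mask=labels, size_classes=classes,
                              lengths_um=lengths, rendered_lengths_um=rendered,
                              centers_rc=centers,
                              ml_gradient_slope=ml_gradient_slope)
    return LabeledImage(img, pixels_per_um), truth


def gen_spot_series(initial_extent_px: Tuple[int, int] = (60, 40),
                    ml_shrink_fraction: float = 0.0,
                    ap_change_fraction: float = 0.0,
                    bleach_per_frame: float = 1.0,
                    n_frames: int = 5, seed: int = 0,
                    pixels_per_um: float = 5.0,
                    anchor: str = "center",
                    peak_intensity: float = 200.0,
                    noise_sd: float = 4.0,
                    pad_px: int = 40) -> SpotSeries:
    """Elliptical photolabeled spot with programmed anisotropic shrinkage.

    ``initial_extent_px`` is the (ML, AP) half-axis pair in pixels; the
    ML extent of frame t is scaled by ``(1 - ml_shrink_fraction)^(t/(T-1))``
    so the last frame carries the full programmed shrink.  Columns are the
    ML axis.  ``anchor`` places the shrink about the spot center
    ("center") or keeps the lateral (rightmost) edge fixed ("lateral").
    Intensity is multiplied by ``bleach_per_frame`` at every frame.
    """
    if not (0 <= ml_shrink_fraction < 1 and 0 <= abs(ap_change_fraction) < 1):
        raise SynthesisError("fractions must lie in [0, 1)")
    if n_frames < 2:
        raise SynthesisError("need at least 2 frames")
    if anchor not in ("center", "lateral"):
        raise SynthesisError("anchor must be 'center' or 'lateral'")
    rng = np.random.default_rng(seed)
    a0, b0 = float(initial_extent_px[0]), float(initial_extent_px[1])
    shape = (int(2 * b0 + 2 * pad_px), int(2 * a0 + 2 * pad_px))
    cy = shape[0] / 2.0
    lateral_edge = shape[1] / 2.0 + a0
    frames: List[LabeledImage] = []
    mls, aps = [], []
    for t in range(n_frames):
        frac = t / (n_frames - 1)
        a = a0 * (1.0 - ml_shrink_fraction) ** frac
        b = b0 * (1.0 - ap_change_fraction) ** frac
        if a < 3 or b < 3:
            raise SynthesisError(f"frame {t}: spot smaller than 3 px")
        cx = shape[1] / 2.0 if anchor == "center" else lateral_edge - a
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        level = peak_intensity * bleach_per_frame ** t
        img = inside * level + rng.normal(8.0, noise_sd, shape)
        frames.append(LabeledImage(np.clip(img, 0, 255).astype(np.uint8),
                                   pixels_per_um))
        mls.append(a)
        aps.append(b)
    return SpotSeries(frames=frames, ml_extents_px=np.array(mls),
                      ap_extents_px=np.array(aps),
                      ml_shrink_fraction=ml_shrink_fraction,
                      ap_change_fraction=ap_change_fraction,
                      bleach_per_frame=bleach_per_frame, seed=seed)


def gen_circle_points(center: Tuple[float, float] = (0.0, 0.0),
                      radius: float = 1.0, n: int = 20,
                      angular_span: float = 2 * np.pi,
                      noise_sd: float = 0.0, seed: int = 0,
                      start_angle: float = 0.0
                      ) -> Tuple[np.ndarray, dict]:
    """Points on a circular arc with isotropic Gaussian noise."""
    if n < 3:
        raise SynthesisError("need at least 3 points")
    if radius <= 0:
        raise SynthesisError("radius must be positive")
    if angular_span == 0:
        raise SynthesisError("angular span must be nonzero")
    rng = np.random.default_rng(seed)
    t = start_angle + np.linspace(0.0, angular_span, n)
    pts = np.column_stack([center[0] + radius * np.cos(t),
                           center[1] + radius * np.sin(t)])
    pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return pts, {"center": tuple(center), "radius": radius,
                 "noise_sd": noise_sd, "angular_span": angular_span}


def gen_ratio_pair(shape: Tuple[int, int] = (200, 400),
                   ratio_profile: Callable[[np.ndarray], np.ndarray] | float = 1.0,
                   saturation_fraction: float = 0.0, seed: int = 0,
                   fiber_fraction: float = 0.25,
                   fiber_level: float = 110.0,
                   background_level: float = 15.0,
                   pixels_per_um: float = DEFAULT_PIXELS_PER_UM
                   ) -> Tuple[LabeledImage, LabeledImage, dict]:
    """Two-channel pair: channel B is a fibrous base pattern, channel A is
    B multiplied by a medial-lateral ratio profile.

    ``ratio_profile`` maps relative ML position (0 medial .. 1 lateral,
    along columns) to the programmed A/B ratio; a scalar means a constant
    ratio.  ``saturation_fraction`` of the fiber pixels in channel A is
    clipped to 255.  Ground truth includes per-bin programmed ratios for
    a 10-bin analysis.
    """
    if not 0 <= saturation_fraction <= 0.05:
        raise SynthesisError("saturation_fraction must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    # fibrous base: smoothed binary noise, thresholded to the target fraction
    field = ndimage.gaussian_filter(rng.normal(size=shape), 3.0)
    cut = np.quantile(field, 1.0 - fiber_fraction)
    fibers = field > cut
    b = np.where(fibers, fiber_level + 30.0 * (field - cut) / field.std(),
                 background_level + 4.0 * rng.normal(size=shape))
    b = np.clip(b, 1, 220)
    u = np.linspace(0.0, 1.0, shape[1])
    if callable(ratio_profile):
        ratio = np.asarray(ratio_profile(u), dtype=float)
    else:
        ratio = np.full(shape[1], float(ratio_profile))
    if (ratio <= 0).any():
        raise SynthesisError("ratio profile must be positive")
    a = b * ratio[None, :]
    if saturation_fraction > 0:
        idx = np.flatnonzero(fibers.ravel())
        n_sat = int(round(saturation_fraction * idx.size))
        if n_sat:
            sat = rng.choice(idx, size=n_sat, replace=False)
            a.ravel()[sat] = 255.0
    imgA = LabeledImage(np.clip(np.round(a), 0, 255).astype(np.uint8),
                        pixels_per_um)
    imgB = LabeledImage(np.clip(np.round(b), 0, 255).astype(np.uint8),
                        pixels_per_um)
    nbins = 10
    binsize = shape[1] // nbins
    bin_ratio = []
    for k in range(nbins):
        lo = k * binsize
        hi = shape[1] if k == nbins - 1 else (k + 1) * binsize
        sel = fibers[:, lo:hi]
        bin_ratio.append(float(np.mean(np.broadcast_to(ratio[lo:hi],
                                                       sel.shape)[sel]))
                         if sel.any() else np.nan)
    truth = {"ratio_profile": ratio, "fibers": fibers,
             "bin_ratios": np.array(bin_ratio),
             "bin_ratios_norm": np.array(bin_ratio) / bin_ratio[-1]}
    return imgA, imgB, truth
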