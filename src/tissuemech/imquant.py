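"""Quantification of 2D microscopy-style images.

Implements the processing chain used on tissue-interface images:
local/global thresholding, size-sorting of matrix elements, medial-lateral
distribution histograms, anterior-posterior density profiles, spot
deformation metrics, multi-pass block-matching displacement fields with
rose histograms, the moment-based algebraic circle fit, ratiometric
medial-lateral gradients, and polygonal region means.

Axis convention (configurable where relevant): columns run along the
anterior-posterior (AP) axis, rows along the medial-lateral (ML) axis,
with the reference (notochord/neural-tube) side at the maximal row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

DEFAULT_PIXELS_PER_UM = 17.4


class ImageQuantError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers


@dataclass
class BinaryMask:
    """Boolean image with a physical pixel scale (True = signal)."""

    data: np.ndarray
    pixels_per_um: float = DEFAULT_PIXELS_PER_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ImageQuantError("mask must be 2D")
        if self.pixels_per_um <= 0:
            raise ImageQuantError("pixels_per_um must be positive")


@dataclass
class SizeClasses:
    """Foreground split into noise (<4 um), small (4-40 um), large (>40 um)."""

    noise: BinaryMask
    small: BinaryMask
    large: BinaryMask
    extents_um: dict = field(default_factory=dict)  # component label -> Feret um
    labels: Optional[np.ndarray] = None


@dataclass
class MLProfile:
    """Binned profile along the relative medial-lateral axis."""

    positions: np.ndarray      # bin centers, relative ML position in [0, 1]
    values: np.ndarray
    nbins: int
    kind: str = "counts"


@dataclass
class SpotMetrics:
    """Per-frame spot extent: std of foreground pixel coordinates."""

    widths: np.ndarray          # std of column (ML) coordinates, px
    heights: np.ndarray         # std of row (AP) coordinates, px
    widths_norm: np.ndarray     # divided by frame 1
    heights_norm: np.ndarray


@dataclass
class DisplacementField:
    """Block-matching displacement vectors on a regular grid."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    vectors: np.ndarray        # (ny, nx, 2) as (dx, dy) in px
    scores: np.ndarray         # peak normalized cross-correlation
    valid: np.ndarray          # False where the patch was flat / out of range
    iw: int
    sw: int
    vs: int


# ---------------------------------------------------------------------------
# thresholding


def _disk_kernel(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    k = (x * x + y * y <= radius * radius).astype(float)
    return k / k.sum()


def local_threshold_phansalkar(image: np.ndarray, radius_px: int = 15,
                               p: float = 2.0, q: float = 10.0,
                               k: float = 0.25, r: float = 0.5,
                               pixels_per_um: float = DEFAULT_PIXELS_PER_UM
                               ) -> BinaryMask:
    """Local adaptive threshold t = m (1 + p e^{-q m} + k ((s/r) - 1)).

    ``m`` and ``s`` are the local mean and standard deviation inside a
    circular window of ``radius_px``, computed on intensities normalized
    to [0, 1].  Pixels brighter than their local threshold are foreground
    (bright-on-dark polarity).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ImageQuantError("image must be 2D")
    if radius_px < 1:
        raise ImageQuantError("radius must be >= 1")
    if 2 * radius_px + 1 > min(img.shape):
        raise ImageQuantError("threshold window larger than image")
    norm = img / 255.0
    kernel = _disk_kernel(radius_px)
    pad = radius_px
    padded = np.pad(norm, pad, mode="reflect")
    m = fftconvolve(padded, kernel, mode="valid")
    m2 = fftconvolve(padded * padded, kernel, mode="valid")
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    t = m * (1.0 + p * np.exp(-q * m) + k * ((s / r) - 1.0))
    return BinaryMask(norm > t, pixels_per_um)


def global_threshold_minfrac(image: np.ndarray, frac: float = 0.20,
                             pixels_per_um: float = DEFAULT_PIXELS_PER_UM
                             ) -> BinaryMask:
    """Foreground where intensity exceeds min + frac * (max - min)."""
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise ImageQuantError("constant image: global threshold undefined")
    return BinaryMask(img > lo + frac * (hi - lo), pixels_per_um)


def otsu_mask(image: np.ndarray,
              pixels_per_um: float = DEFAULT_PIXELS_PER_UM) -> BinaryMask:
    """Otsu global threshold (used as the default spot binarization)."""
    from skimage.filters import threshold_otsu
    img = np.asarray(image)
    if img.max() == img.min():
        raise ImageQuantError("constant image: Otsu threshold undefined")
    return BinaryMask(img > threshold_otsu(img), pixels_per_um)


# ---------------------------------------------------------------------------
# matrix size sorting


def size_sort(mask: BinaryMask, noise_cutoff_um: float = 4.0,
              large_cutoff_um: float = 40.0) -> SizeClasses:
    """Classify 8-connected components by maximum Feret diameter in um."""
    from skimage import measure
    labels = measure.label(mask.data, connectivity=2)
    noise = np.zeros_like(mask.data)
    small = np.zeros_like(mask.data)
    large = np.zeros_like(mask.data)
    extents = {}
    if labels.max() > 0:
        for prop in measure.regionprops(labels):
            if prop.num_pixels == 1:
                feret_px = 1.0
            else:
                feret_px = prop.feret_diameter_max
            um = feret_px / mask.pixels_per_um
            extents[prop.label] = um
            target = noise if um < noise_cutoff_um else (
                small if um <= large_cutoff_um else large)
            target[labels == prop.label] = True
    ppu = mask.pixels_per_um
    return SizeClasses(noise=BinaryMask(noise, ppu), small=BinaryMask(small, ppu),
                       large=BinaryMask(large, ppu), extents_um=extents,
                       labels=labels)


# ---------------------------------------------------------------------------
# ML distribution / AP density


def _ap_sectors(n_cols: int, sector_px: int) -> List[slice]:
    n = max(1, int(round(n_cols / sector_px)))
    edges = [min(i * sector_px, n_cols) for i in range(n)] + [n_cols]
    return [slice(edges[i], edges[i + 1]) for i in range(n)
            if edges[i + 1] > edges[i]]


def ml_distribution(signal: BinaryMask, tissue: BinaryMask,
                    sector_um: float = 10.0, nbins: int = 30) -> MLProfile:
    """Pooled histogram of relative ML positions of signal pixels.

    The image is cut into AP sectors of ``sector_um``; within each sector
    every signal pixel's position is expressed relative to the local
    tissue extent, measured from the reference side at the maximal row.
    Counts are normalized by the total signal pixel count analyzed.
    """
    if signal.data.shape != tissue.data.shape:
        raise ImageQuantError("signal and tissue masks must share a shape")
    sector_px = max(1, int(round(sector_um * signal.pixels_per_um)))
    rel: List[np.ndarray] = []
    for sl in _ap_sectors(signal.data.shape[1], sector_px):
        tis_rows = np.where(tissue.data[:, sl].any(axis=1))[0]
        sig_rows = np.where(signal.data[:, sl])[0]
        if tis_rows.size == 0:
            if sig_rows.size:
                warnings.warn("AP sector with signal but empty tissue mask; skipped")
            continue
        ref = tis_rows.max()
        extent = tis_rows.max() - tis_rows.min()
        if extent == 0:
            warnings.warn("AP sector with degenerate tissue extent; skipped")
            continue
        rel.append(np.abs(sig_rows - ref) / extent)
    pooled = np.concatenate(rel) if rel else np.empty(0)
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(np.clip(pooled, 0, 1), bins=edges)
    total = pooled.size
    values = counts / total if total else counts.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return MLProfile(positions=centers, values=values, nbins=nbins)


def ap_density(signal: BinaryMask, tissue: BinaryMask,
               sector_um: float = 50.0, first_center_um: float = 25.0
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Signal density (signal px / tissue px) per AP sector.

    Returns ``(positions_um, densities)``; sectors with an empty tissue
    mask yield NaN.
    """
    if signal.data.shape != tissue.data.shape:
        raise ImageQuantError("signal and tissue masks must share a shape")
    sector_px = max(1, int(round(sector_um * signal.pixels_per_um)))
    sectors = _ap_sectors(signal.data.shape[1], sector_px)
    positions = first_center_um + sector_um * np.arange(len(sectors))
    densities = np.full(len(sectors), np.nan)
    for i, sl in enumerate(sectors):
        n_tis = int(tissue.data[:, sl].sum())
        if n_tis == 0:
            warnings.warn(f"AP sector {i}: empty tissue mask, density undefined")
            continue
        densities[i] = signal.data[:, sl].sum() / n_tis
    return positions, densities


# ---------------------------------------------------------------------------
# spot metrics


def spot_metrics(series: Sequence[np.ndarray | BinaryMask]) -> SpotMetrics:
    """Per-frame width/height of a binary spot.

    Width is the standard deviation of foreground column coordinates
    (ML axis), height the standard deviation of row coordinates (AP
    axis); both are also reported normalized to the first frame.
    """
    if len(series) < 1:
        raise ImageQuantError("spot series requires at least one frame")
    widths, heights = [], []
    for i, frame in enumerate(series):
        data = frame.data if isinstance(frame, BinaryMask) else np.asarray(frame)
        rows, cols = np.nonzero(data)
        if rows.size == 0:
            raise ImageQuantError(f"frame {i}: no foreground pixels")
        widths.append(float(np.std(cols)))
        heights.append(float(np.std(rows)))
    widths = np.array(widths)
    heights = np.array(heights)
    w0 = widths[0] if widths[0] > 0 else np.nan
    h0 = heights[0] if heights[0] > 0 else np.nan
    return SpotMetrics(widths=widths, heights=heights,
                       widths_norm=widths / w0, heights_norm=heights / h0)


# ---------------------------------------------------------------------------
# displacement fields


def _ncc_peak(template: np.ndarray, search: np.ndarray):
    """Peak of normalized cross-correlation of template inside search."""
    from skimage.feature import match_template
    if template.std() < 1e-12 or search.std() < 1e-12:
        return None
    ncc = match_template(search, template)
    idx = np.unravel_index(np.argmax(ncc), ncc.shape)
    peak = float(ncc[idx])
    dy, dx = float(idx[0]), float(idx[1])
    # parabolic sub-pixel refinement in each axis
    for axis, coord in ((0, idx[0]), (1, idx[1])):
        if 0 < coord < ncc.shape[axis] - 1:
            sel = [idx[0], idx[1]]
            sel[axis] = coord - 1
            y0 = ncc[tuple(sel)]
            sel[axis] = coord + 1
            y2 = ncc[tuple(sel)]
            y1 = ncc[idx]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                shift = 0.5 * (y0 - y2) / denom
                if axis == 0:
                    dy += np.clip(shift, -1, 1)
                else:
                    dx += np.clip(shift, -1, 1)
    return dx, dy, peak


def displacement_field(frameA: np.ndarray, frameB: np.ndarray,
                       iw: int, sw: int, vs: int,
                       prior: Optional[DisplacementField] = None
                       ) -> DisplacementField:
    """Single-pass block matching: for each grid node, the displacement
    maximizing normalized cross-correlation of the interrogation-window
    patch of ``frameA`` within the search window of ``frameB``.

    ``prior`` (a coarser field) pre-shifts the search windows.
    """
    a = np.asarray(frameA, dtype=float)
    b = np.asarray(frameB, dtype=float)
    if a.shape != b.shape:
        raise ImageQuantError("frames must share a shape")
    if not iw < sw:
        raise ImageQuantError("interrogation window must be smaller than search window")
    h, w = a.shape
    half_iw = iw // 2
    margin = half_iw
    xs = np.arange(margin, w - margin, vs)
    ys = np.arange(margin, h - margin, vs)
    if xs.size == 0 or ys.size == 0:
        raise ImageQuantError("image too small for the requested windows")
    vectors = np.zeros((ys.size, xs.size, 2))
    scores = np.zeros((ys.size, xs.size))
    valid = np.zeros((ys.size, xs.size), dtype=bool)
    prior_interp = _field_interpolator(prior) if prior is not None else None
    half_sw = sw // 2
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            shift = np.array([0.0, 0.0])
            if prior_interp is not None:
                shift = prior_interp(x, y)
            cx = int(round(x + shift[0]))
            cy = int(round(y + shift[1]))
            ty0, ty1 = y - half_iw, y - half_iw + iw
            tx0, tx1 = x - half_iw, x - half_iw + iw
            sy0, sy1 = cy - half_sw, cy - half_sw + sw
            sx0, sx1 = cx - half_sw, cx - half_sw + sw
            if sy0 < 0 or sx0 < 0 or sy1 > h or sx1 > w:
                sy0, sy1 = max(sy0, 0), min(sy1, h)
                sx0, sx1 = max(sx0, 0), min(sx1, w)
                if sy1 - sy0 <= iw or sx1 - sx0 <= iw:
                    continue
            template = a[ty0:ty1, tx0:tx1]
            search = b[sy0:sy1, sx0:sx1]
            res = _ncc_peak(template, search)
            if res is None:
                continue
            dx, dy, score = res
            vectors[j, i, 0] = (sx0 + dx) - tx0
            vectors[j, i, 1] = (sy0 + dy) - ty0
            scores[j, i] = score
            valid[j, i] = True
    return DisplacementField(grid_x=xs, grid_y=ys, vectors=vectors,
                            scores=scores, valid=valid, iw=iw, sw=sw, vs=vs)


def _field_interpolator(fld: DisplacementField):
    from scipy.interpolate import RegularGridInterpolator
    vec = fld.vectors.copy()
    vec[~fld.valid] = 0.0
    interp = RegularGridInterpolator(
        (fld.grid_y.astype(float), fld.grid_x.astype(float)), vec,
        bounds_error=False, fill_value=None, method="linear")

    def at(x, y):
        return interp((float(y), float(x)))
    return at


DEFAULT_PASSES = ((60, 120, 15), (50, 120, 12), (40, 80, 10))


def multipass_displacement(frameA: np.ndarray, frameB: np.ndarray,
                           passes: Sequence[Tuple[int, int, int]] = DEFAULT_PASSES
                           ) -> DisplacementField:
    """Three-pass refinement: each pass pre-shifts its search windows by
    the interpolated coarser field."""
    fld = None
    for iw, sw, vs in passes:
        fld = displacement_field(frameA, frameB, iw, sw, vs, prior=fld)
    return fld


def rose_histogram(fields: Iterable[DisplacementField], nbins_angle: int = 24,
                   min_norm: float = 1e-6) -> Tuple[np.ndarray, np.ndarray]:
    """Pooled angular histogram of displacement vectors.

    Angles follow image convention (x right, y down); zero-length and
    invalid vectors are excluded.  Returns (bin_centers_rad, counts).
    """
    angles = []
    for fld in fields:
        v = fld.vectors[fld.valid]
        norm = np.linalg.norm(v, axis=1)
        keep = norm > min_norm
        angles.append(np.arctan2(v[keep, 1], v[keep, 0]))
    pooled = np.concatenate(angles) if angles else np.empty(0)
    edges = np.linspace(-np.pi, np.pi, nbins_angle + 1)
    counts, _ = np.histogram(pooled, bins=edges)
    return 0.5 * (edges[:-1] + edges[1:]), counts


# ---------------------------------------------------------------------------
# circle fit


def pratt_circle_fit(points: np.ndarray) -> Tuple[Tuple[float, float], float]:
    """Moment-based algebraic circle fit (Newton iteration from x = 0).

    Returns ``((cx, cy), radius)``.  Raises :class:`ImageQuantError` with
    the messages "At least 3 points are required to fit a circle." /
    "Points selected are collinear." on the degenerate inputs.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ImageQuantError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 3:
        raise ImageQuantError("At least 3 points are required to fit a circle.")
    mean = pts.mean(axis=0)
    X = pts[:, 0] - mean[0]
    Y = pts[:, 1] - mean[1]
    Z = X * X + Y * Y
    Mxx = float(np.mean(X * X))
    Myy = float(np.mean(Y * Y))
    Mxy = float(np.mean(X * Y))
    Mxz = float(np.mean(X * Z))
    Myz = float(np.mean(Y * Z))
    Mzz = float(np.mean(Z * Z))
    Mz = Mxx + Myy
    Cov_xy = Mxx * Myy - Mxy * Mxy
    A2 = 4 * Cov_xy - 3 * Mz * Mz - Mzz
    A1 = Mzz * Mz + 4 * Cov_xy * Mz - Mxz ** 2 - Myz ** 2 - Mz ** 3
    A0 = (Mxz ** 2 * Myy + Myz ** 2 * Mxx - Mzz * Cov_xy
          - 2 * Mxz * Myz * Mxy + Mz * Mz * Cov_xy)
    A22 = 2 * A2

    x = 0.0
    y = A0
    for _ in range(20):
        Dy = A1 + x * (A22 + 16 * x * x)
        if Dy == 0:
            break
        x_old = x
        x = x_old - y / Dy
        if x != 0 and abs((x - x_old) / x) < 1e-12:
            break
        y_new = A0 + x * (A1 + x * (A2 + 4 * x * x))
        if abs(y_new) > abs(y):
            x = 0.0
            break
        if x < 0:
            x = 0.0
        y = y_new

    det = x * x - x * Mz + Cov_xy
    if det == 0:
        raise ImageQuantError("Points selected are collinear.")
    with np.errstate(divide="ignore", invalid="ignore"):
        cx = (Mxz * (Myy - x) - Myz * Mxy) / (2 * det)
        cy = (Myz * (Mxx - x) - Mxz * Mxy) / (2 * det)
        radius = np.sqrt(cx * cx + cy * cy + Mz + 2 * x)
    if not np.isfinite(radius):
        raise ImageQuantError("Points selected are collinear.")
    return (float(cx + mean[0]), float(cy + mean[1])), float(radius)


# ---------------------------------------------------------------------------
# ratiometric gradient


def ratio_gradient(imgA: np.ndarray, imgB: np.ndarray,
                   thA: float = 33, thB: float = 30, nbins: int = 10
                   ) -> Tuple[MLProfile, MLProfile, MLProfile]:
    """Medial-lateral level and ratio profiles of a two-channel pair.

    In both channels pixels at 0 (outside the tissue) and 255
    (saturated) are excluded; pixels below the per-channel threshold are
    background.  Level profiles average over all tissue pixels with
    background set to zero; the ratio profile averages A/B over matrix
    pixels only.  The image is cut into ``nbins`` equal column bins
    (lateral = last bin) and every profile is normalized to its most
    lateral bin.
    """
    a = np.asarray(imgA, dtype=float)
    b = np.asarray(imgB, dtype=float)
    if a.shape != b.shape:
        raise ImageQuantError("channel images must share a shape")
    outside = (a == 0) | (b == 0) | (a == 255) | (b == 255)
    bgA = a < thA
    bgB = b < thB
    levelA = np.where(outside, np.nan, np.where(bgA, 0.0, a))
    levelB = np.where(outside, np.nan, np.where(bgB, 0.0, b))
    matrix = ~outside & ~bgA & ~bgB
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(matrix, a / b, np.nan)
    ratio[~np.isfinite(ratio)] = np.nan
    profiles = []
    for img, kind in ((levelA, "level_A"), (levelB, "level_B"), (ratio, "ratio")):
        means = _ml_bin_means(img, nbins)
        last = means[-1]
        if not np.isfinite(last) or last == 0:
            raise ImageQuantError(
                f"{kind}: most-lateral bin empty or zero, cannot normalize")
        positions = (np.arange(nbins) + 0.5) / nbins
        profiles.append(MLProfile(positions=positions, values=means / last,
                                  nbins=nbins, kind=kind))
    return tuple(profiles)


def _ml_bin_means(img: np.ndarray, nbins: int) -> np.ndarray:
    width = img.shape[1]
    binsize = width // nbins
    if binsize < 1:
        raise ImageQuantError("image narrower than the number of bins")
    means = np.full(nbins, np.nan)
    for k in range(nbins):
        lo = k * binsize
        hi = width if k == nbins - 1 else (k + 1) * binsize
        block = img[:, lo:hi]
        if np.isfinite(block).any():
            means[k] = np.nanmean(block)
    return means


# ---------------------------------------------------------------------------
# region means


def region_means(image: np.ndarray, regions: Sequence[np.ndarray]) -> np.ndarray:
    """Mean intensity inside each polygon (vertices as (x, y) pairs)."""
    from skimage.draw import polygon as draw_polygon
    img = np.asarray(image, dtype=float)
    out = np.empty(len(regions))
    for i, poly in enumerate(regions):
        poly = np.asarray(poly, dtype=float)
        x, y = poly[:, 0], poly[:, 1]
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=img.shape)
        if rr.size == 0 or area == 0:
            raise ImageQuantError(f"region {i} contains no pixels")
        out[i] = img[rr, cc].mean()
    return out
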