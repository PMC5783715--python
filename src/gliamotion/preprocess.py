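"""Preprocessing of calibrated 4-D two-photon stacks into binary cell movies.

The chain mirrors standard practice for time-lapse microglia imaging:
per-slice median filtering and rolling-ball background subtraction, lateral
and axial drift registration by cross-correlation, maximum-intensity
projection over z, a single per-movie binarisation threshold, and per-cell
ROI masking.  The product is a ``BinaryCellMovie`` — one cell's boolean
(t, y, x) movie with its calibration — which every downstream motility
metric consumes.

Conventions: arrays are (t, z, y, x) or (t, y, x), row/col 0-based with the
origin top-left; polygons are lists of [x, y] vertices in pixel units with
even-odd fill, boundary pixels inside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "TimeLapseStack",
    "BinaryCellMovie",
    "read_tiff",
    "write_tiff",
    "median_filter_frames",
    "subtract_background",
    "register_lateral",
    "register_axial",
    "max_project",
    "binarise",
    "apply_roi",
    "preprocess_stack",
]


class GeometryError(ValueError):
    """Bad spatial input (polygon, target, or center outside the field)."""


@dataclass
class TimeLapseStack:
    """Calibrated 4-D intensity data, axes (t, z, y, x)."""

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float = 2.0
    frame_interval_s: float = 60.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("stack must be 4-D (t, z, y, x)")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("need at least one frame and one z-slice")
        for name in ("pixel_size_um", "z_step_um", "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class BinaryCellMovie:
    """One cell's binarised 2-D movie (t, y, x) with calibration and ROI."""

    mask: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    roi: np.ndarray | None = None       # (k, 2) [x, y] vertices, px
    threshold: float | None = None
    empty_flag: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D (t, y, x)")

    @property
    def n_frames(self) -> int:
        return self.mask.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


# ---------------------------------------------------------------------------
# TIFF I/O with calibration metadata
# ---------------------------------------------------------------------------

def write_tiff(stack: TimeLapseStack, path) -> None:
    """Write a (t, z, y, x) stack as an ImageJ-style TIFF with calibration."""
    import tifffile

    res = 1.0 / stack.pixel_size_um  # pixels per micrometre
    tifffile.imwrite(
        path,
        np.asarray(stack.data, dtype=np.float32),
        imagej=True,
        resolution=(res, res),
        metadata={
            "axes": "TZYX",
            "unit": "um",
            "spacing": stack.z_step_um,
            "finterval": stack.frame_interval_s,
        },
    )


def read_tiff(path, pixel_size_um: float | None = None,
              z_step_um: float | None = None,
              frame_interval_s: float | None = None) -> TimeLapseStack:
    """Read a multi-page TIFF; calibration from tags, overridable by args."""
    import tifffile

    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta = tf.imagej_metadata or {}
        page = tf.pages[0]
        if pixel_size_um is None:
            try:
                num, den = page.tags["XResolution"].value
                pixel_size_um = den / num
            except (KeyError, ZeroDivisionError):
                raise ValueError("pixel size not in TIFF tags; pass pixel_size_um")
        if z_step_um is None:
            z_step_um = float(meta.get("spacing", 1.0))
        if frame_interval_s is None:
            frame_interval_s = float(meta.get("finterval", 1.0))
    # coerce to (t, z, y, x)
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[:, None] if "T" in axes and "Z" not in axes else data[None]
    return TimeLapseStack(
        data=data,
        pixel_size_um=float(pixel_size_um),
        z_step_um=float(z_step_um),
        frame_interval_s=float(frame_interval_s),
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def median_filter_frames(data: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter each 2-D (z-)slice of every frame.

    Each pixel is replaced by the median of the window x window array
    centred on it; edges use reflected padding.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    data = np.asarray(data)
    if data.ndim == 2:
        return ndimage.median_filter(data, size=window, mode="reflect")
    out = np.empty_like(data)
    for idx in np.ndindex(data.shape[:-2]):
        out[idx] = ndimage.median_filter(data[idx], size=window, mode="reflect")
    return out


def subtract_background(frame: np.ndarray, ball_radius_px: int = 30) -> np.ndarray:
    """Rolling-ball background subtraction of a single 2-D frame.

    The background is the surface traced by a ball of the given radius
    rolled under the intensity landscape; it is subtracted and the result
    clipped at zero, so a flat image maps to zero everywhere.
    """
    if ball_radius_px < 1:
        raise ValueError("ball_radius_px must be >= 1")
    from skimage.restoration import rolling_ball

    frame = np.asarray(frame, dtype=float)
    bg = rolling_ball(frame, radius=ball_radius_px)
    return np.clip(frame - bg, 0.0, None)


def subtract_background_stack(data: np.ndarray, ball_radius_px: int = 30) -> np.ndarray:
    """Apply rolling-ball subtraction to every (t, z) slice."""
    data = np.asarray(data, dtype=float)
    out = np.empty_like(data)
    for idx in np.ndindex(data.shape[:-2]):
        out[idx] = subtract_background(data[idx], ball_radius_px)
    return out


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def _integer_shift2d(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate a 2-D image by integer (dy, dx), zero-filling exposed edges."""
    out = np.zeros_like(img)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def _estimate_shift(ref: np.ndarray, img: np.ndarray, subpixel: bool) -> np.ndarray:
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(
        ref, img, upsample_factor=10 if subpixel else 1, normalization=None
    )
    return shift


def register_lateral(data: np.ndarray, subpixel: bool = False):
    """Align each frame to the first by translation (cross-correlation peak).

    Accepts a 2-D movie (t, y, x) or a 4-D stack (t, z, y, x); for stacks
    the shift is estimated on the per-frame maximum projection and applied
    to every slice.  Returns (registered, shifts, warn_flags) where
    ``shifts[t]`` is the (dy, dx) applied to frame t and ``warn_flags``
    marks frames that were all-zero (shift forced to (0, 0)).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim not in (3, 4):
        raise ValueError("expected (t, y, x) or (t, z, y, x)")
    if data.shape[0] < 2:
        raise ValueError("need at least two frames to register")
    planes = data.max(axis=1) if data.ndim == 4 else data
    ref = planes[0]
    n = data.shape[0]
    shifts = np.zeros((n, 2))
    flags = np.zeros(n, dtype=bool)
    out = data.copy()
    for t in range(1, n):
        if not np.any(planes[t]):
            flags[t] = True
            continue
        shift = _estimate_shift(ref, planes[t], subpixel)
        shifts[t] = shift
        if subpixel and not np.allclose(shift, np.round(shift)):
            if data.ndim == 4:
                for z in range(data.shape[1]):
                    out[t, z] = ndimage.shift(data[t, z], shift, order=1, cval=0.0)
            else:
                out[t] = ndimage.shift(data[t], shift, order=1, cval=0.0)
        else:
            dy, dx = int(round(shift[0])), int(round(shift[1]))
            if data.ndim == 4:
                for z in range(data.shape[1]):
                    out[t, z] = _integer_shift2d(data[t, z], dy, dx)
            else:
                out[t] = _integer_shift2d(data[t], dy, dx)
    return out, shifts, flags


def register_axial(data: np.ndarray):
    """Correct per-frame z-drift of a (t, z, y, x) stack.

    Implements the reslice recipe: view the stack from the side (project
    over y to a (z, x) image), estimate each frame's z-translation against
    the first frame by the same cross-correlation method used laterally,
    shift in z with zero fill, and return to the original orientation.
    Frames whose estimated |z-shift| exceeds half the stack depth are
    flagged as unusable and left unshifted.

    Returns (registered, z_shifts, dropped_flags).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected (t, z, y, x)")
    n, nz = data.shape[0], data.shape[1]
    if nz < 3:
        raise ValueError("need z >= 3 for axial registration")
    side = data.max(axis=2)  # (t, z, x) side view
    ref = side[0]
    z_shifts = np.zeros(n, dtype=int)
    dropped = np.zeros(n, dtype=bool)
    out = data.copy()

    def best_z_shift(img):
        # explicit non-cyclic search: FFT correlation aliases shifts larger
        # than half the (small) z range
        best_dz, best_score = 0, -np.inf
        for dz in range(-(nz - 1), nz):
            if dz >= 0:
                score = float(np.sum(ref[dz:] * img[:nz - dz]))
            else:
                score = float(np.sum(ref[:nz + dz] * img[-dz:]))
            if score > best_score:
                best_score, best_dz = score, dz
        return best_dz

    for t in range(1, n):
        if not np.any(side[t]):
            dropped[t] = True
            continue
        dz = best_z_shift(side[t])
        if abs(dz) > nz // 2:
            dropped[t] = True
            continue
        z_shifts[t] = dz
        if dz != 0:
            shifted = np.zeros_like(data[t])
            if dz > 0:
                shifted[dz:] = data[t, :nz - dz]
            else:
                shifted[:nz + dz] = data[t, -dz:]
            out[t] = shifted
    return out, z_shifts, dropped


# ---------------------------------------------------------------------------
# Projection / binarisation / ROI
# ---------------------------------------------------------------------------

def max_project(data: np.ndarray) -> np.ndarray:
    """Per-frame maximum-intensity projection over z: (t, z, y, x) -> (t, y, x)."""
    data = np.asarray(data)
    if data.ndim == 3:
        return data
    if data.ndim != 4:
        raise ValueError("expected (t, z, y, x)")
    return data.max(axis=1)


def binarise(movie: np.ndarray, method: str = "otsu",
             threshold: float | None = None):
    """Threshold a 2-D movie with a single per-movie threshold.

    ``fixed`` uses the supplied threshold; ``otsu`` computes Otsu's
    threshold once on the temporal-mean frame and applies it to every
    frame, so bleaching cannot modulate the mask via per-frame thresholds.
    A pixel is foreground iff intensity >= threshold.

    Returns (mask (t, y, x) bool, threshold, empty_flag).
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("expected (t, y, x)")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(movie.mean(axis=0)))
    else:
        raise ValueError(f"unknown binarisation method {method!r}")
    mask = movie >= thr
    empty = not bool(mask.any())
    if empty:
        warnings.warn("binarisation produced no foreground pixels", stacklevel=2)
    return mask, thr, empty


def _polygon_is_simple(poly: np.ndarray) -> bool:
    from shapely.geometry import LinearRing

    try:
        return LinearRing(poly).is_simple
    except Exception:
        return False


def polygon_mask(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels inside a polygon (even-odd rule, boundary in).

    ``poly`` is (k, 2) [x, y] vertices in pixel units; a pixel belongs to
    the polygon iff its centre (col, row) is inside or on the boundary.
    """
    poly = np.asarray(poly, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise GeometryError("polygon needs >= 3 [x, y] vertices")
    if not _polygon_is_simple(poly):
        raise GeometryError("polygon is self-intersecting")
    from matplotlib.path import Path

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    path = Path(poly)  # implicitly closed for point tests
    # the signed radius grows the path on one side depending on vertex
    # orientation; taking the union of both signs puts boundary points inside
    inside = path.contains_points(pts, radius=1e-9)
    inside |= path.contains_points(pts, radius=-1e-9)
    return inside.reshape(h, w)


def apply_roi(movie_mask: np.ndarray, poly: Sequence[Sequence[float]],
              pixel_size_um: float, frame_interval_s: float,
              threshold: float | None = None) -> BinaryCellMovie:
    """Erase everything outside the ROI polygon and wrap as one cell's movie."""
    movie_mask = np.asarray(movie_mask, dtype=bool)
    roi = polygon_mask(np.asarray(poly, float), movie_mask.shape[-2:])
    return BinaryCellMovie(
        mask=movie_mask & roi[None],
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        roi=np.asarray(poly, float),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def preprocess_stack(stack: TimeLapseStack,
                     rois: Sequence[Sequence[Sequence[float]]] | None = None,
                     median_window: int = 3,
                     ball_radius_px: int = 30,
                     background_first: bool = True,
                     register: bool = True,
                     binarise_method: str = "otsu",
                     threshold: float | None = None):
    """Run the full preprocessing chain on a calibrated stack.

    Order (the surveillance recipe): background subtraction, then median
    filtering per slice (``background_first=False`` swaps them, the order
    used when no background step is wanted first), lateral then axial
    registration, maximum projection, single-threshold binarisation, and
    per-ROI cropping.  With ``rois=None`` a single whole-frame movie is
    returned.

    Returns (cells: list[BinaryCellMovie], info: dict).
    """
    data = np.asarray(stack.data, dtype=float)
    if background_first:
        if ball_radius_px:
            data = subtract_background_stack(data, ball_radius_px)
        data = median_filter_frames(data, median_window)
    else:
        data = median_filter_frames(data, median_window)
        if ball_radius_px:
            data = subtract_background_stack(data, ball_radius_px)
    info: dict = {}
    if register and stack.n_frames >= 2:
        data, shifts, flags = register_lateral(data)
        info["lateral_shifts"] = shifts
        info["lateral_flags"] = flags
        if data.shape[1] >= 3:
            data, z_shifts, dropped = register_axial(data)
            info["z_shifts"] = z_shifts
            info["z_dropped"] = dropped
    movie = max_project(data)
    mask, thr, empty = binarise(movie, method=binarise_method, threshold=threshold)
    info["threshold"] = thr
    info["empty"] = empty
    if rois is None:
        h, w = mask.shape[-2:]
        full = [[-0.5, -0.5], [w - 0.5, -0.5], [w - 0.5, h - 0.5], [-0.5, h - 0.5]]
        rois = [full]
    cells = [
        apply_roi(mask, roi, stack.pixel_size_um, stack.frame_interval_s, thr)
        for roi in rois
    ]
    return cells, info
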