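"""Radial-sector front tracking of directed microglial process motility.

When processes converge on an ATP source or laser lesion, the advancing
process front is tracked on binarised movies by dividing the field around
the target into concentric rings (2 um apart by default) crossed with 32
radial sectors.  For each frame and sector the algorithm scans outward from
the target for the first ring/sector patch holding more than ``min_pixels``
foreground pixels; the inner radius of that patch is the front distance.
The "clear area" still free of processes is the sum of circular-sector
areas at each sector's front radius — its shrinkage over time is the
directed-motility readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import BinaryCellMovie, GeometryError

__all__ = [
    "ChemotaxisGeometry",
    "FrontResult",
    "build_patches",
    "front_distances",
    "front_area",
    "chemotaxis_timecourse",
]


@dataclass
class ChemotaxisGeometry:
    """Ring/sector decomposition around a chemotactic target.

    ``target_px`` is (x, y) in pixel units; ``ring_um`` the concentric ring
    spacing; sectors span equal angles measured counterclockwise from +x.
    """

    target_px: tuple[float, float]
    pixel_size_um: float
    ring_um: float = 2.0
    n_sectors: int = 32
    min_pixels: int = 10
    max_radius_um: float = 100.0

    def __post_init__(self) -> None:
        if self.ring_um <= 0:
            raise ValueError("ring_um must be positive")
        if self.n_sectors < 4:
            raise ValueError("need at least 4 sectors")
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_rings(self) -> int:
        return int(np.ceil(self.max_radius_um / self.ring_um))


def build_patches(geometry: ChemotaxisGeometry, shape: tuple[int, int]):
    """Assign every pixel within ``max_radius_um`` a (ring, sector) patch.

    Ring j covers radii [j dr, (j+1) dr); sector k covers angles
    [2 pi k / n, 2 pi (k+1) / n) counterclockwise from +x.  Returns integer
    (ring_map, sector_map) arrays with -1 outside the search radius.
    """
    h, w = shape
    tx, ty = geometry.target_px
    if not (0 <= tx < w and 0 <= ty < h):
        raise GeometryError(f"target {geometry.target_px} outside frame {shape}")
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx = xx - tx
    dy = yy - ty
    r_um = np.hypot(dx, dy) * geometry.pixel_size_um
    ring = np.floor(r_um / geometry.ring_um).astype(int)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    sector = np.floor(theta / (2.0 * np.pi / geometry.n_sectors)).astype(int)
    sector = np.clip(sector, 0, geometry.n_sectors - 1)
    outside = r_um >= geometry.max_radius_um
    ring[outside] = -1
    sector[outside] = -1
    return ring, sector


def front_distances(frame: np.ndarray, geometry: ChemotaxisGeometry,
                    patches=None):
    """Per-sector front distance for one binary frame.

    For each sector, rings are scanned outward from the target; the front
    is the inner radius of the first patch with strictly more than
    ``min_pixels`` foreground pixels.  A sector with no qualifying patch is
    censored at ``max_radius_um``.

    Returns (distance_um (n_sectors,), censored (n_sectors,) bool).
    """
    frame = np.asarray(frame, dtype=bool)
    if patches is None:
        patches = build_patches(geometry, frame.shape)
    ring_map, sector_map = patches
    n_rings, n_sec = geometry.n_rings, geometry.n_sectors
    inside = ring_map >= 0
    fg = frame & inside
    # 2-D histogram of foreground pixels over (ring, sector)
    counts = np.zeros((n_rings, n_sec), dtype=np.int64)
    if fg.any():
        r = ring_map[fg]
        s = sector_map[fg]
        np.add.at(counts, (np.clip(r, 0, n_rings - 1), s), 1)
    dist = np.full(n_sec, geometry.max_radius_um, dtype=float)
    censored = np.ones(n_sec, dtype=bool)
    qualifies = counts > geometry.min_pixels
    for k in range(n_sec):
        hits = np.flatnonzero(qualifies[:, k])
        if len(hits):
            dist[k] = hits[0] * geometry.ring_um
            censored[k] = False
    return dist, censored


def front_area(distances: np.ndarray, geometry: ChemotaxisGeometry) -> float:
    """Area enclosed by the front: sum of circular-sector areas pi d_k^2 / n.

    Equals pi d^2 when every sector fronts at distance d, and
    pi max_radius^2 iff all sectors are censored.
    """
    d = np.asarray(distances, dtype=float)
    if len(d) != geometry.n_sectors:
        raise ValueError("distances must cover every sector")
    return float(np.sum(np.pi * d * d) / geometry.n_sectors)


@dataclass
class FrontResult:
    """Per-frame, per-sector front distances and the clear-area time course."""

    times_s: np.ndarray
    distance_um: np.ndarray      # (T, n_sectors)
    censored: np.ndarray         # (T, n_sectors) bool
    area_um2: np.ndarray         # (T,)
    geometry: ChemotaxisGeometry

    def normalized_area(self) -> np.ndarray:
        """Clear area relative to the first frame (starts at 1.0)."""
        if self.area_um2[0] == 0:
            raise ValueError("first-frame area is zero; cannot normalise")
        return self.area_um2 / self.area_um2[0]

    def to_sector_dataframe(self) -> pd.DataFrame:
        T, S = self.distance_um.shape
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(T), S),
                "time_s": np.repeat(self.times_s, S),
                "sector": np.tile(np.arange(S), T),
                "front_um": self.distance_um.ravel(),
                "censored": self.censored.ravel(),
            }
        )

    def to_area_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "clear_area_um2": self.area_um2,
                "normalized_area": self.normalized_area(),
            }
        )


def chemotaxis_timecourse(movie: BinaryCellMovie | np.ndarray,
                          geometry: ChemotaxisGeometry,
                          frame_interval_s: float | None = None) -> FrontResult:
    """Track the process front across a whole movie."""
    if isinstance(movie, BinaryCellMovie):
        mask = movie.mask
        frame_interval_s = movie.frame_interval_s
    else:
        mask = np.asarray(movie, dtype=bool)
        if frame_interval_s is None:
            raise ValueError("raw arrays need frame_interval_s")
    if mask.shape[0] < 2:
        raise ValueError("need at least two frames")
    patches = build_patches(geometry, mask.shape[-2:])
    T = mask.shape[0]
    dist = np.zeros((T, geometry.n_sectors))
    cens = np.zeros((T, geometry.n_sectors), dtype=bool)
    area = np.zeros(T)
    for t in range(T):
        dist[t], cens[t] = front_distances(mask[t], geometry, patches)
        area[t] = front_area(dist[t], geometry)
    times = np.arange(T) * frame_interval_s
    return FrontResult(times, dist, cens, area, geometry)


def aggregate_timecourses(results: list[FrontResult],
                          normalize: bool = True) -> pd.DataFrame:
    """Mean +- SEM clear area across movies per time point."""
    if not results:
        raise ValueError("no results to aggregate")
    T = min(len(r.area_um2) for r in results)
    stack = np.stack(
        [r.normalized_area()[:T] if normalize else r.area_um2[:T] for r in results]
    )
    return pd.DataFrame(
        {
            "time_s": results[0].times_s[:T],
            "mean": stack.mean(axis=0),
            "sem": stack.std(axis=0, ddof=1) / np.sqrt(len(results))
            if len(results) > 1
            else np.zeros(T),
            "n": len(results),
        }
    )
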