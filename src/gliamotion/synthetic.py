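"""Synthetic microglia time-lapse generator with complete ground truth.

No raw two-photon data ship with the analysis this package re-implements,
so every stage is validated against simulated movies that emulate the
acquisition geometry of slice/in-vivo microglia imaging: 512 x 512 frames
covering a 200-250 um field, 21-31 z-slices at 2 um spacing, frames every
30-60 s.  Cells are a disk-shaped soma plus branching processes whose tips
perform biased random walks (extend/retract at configurable um/min rates,
optionally drawn toward a chemotactic target).  The continuous skeleton is
the ground truth; it is rasterized into per-frame binary masks (the oracle
for every mask-level metric) and rendered into a calibrated intensity
stack with a bright soma, steep-shouldered process cross-section, additive
noise, and optional exponential bleaching.

Reproducibility: every cell owns a named generator derived from the master
seed, so adding cells (or changing the noise) never perturbs the movement
of existing ones; identical (config, seed) gives bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .morphometry import MorphTree, ShollProfile, sholl_intersections, write_swc
from .preprocess import GeometryError, TimeLapseStack

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_cell",
    "simulate_surveillance",
    "simulate_chemotaxis",
    "generate_swc_population",
]

_SOMA_AMP = 1.6     # soma peak intensity relative to process amplitude 1.0
_SEG_UM = 1.2       # sub-segment length used when growing processes
_TURN_SD = 0.18     # radians of direction noise per sub-segment
_Z_SIGMA_SLICES = 1.2


@dataclass
class SynthConfig:
    """Study conditions for the simulator.

    Defaults follow the acquisition they emulate (225 um field on 512 px,
    25 slices at 2 um, 60 s frames for surveillance); tip kinetics are
    plausible-by-literature phenomenological knobs, not measured values.
    """

    field_width_um: float = 225.0
    frame_px: int = 512
    n_z: int = 25
    z_step_um: float = 2.0
    frame_interval_s: float = 60.0
    n_frames: int = 20
    n_cells: int = 3
    n_primary_processes: int = 6
    branch_prob_per_um: float = 0.04
    extend_rate_um_per_min: float = 1.5
    retract_rate_um_per_min: float = 1.5
    process_width_um: float = 2.0      # full width of the dilated process
    soma_radius_um: float = 4.0
    initial_process_length_um: float = 18.0
    target_point: tuple[float, float] | None = None   # (x, y) in um
    bias_strength: float = 0.0
    noise_sd: float = 0.05
    bleach_tau_frames: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("extend_rate_um_per_min", "retract_rate_um_per_min",
                     "branch_prob_per_um", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.bias_strength <= 1.0):
            raise ValueError("bias_strength must lie in [0, 1]")
        for name in ("field_width_um", "frame_interval_s", "z_step_um",
                     "process_width_um", "soma_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.frame_px < 16 or self.n_z < 1:
            raise ValueError("frame_px >= 16 and n_z >= 1 required")
        if self.n_primary_processes < 0:
            raise ValueError("n_primary_processes must be >= 0")

    @property
    def pixel_size_um(self) -> float:
        return self.field_width_um / self.frame_px

    @property
    def dt_min(self) -> float:
        return self.frame_interval_s / 60.0


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    masks: np.ndarray                 # (n_cells, T, H, W) bool
    pe_counts: np.ndarray             # (n_cells, T-1) true extension pixels
    pr_counts: np.ndarray             # (n_cells, T-1) true retraction pixels
    area_um2: np.ndarray              # (n_cells, T) analytic (overlap-ignoring)
    perimeter_um: np.ndarray          # (n_cells, T) analytic (overlap-ignoring)
    n_processes: np.ndarray           # (n_cells,) primary stems
    n_branch_points: np.ndarray       # (n_cells, T)
    total_length_um: np.ndarray       # (n_cells, T)
    trees: list[MorphTree]            # first-frame morphologies
    front_distance_um: np.ndarray | None = None   # (T, n_sectors), chemotaxis
    front_censored: np.ndarray | None = None
    front_area_um2: np.ndarray | None = None

    def combined_masks(self) -> np.ndarray:
        """(T, H, W) union over cells."""
        return self.masks.any(axis=0)


# ---------------------------------------------------------------------------
# growth model
# ---------------------------------------------------------------------------

class _Branch:
    __slots__ = ("points", "z_um", "init_dir", "parent", "anchor_idx",
                 "children_anchor")

    def __init__(self, start, direction, z_um, parent=-1, anchor_idx=0):
        self.points: list[np.ndarray] = [np.asarray(start, float)]
        self.init_dir = np.asarray(direction, float)
        self.z_um = float(z_um)
        self.parent = parent              # index into cell.branches, -1 = soma
        self.anchor_idx = anchor_idx      # point index on the parent
        self.children_anchor: list[int] = []   # own point indices with children

    @property
    def tip(self) -> np.ndarray:
        return self.points[-1]

    def direction(self) -> np.ndarray:
        if len(self.points) >= 2:
            d = self.points[-1] - self.points[-2]
            n = np.linalg.norm(d)
            if n > 0:
                return d / n
        return self.init_dir

    def length(self) -> float:
        pts = np.asarray(self.points)
        if len(pts) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def retract_floor(self) -> int:
        return max(self.children_anchor, default=0)


class _Cell:
    def __init__(self, center, soma_z_um, rng):
        self.center = np.asarray(center, float)
        self.soma_z_um = float(soma_z_um)
        self.rng = rng
        self.branches: list[_Branch] = []


def _rotate(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _extend_branch(cell: _Cell, branch: _Branch, length_um: float,
                   config: SynthConfig, target_um=None,
                   bias: float = 0.0) -> float:
    """Grow a branch tip by ~length_um; returns the length actually added.

    May spawn child branches (Poisson along the newly extended length).
    """
    rng = cell.rng
    added = 0.0
    remaining = length_um
    d = branch.direction()
    while remaining > 1e-9:
        seg = min(_SEG_UM, remaining)
        d = _rotate(d, rng.normal(0.0, _TURN_SD))
        if bias > 0.0 and target_um is not None:
            to_t = np.asarray(target_um, float) - branch.tip
            dist_t = np.linalg.norm(to_t)
            if dist_t > 1e-9:
                d = _unit((1.0 - bias) * d + bias * (to_t / dist_t))
                seg = min(seg, dist_t)   # never overshoot the target
            else:
                break
        new = branch.tip + seg * d
        half = config.field_width_um
        new = np.clip(new, 1.0, half - 1.0)  # stay inside the field
        branch.points.append(new)
        added += seg
        remaining -= seg
    if added > 0 and config.branch_prob_per_um > 0:
        n_spawn = rng.poisson(config.branch_prob_per_um * added)
        for _ in range(min(n_spawn, 2)):
            if len(branch.points) < 3:
                break
            # interior anchor only, so the anchor node always has both a
            # continuation child and the spawned branch (a true branch point)
            idx = rng.integers(1, len(branch.points) - 1)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            child_dir = _rotate(branch.direction(),
                                sign * rng.uniform(0.5, 1.1))
            child = _Branch(branch.points[idx], child_dir,
                            branch.z_um + rng.uniform(-0.5, 0.5) * config.z_step_um,
                            parent=cell.branches.index(branch),
                            anchor_idx=idx)
            branch.children_anchor.append(idx)
            cell.branches.append(child)
    return added


def _retract_branch(branch: _Branch, length_um: float) -> float:
    removed = 0.0
    floor = branch.retract_floor()
    while removed < length_um and len(branch.points) - 1 > floor:
        seg = np.linalg.norm(branch.points[-1] - branch.points[-2])
        if removed + seg > length_um and len(branch.points) >= 2:
            # partial removal of the last segment
            frac = (length_um - removed) / seg
            branch.points[-1] = branch.points[-1] * (1 - frac) + \
                branch.points[-2] * frac
            removed = length_um
            break
        branch.points.pop()
        removed += seg
    return removed


def _init_cell(config: SynthConfig, center, rng, z_um: float | None = None) -> _Cell:
    field_w = config.field_width_um
    center = np.asarray(center, float)
    if not (0 <= center[0] <= field_w and 0 <= center[1] <= field_w):
        raise GeometryError(f"cell center {tuple(center)} outside the field")
    if z_um is None:
        z_um = (config.n_z // 2) * config.z_step_um
    cell = _Cell(center, z_um, rng)
    n = config.n_primary_processes
    base = rng.uniform(0.0, 2.0 * np.pi)
    for k in range(n):
        ang = base + 2.0 * np.pi * k / max(n, 1) + rng.normal(0.0, 0.25)
        d = np.array([math.cos(ang), math.sin(ang)])
        start = center + config.soma_radius_um * d
        branch = _Branch(start, d,
                         z_um + rng.uniform(-3.0, 3.0) * config.z_step_um / 2.0)
        cell.branches.append(branch)
        target_len = config.initial_process_length_um * rng.uniform(0.7, 1.3)
        _extend_branch(cell, branch, target_len, config)
    # grow side branches spawned during initial outgrowth (their own
    # children, if any, are picked up by later sweeps)
    for depth, frac in enumerate((0.5, 0.3, 0.2)):
        stubs = [b for b in cell.branches if b.parent != -1 and
                 len(b.points) == 1]
        if not stubs:
            break
        for b in stubs:
            _extend_branch(cell, b, frac * config.initial_process_length_um *
                           rng.uniform(0.6, 1.2), config)
    return cell


def _step_cell(cell: _Cell, config: SynthConfig,
               target_um=None, bias: float = 0.0) -> None:
    """Advance every process tip by one frame interval."""
    rng = cell.rng
    dt = config.dt_min
    p_retract = 0.5 * (1.0 - bias)
    for branch in list(cell.branches):
        if config.retract_rate_um_per_min > 0 and rng.random() < p_retract:
            L = config.retract_rate_um_per_min * dt * rng.uniform(0.5, 1.5)
            if L > 0:
                _retract_branch(branch, L)
        else:
            L = config.extend_rate_um_per_min * dt * rng.uniform(0.5, 1.5)
            if L > 0:
                _extend_branch(cell, branch, L, config, target_um, bias)


# ---------------------------------------------------------------------------
# tree export and analytic ground truth
# ---------------------------------------------------------------------------

def _cell_to_tree(cell: _Cell, config: SynthConfig) -> MorphTree:
    ids, types, xyz, radius, parent = [], [], [], [], []
    ids.append(1)
    types.append(1)
    xyz.append([cell.center[0], cell.center[1], cell.soma_z_um])
    radius.append(config.soma_radius_um)
    parent.append(-1)
    next_id = 2
    node_of: dict[tuple[int, int], int] = {}
    for bi, branch in enumerate(cell.branches):
        if branch.parent == -1:
            parent_id = 1
        else:
            parent_id = node_of[(branch.parent, branch.anchor_idx)]
        for pi, pt in enumerate(branch.points):
            if branch.parent != -1 and pi == 0:
                # the anchor point already exists as a node on the parent
                node_of[(bi, 0)] = parent_id
                continue
            ids.append(next_id)
            types.append(3)
            xyz.append([pt[0], pt[1], branch.z_um])
            radius.append(config.process_width_um / 2.0)
            parent.append(parent_id)
            node_of[(bi, pi)] = next_id
            parent_id = next_id
            next_id += 1
    return MorphTree(ids=np.array(ids), types=np.array(types),
                     xyz=np.array(xyz), radius=np.array(radius),
                     parent=np.array(parent))


def _cell_stats(cell: _Cell, config: SynthConfig):
    """(n_stems, n_branch_points, total_length_um) from the growth state.

    Lengths are 3-D: a branch lives at a fixed z-offset, so only its first
    edge (anchor on the parent, or the soma-to-rim stem edge) spans a dz.
    """
    stems = 0
    # a branch point exists only where a spawned child has actual length
    anchors = {(b.parent, b.anchor_idx) for b in cell.branches
               if b.parent != -1 and len(b.points) >= 2}
    branch_points = len(anchors)
    length = 0.0
    for b in cell.branches:
        pts = b.points
        if b.parent == -1:
            stems += 1
            dz = b.z_um - cell.soma_z_um
            length += math.hypot(config.soma_radius_um, dz)
            parent_z = b.z_um     # stem polyline itself is planar
        else:
            parent_z = cell.branches[b.parent].z_um
        for i in range(1, len(pts)):
            d2 = float(np.linalg.norm(pts[i] - pts[i - 1]))
            if i == 1 and b.parent != -1:
                d2 = math.hypot(d2, b.z_um - parent_z)
            length += d2
    return stems, branch_points, length


def _analytic_geometry(cell: _Cell, config: SynthConfig):
    """Overlap-ignoring analytic area and perimeter (upper bounds, um)."""
    w = config.process_width_um / 2.0
    r = config.soma_radius_um
    total_len = sum(b.length() for b in cell.branches)
    n_tips = len(cell.branches)
    area = math.pi * r * r + 2.0 * w * total_len + n_tips * math.pi * w * w / 2.0
    perim = 2.0 * math.pi * r + 2.0 * total_len + n_tips * math.pi * w
    return area, perim


# ---------------------------------------------------------------------------
# rasterization and rendering
# ---------------------------------------------------------------------------

def _skeleton_samples(cell: _Cell, config: SynthConfig):
    """Dense (x, y, z) samples along every branch polyline, in um."""
    step = 0.3 * config.pixel_size_um
    pts, zs = [], []
    for branch in cell.branches:
        poly = np.asarray(branch.points)
        if len(poly) == 1:
            pts.append(poly)
            zs.append(np.full(1, branch.z_um))
            continue
        seg = np.diff(poly, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        for i in range(len(seg)):
            n = max(2, int(math.ceil(seg_len[i] / step)) + 1)
            t = np.linspace(0.0, 1.0, n, endpoint=False)
            pts.append(poly[i] + t[:, None] * seg[i])
            zs.append(np.full(n, branch.z_um))
        pts.append(poly[-1:])
        zs.append(np.full(1, branch.z_um))
    if pts:
        return np.concatenate(pts), np.concatenate(zs)
    return np.empty((0, 2)), np.empty(0)


def _rasterize_cell(cell: _Cell, config: SynthConfig):
    """(true_mask, d_skel_px, z_map_um, d_soma_px) on the full frame grid."""
    H = W = config.frame_px
    ps = config.pixel_size_um
    samples, zs = _skeleton_samples(cell, config)
    canvas = np.zeros((H, W), dtype=bool)
    zcanvas = np.full((H, W), cell.soma_z_um)
    if len(samples):
        cols = np.clip(np.round(samples[:, 0] / ps).astype(int), 0, W - 1)
        rows = np.clip(np.round(samples[:, 1] / ps).astype(int), 0, H - 1)
        canvas[rows, cols] = True
        zcanvas[rows, cols] = zs
    if canvas.any():
        d_skel, (ir, ic) = ndimage.distance_transform_edt(
            ~canvas, return_indices=True)
        z_map = zcanvas[ir, ic]
    else:
        d_skel = np.full((H, W), np.inf)
        z_map = zcanvas
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    d_soma = np.hypot(xx - cell.center[0] / ps, yy - cell.center[1] / ps)
    w_px = (config.process_width_um / 2.0) / ps
    soma_px = config.soma_radius_um / ps
    mask = (d_skel <= w_px) | (d_soma <= soma_px)
    return mask, d_skel, z_map, d_soma


def _render_cell(cell: _Cell, config: SynthConfig, d_skel, z_map, d_soma):
    """(intensity_2d, z_center_um) maps for one cell.

    Cross-sections are steep super-Gaussian (exponent 8) with half-maximum
    at the ground-truth radius, so the half-height contour of the rendered
    image coincides with the true mask boundary and any threshold in a wide
    band recovers the true process width.
    """
    ps = config.pixel_size_um
    w_px = max((config.process_width_um / 2.0) / ps, 0.5)
    soma_px = max(config.soma_radius_um / ps, 0.5)
    ln2 = math.log(2.0)
    with np.errstate(over="ignore"):
        proc = np.exp(-ln2 * (d_skel / w_px) ** 8)
        soma = _SOMA_AMP * np.exp(-ln2 * (d_soma / soma_px) ** 8)
    intensity = np.maximum(proc, soma)
    zc = np.where(soma >= proc, cell.soma_z_um, z_map)
    return intensity, zc


def _render_stack_frame(cells_maps, config: SynthConfig) -> np.ndarray:
    """Compose per-cell (intensity, z_center) maps into one (z, y, x) frame."""
    H = W = config.frame_px
    frame = np.zeros((config.n_z, H, W), dtype=np.float32)
    sigma_z = _Z_SIGMA_SLICES * config.z_step_um
    z_levels = np.arange(config.n_z) * config.z_step_um
    for intensity, zc in cells_maps:
        nz = intensity > 1e-4
        if not nz.any():
            continue
        inten = intensity[nz].astype(np.float32)
        zcv = zc[nz]
        for zi, z_um in enumerate(z_levels):
            w = np.exp(-((z_um - zcv) ** 2) / (2.0 * sigma_z ** 2))
            plane = frame[zi]
            vals = (inten * w).astype(np.float32)
            flat = plane[nz]
            plane[nz] = np.maximum(flat, vals)
    return frame


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _cell_rng(config: SynthConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 101, index])


def generate_cell(config: SynthConfig, center) -> tuple[MorphTree, np.ndarray]:
    """Generate one static ramified cell: its morphology tree and true mask.

    ``center`` is (x, y) in micrometres; must lie inside the field.
    """
    cell = _init_cell(config, center, _cell_rng(config, 0))
    tree = _cell_to_tree(cell, config)
    mask, *_ = _rasterize_cell(cell, config)
    return tree, mask


def _place_centers(config: SynthConfig, mode: str):
    """Per-cell soma positions; each drawn from that cell's own generator."""
    centers = []
    margin = 0.18 * config.field_width_um
    for i in range(config.n_cells):
        rng = np.random.default_rng([config.seed, 202, i])
        if mode == "chemotaxis":
            # microglia tile the parenchyma roughly evenly, so the somata
            # surrounding a damage site are stratified in angle
            tx, ty = config.target_point
            ang = (2.0 * np.pi * i / config.n_cells +
                   rng.uniform(-0.3, 0.3))
            rad = rng.uniform(45.0, 70.0)
            c = np.array([tx + rad * math.cos(ang), ty + rad * math.sin(ang)])
            c = np.clip(c, margin * 0.3, config.field_width_um - margin * 0.3)
        else:
            c = rng.uniform(margin, config.field_width_um - margin, size=2)
        centers.append(c)
    return centers


def _sector_of(dx: np.ndarray, dy: np.ndarray, n_sectors: int) -> np.ndarray:
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    return np.clip(np.floor(theta / (2.0 * np.pi / n_sectors)).astype(int),
                   0, n_sectors - 1)


def _true_front(cells, config: SynthConfig, n_sectors: int,
                ring_um: float, max_radius_um: float,
                min_pixels: int = 10, oversample: int = 3):
    """True per-sector front by the qualifying-patch rule, measured on the
    continuous cell footprint.

    The union of all soma disks and process tubes (skeleton dilated to the
    true half-width) is evaluated on a grid ``oversample`` times finer than
    the image raster, so the truly occupied area of every (ring, sector)
    patch is known without rendering, noise, or thresholding.  The front is
    the inner radius of the first patch whose occupied area exceeds
    ``min_pixels`` image pixels' worth — the same criterion the mask-based
    tracker applies.
    """
    tx, ty = config.target_point
    fine = config.pixel_size_um / oversample
    half = max_radius_um
    n = int(math.ceil(2.0 * half / fine)) + 1
    x0, y0 = tx - half, ty - half
    canvas = np.zeros((n, n), dtype=bool)
    step = 0.4 * fine
    for cell in cells:
        for branch in cell.branches:
            poly = np.asarray(branch.points)
            if len(poly) < 2:
                continue
            seg = np.diff(poly, axis=0)
            seg_len = np.linalg.norm(seg, axis=1)
            for i in range(len(seg)):
                if seg_len[i] == 0:
                    continue
                m = max(2, int(math.ceil(seg_len[i] / step)))
                t = np.linspace(0.0, 1.0, m + 1)
                pts = poly[i] + t[:, None] * seg[i]
                cols = np.round((pts[:, 0] - x0) / fine).astype(int)
                rows = np.round((pts[:, 1] - y0) / fine).astype(int)
                ok = (cols >= 0) & (cols < n) & (rows >= 0) & (rows < n)
                canvas[rows[ok], cols[ok]] = True
    if canvas.any():
        d_um = ndimage.distance_transform_edt(~canvas) * fine
    else:
        d_um = np.full((n, n), np.inf)
    occupied = d_um <= config.process_width_um / 2.0
    coords = np.arange(n) * fine
    X = x0 + coords[None, :]
    Y = y0 + coords[:, None]
    for cell in cells:
        cx, cy = cell.center
        occupied |= (X - cx) ** 2 + (Y - cy) ** 2 <= config.soma_radius_um ** 2
    dx = np.broadcast_to(X - tx, (n, n))
    dy = np.broadcast_to(Y - ty, (n, n))
    r = np.hypot(dx, dy)
    keep = occupied & (r < max_radius_um)
    n_rings = int(math.ceil(max_radius_um / ring_um))
    acc = np.zeros((n_rings, n_sectors))
    if keep.any():
        ring = np.floor(r[keep] / ring_um).astype(int)
        sec = _sector_of(dx[keep], dy[keep], n_sectors)
        np.add.at(acc, (np.clip(ring, 0, n_rings - 1), sec), fine * fine)
    thresh = min_pixels * config.pixel_size_um ** 2
    dist = np.full(n_sectors, max_radius_um)
    cens = np.ones(n_sectors, dtype=bool)
    qual = acc > thresh
    for k in range(n_sectors):
        hits = np.flatnonzero(qual[:, k])
        if len(hits):
            dist[k] = hits[0] * ring_um
            cens[k] = False
    return dist, cens


def _simulate(config: SynthConfig, mode: str,
              n_sectors: int = 32, ring_um: float = 2.0,
              max_radius_um: float | None = None,
              render: bool = True):
    if config.n_frames < 2:
        raise ValueError("need n_frames >= 2")
    if config.n_cells < 1:
        raise ValueError("need n_cells >= 1")
    if mode == "chemotaxis":
        if config.target_point is None:
            raise ValueError("chemotaxis mode requires target_point")
        if max_radius_um is None:
            max_radius_um = 0.45 * config.field_width_um
    bias = config.bias_strength if mode == "chemotaxis" else 0.0
    target = config.target_point if mode == "chemotaxis" else None

    centers = _place_centers(config, mode)
    cells = [
        _init_cell(config, centers[i], _cell_rng(config, i))
        for i in range(config.n_cells)
    ]
    T = config.n_frames
    H = W = config.frame_px
    n_z_out = config.n_z if render else 1
    masks = np.zeros((config.n_cells, T, H, W), dtype=bool)
    area = np.zeros((config.n_cells, T))
    perim = np.zeros((config.n_cells, T))
    nbp = np.zeros((config.n_cells, T), dtype=int)
    tlen = np.zeros((config.n_cells, T))
    stack = np.zeros((T, n_z_out, H, W), dtype=np.float32)
    fronts = np.zeros((T, n_sectors)) if mode == "chemotaxis" else None
    fcens = np.zeros((T, n_sectors), dtype=bool) if mode == "chemotaxis" else None
    fareas = np.zeros(T) if mode == "chemotaxis" else None

    trees = [_cell_to_tree(c, config) for c in cells]
    stems = np.array([_cell_stats(c, config)[0] for c in cells])

    noise_rng = np.random.default_rng([config.seed, 909])
    for t in range(T):
        if t > 0:
            for cell in cells:
                _step_cell(cell, config, target_um=target, bias=bias)
        maps = []
        for i, cell in enumerate(cells):
            mask, d_skel, z_map, d_soma = _rasterize_cell(cell, config)
            masks[i, t] = mask
            area[i, t], perim[i, t] = _analytic_geometry(cell, config)
            _, nbp[i, t], tlen[i, t] = _cell_stats(cell, config)
            if render:
                maps.append(_render_cell(cell, config, d_skel, z_map, d_soma))
        if render:
            frame = _render_stack_frame(maps, config)
            if config.bleach_tau_frames:
                frame *= np.float32(math.exp(-t / config.bleach_tau_frames))
            if config.noise_sd > 0:
                frame = frame + noise_rng.normal(
                    0.0, config.noise_sd, frame.shape).astype(np.float32)
                np.clip(frame, 0.0, None, out=frame)
            stack[t] = frame
        if mode == "chemotaxis":
            fronts[t], fcens[t] = _true_front(
                cells, config, n_sectors, ring_um, max_radius_um)
            fareas[t] = float(np.sum(np.pi * fronts[t] ** 2) / n_sectors)

    pe = np.zeros((config.n_cells, T - 1), dtype=np.int64)
    pr = np.zeros((config.n_cells, T - 1), dtype=np.int64)
    for i in range(config.n_cells):
        curr, prev = masks[i, 1:], masks[i, :-1]
        pe[i] = (curr & ~prev).reshape(T - 1, -1).sum(axis=1)
        pr[i] = (prev & ~curr).reshape(T - 1, -1).sum(axis=1)

    gt = GroundTruth(
        masks=masks, pe_counts=pe, pr_counts=pr,
        area_um2=area, perimeter_um=perim,
        n_processes=stems, n_branch_points=nbp, total_length_um=tlen,
        trees=trees,
        front_distance_um=fronts, front_censored=fcens,
        front_area_um2=fareas,
    )
    tls = TimeLapseStack(
        data=stack,
        pixel_size_um=config.pixel_size_um,
        z_step_um=config.z_step_um,
        frame_interval_s=config.frame_interval_s,
    )
    return tls, gt


def simulate_surveillance(config: SynthConfig, render: bool = True):
    """Baseline-surveillance movie: tips wander isotropically.

    Returns (TimeLapseStack, GroundTruth).  ``render=False`` skips the
    intensity rendering (the returned stack is a single empty z-plane) for
    work that only needs the ground truth.
    """
    return _simulate(config, "surveillance", render=render)


def simulate_chemotaxis(config: SynthConfig, n_sectors: int = 32,
                        ring_um: float = 2.0,
                        max_radius_um: float | None = None,
                        render: bool = True):
    """Directed-motility movie: tips biased toward ``config.target_point``.

    ``bias_strength`` blends the isotropic walk (0) with a straight march
    on the target (1); retraction probability scales down with bias, so at
    bias 1 every tip's distance to the target is non-increasing.  The
    ground truth includes per-frame per-sector true front distances.
    """
    if config.target_point is None:
        raise ValueError("chemotaxis mode requires target_point in the config")
    return _simulate(config, "chemotaxis", n_sectors=n_sectors,
                     ring_um=ring_um, max_radius_um=max_radius_um,
                     render=render)


# ---------------------------------------------------------------------------
# SWC population generator (fixed-tissue morphometry fixtures)
# ---------------------------------------------------------------------------

def _grow_tree_3d(rng: np.random.Generator, n_stems: int, soma_radius: float,
                  mean_length: float, branch_prob_per_um: float,
                  z_compression: float = 0.4):
    """Random 3-D tree around a soma at the origin; returns a MorphTree."""
    ids = [1]
    types = [1]
    xyz = [[0.0, 0.0, 0.0]]
    radius = [soma_radius]
    parent = [-1]
    next_id = 2
    n_branch_points = 0
    queue = []
    for _ in range(n_stems):
        d = rng.normal(size=3)
        d[2] *= z_compression
        d /= np.linalg.norm(d)
        start = soma_radius * d
        queue.append((1, start, d, mean_length * rng.uniform(0.7, 1.3)))
    seg = 1.5
    while queue:
        parent_id, pos, d, remaining = queue.pop(0)
        # attach first node of this branch
        first = True
        while remaining > 0:
            step = min(seg, remaining)
            turn = rng.normal(0.0, 0.25, size=3)
            turn[2] *= z_compression
            d = d + turn
            d /= np.linalg.norm(d)
            pos = pos + step * d
            ids.append(next_id)
            types.append(3)
            xyz.append(list(pos))
            radius.append(0.6)
            parent.append(parent_id)
            parent_id = next_id
            next_id += 1
            remaining -= step
            if not first and remaining > seg and \
                    rng.random() < branch_prob_per_um * step:
                child_d = d + rng.normal(0.0, 0.8, size=3)
                child_d[2] *= z_compression
                child_d /= np.linalg.norm(child_d)
                queue.append((parent_id, pos.copy(), child_d, remaining * 0.7))
                n_branch_points += 1
            first = False
    tree = MorphTree(ids=np.array(ids), types=np.array(types),
                     xyz=np.array(xyz), radius=np.array(radius),
                     parent=np.array(parent))
    return tree


@dataclass
class SwcGroundTruth:
    n_processes: list[int]
    n_branch_points: list[int]
    total_length_um: list[float]
    sholl: list[ShollProfile]
    paths: list[str] = field(default_factory=list)


def generate_swc_population(n_cells: int, seed: int = 0,
                            n_stems: int = 6, soma_radius_um: float = 4.0,
                            mean_length_um: float = 25.0,
                            branch_prob_per_um: float = 0.05,
                            dr_um: float = 1.0,
                            out_dir=None):
    """Generate a population of random SWC morphologies with ground truth.

    Each cell's tree is grown by its own generator derived from the master
    seed.  If ``out_dir`` is given, deterministic SWC files are written
    there (cell_000.swc, ...).  Returns (trees, SwcGroundTruth).
    """
    if n_cells < 1:
        raise ValueError("need n_cells >= 1")
    from .morphometry import count_processes, total_length

    trees, gt_sholl = [], []
    n_proc, n_bp, lengths, paths = [], [], [], []
    for i in range(n_cells):
        rng = np.random.default_rng([seed, 303, i])
        tree = _grow_tree_3d(rng, n_stems, soma_radius_um,
                             mean_length_um, branch_prob_per_um)
        trees.append(tree)
        s, b = count_processes(tree)
        n_proc.append(s)
        n_bp.append(b)
        lengths.append(total_length(tree))
        prof = sholl_intersections(tree, dr_um=dr_um)
        prof.label = f"cell_{i:03d}"
        gt_sholl.append(prof)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, tree in enumerate(trees):
            p = out_dir / f"cell_{i:03d}.swc"
            write_swc(tree, p)
            paths.append(str(p))
    gt = SwcGroundTruth(n_processes=n_proc, n_branch_points=n_bp,
                        total_length_um=lengths, sholl=gt_sholl, paths=paths)
    return trees, gt


# ---------------------------------------------------------------------------
# ground-truth archive
# ---------------------------------------------------------------------------

def save_ground_truth(gt: GroundTruth, out_dir) -> None:
    """Write masks as a compressed npz plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out_dir / "ground_truth.npz",
                        masks=gt.masks, pe_counts=gt.pe_counts,
                        pr_counts=gt.pr_counts)
    manifest = {
        "n_cells": int(gt.masks.shape[0]),
        "n_frames": int(gt.masks.shape[1]),
        "n_processes": [int(v) for v in gt.n_processes],
        "total_length_um_t0": [float(v) for v in gt.total_length_um[:, 0]],
        "has_front": gt.front_distance_um is not None,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
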