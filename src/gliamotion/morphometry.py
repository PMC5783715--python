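"""Sholl analysis and morphometrics on SWC tree reconstructions.

Microglial (or neuronal) morphology is commonly summarised by three numbers
— how many primary processes leave the soma, how long the arbor is in total,
and how often the processes intersect concentric shells drawn at increasing
radii from the soma (the Sholl profile).  This module reads standard SWC
reconstructions, computes those measures, and compares groups of cells with
a two-way (group x radius) ANOVA on their Sholl profiles.

SWC dialect: whitespace-delimited, 7 columns (id, type, x, y, z, radius,
parent), ``#`` comments, parent ``-1`` for the root.  Coordinates are in
micrometres.  Unknown type codes are preserved; type 1 marks soma nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MorphTree",
    "ShollProfile",
    "read_swc",
    "write_swc",
    "sholl_intersections",
    "count_processes",
    "total_length",
    "compare_groups",
]

SOMA_TYPE = 1


class SWCFormatError(ValueError):
    """Raised when an SWC file violates the format (with the line number)."""


@dataclass
class MorphTree:
    """A rooted tree morphology: parallel node arrays linked by parent ids.

    ``ids`` are the original SWC identifiers (arbitrary positive ints);
    ``parent`` holds SWC ids as well, with -1 for the single root.
    """

    ids: np.ndarray          # (n,) int
    types: np.ndarray        # (n,) int
    xyz: np.ndarray          # (n, 3) float, micrometres
    radius: np.ndarray       # (n,) float
    parent: np.ndarray       # (n,) int, SWC id or -1

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.types = np.asarray(self.types, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        n = len(self.ids)
        if self.xyz.shape != (n, 3):
            raise SWCFormatError("coordinate table must be (n, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise SWCFormatError("non-finite coordinates")
        if len(np.unique(self.ids)) != n:
            raise SWCFormatError("duplicate node ids")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise SWCFormatError(f"expected exactly one root, found {len(roots)}")
        id_to_idx = {int(i): k for k, i in enumerate(self.ids)}
        self._id_to_idx = id_to_idx
        for k, p in enumerate(self.parent):
            if p != -1 and int(p) not in id_to_idx:
                raise SWCFormatError(f"node {self.ids[k]} references missing parent {p}")
        # cycle check by walking each node to the root
        for k in range(n):
            seen = set()
            j = k
            while self.parent[j] != -1:
                if j in seen:
                    raise SWCFormatError(f"cycle involving node id {self.ids[k]}")
                seen.add(j)
                j = id_to_idx[int(self.parent[j])]

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def parent_index(self) -> np.ndarray:
        """Positional index of each node's parent (-1 for the root)."""
        out = np.full(self.n_nodes, -1, dtype=int)
        for k, p in enumerate(self.parent):
            if p != -1:
                out[k] = self._id_to_idx[int(p)]
        return out

    def children_counts(self) -> np.ndarray:
        pidx = self.parent_index()
        counts = np.zeros(self.n_nodes, dtype=int)
        for p in pidx:
            if p >= 0:
                counts[p] += 1
        return counts

    def soma_centroid(self) -> np.ndarray:
        """Mean position of soma-type nodes; falls back to the root node."""
        soma = self.types == SOMA_TYPE
        if soma.any():
            return self.xyz[soma].mean(axis=0)
        return self.xyz[self.root_index]

    def edges(self, exclude_intra_soma: bool = True) -> np.ndarray:
        """(m, 2) array of (child_idx, parent_idx) positional index pairs."""
        pidx = self.parent_index()
        child = np.flatnonzero(pidx >= 0)
        pairs = np.stack([child, pidx[child]], axis=1)
        if exclude_intra_soma:
            both_soma = (self.types[pairs[:, 0]] == SOMA_TYPE) & (
                self.types[pairs[:, 1]] == SOMA_TYPE
            )
            pairs = pairs[~both_soma]
        return pairs

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "type": self.types,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "radius": self.radius,
                "parent": self.parent,
            }
        )


@dataclass
class ShollProfile:
    """Sholl intersection profile plus scalar morphometrics for one cell."""

    radii_um: np.ndarray
    intersections: np.ndarray
    n_processes: int
    n_branch_points: int
    total_length_um: float
    n_branches_total: int = 0
    label: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius_um": self.radii_um,
                "intersections": self.intersections,
                "cell": self.label,
            }
        )


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> MorphTree:
    """Parse an SWC file; '#' comments and blank lines are skipped."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 7:
                raise SWCFormatError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        int(parts[0]),
                        int(parts[1]),
                        float(parts[2]),
                        float(parts[3]),
                        float(parts[4]),
                        float(parts[5]),
                        int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SWCFormatError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise SWCFormatError(f"{path}: no nodes")
    arr = np.array(rows, dtype=float)
    try:
        return MorphTree(
            ids=arr[:, 0].astype(int),
            types=arr[:, 1].astype(int),
            xyz=arr[:, 2:5],
            radius=arr[:, 5],
            parent=arr[:, 6].astype(int),
        )
    except SWCFormatError as exc:
        raise SWCFormatError(f"{path}: {exc}") from exc


def write_swc(tree: MorphTree, path) -> None:
    """Write a tree in canonical SWC form (deterministic bytes)."""
    with open(path, "w") as fh:
        fh.write("# generated by gliamotion\n")
        for i in range(tree.n_nodes):
            x, y, z = tree.xyz[i]
            fh.write(
                f"{tree.ids[i]} {tree.types[i]} {x:.6f} {y:.6f} {z:.6f} "
                f"{tree.radius[i]:.6f} {tree.parent[i]}\n"
            )


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------

def segment_sphere_crossings(p0, p1, center, r) -> int:
    """Number of times segment p0->p1 crosses the sphere |p - center| = r.

    Solves |p0 + t (p1 - p0) - center|^2 = r^2 for t in [0, 1).  The
    half-open interval means a chain of segments sharing endpoints counts
    each crossing once.  Tangential touches (double root) count zero.
    """
    p0 = np.asarray(p0, float) - center
    d = np.asarray(p1, float) - center - p0
    a = float(d @ d)
    if a == 0.0:
        return 0
    b = 2.0 * float(p0 @ d)
    c = float(p0 @ p0) - r * r
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:
        return 0
    sq = math.sqrt(disc)
    crossings = 0
    for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
        if 0.0 <= t < 1.0:
            crossings += 1
    return crossings


def sholl_intersections(tree: MorphTree, dr_um: float = 1.0,
                        max_radius_um: float | None = None) -> ShollProfile:
    """Sholl profile: process crossings of concentric shells around the soma.

    Shells are spheres of radius ``dr_um, 2 dr_um, ...`` centred on the soma
    centroid.  Each tree edge is a straight 3-D segment; a segment crossing
    k shells contributes one intersection to each.  Zero-length edges are
    skipped; edges internal to the soma are excluded.
    """
    if dr_um <= 0:
        raise ValueError("dr_um must be positive")
    center = tree.soma_centroid()
    pairs = tree.edges(exclude_intra_soma=True)
    n_proc, n_branch = count_processes(tree)
    length = total_length(tree)
    dists = np.linalg.norm(tree.xyz - center, axis=1)
    r_far = float(dists.max()) if len(dists) else 0.0
    if max_radius_um is None:
        max_radius_um = r_far + dr_um
    radii = np.arange(dr_um, max_radius_um + 0.5 * dr_um, dr_um)
    counts = np.zeros(len(radii), dtype=int)
    for ci, pi in pairs:
        p0, p1 = tree.xyz[pi], tree.xyz[ci]
        if np.array_equal(p0, p1):
            continue
        d0, d1 = dists[pi], dists[ci]
        lo = min(d0, d1)
        # the segment can dip closer to the soma than either endpoint
        seg = p1 - p0
        t_star = -float((p0 - center) @ seg) / float(seg @ seg)
        if 0.0 < t_star < 1.0:
            lo = min(lo, float(np.linalg.norm(p0 + t_star * seg - center)))
        hi = max(d0, d1)
        j0 = max(0, int(math.ceil(lo / dr_um)) - 1)
        j1 = min(len(radii), int(math.floor(hi / dr_um)) + 1)
        for j in range(j0, j1):
            counts[j] += segment_sphere_crossings(p0, p1, center, radii[j])
    return ShollProfile(
        radii_um=radii,
        intersections=counts,
        n_processes=n_proc,
        n_branch_points=n_branch,
        total_length_um=length,
        n_branches_total=n_proc + n_branch,
    )


def count_processes(tree: MorphTree) -> tuple[int, int]:
    """(number of primary processes, number of branch points).

    Primary processes are stems: edges from a soma-type node (or the root,
    if no node is soma-typed) to a non-soma node.  Branch points are
    non-soma nodes with two or more children.
    """
    pidx = tree.parent_index()
    soma_mask = tree.types == SOMA_TYPE
    if not soma_mask.any():
        soma_mask = np.zeros(tree.n_nodes, bool)
        soma_mask[tree.root_index] = True
    stems = 0
    for k, p in enumerate(pidx):
        if p >= 0 and soma_mask[p] and not soma_mask[k]:
            stems += 1
    counts = tree.children_counts()
    branch_points = int(np.sum((counts >= 2) & ~soma_mask))
    return stems, branch_points


def total_length(tree: MorphTree) -> float:
    """Total process length in micrometres (intra-soma edges excluded)."""
    pairs = tree.edges(exclude_intra_soma=True)
    if len(pairs) == 0:
        return 0.0
    seg = tree.xyz[pairs[:, 0]] - tree.xyz[pairs[:, 1]]
    return float(np.linalg.norm(seg, axis=1).sum())


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def profiles_to_long(profiles_by_group: Mapping[str, Sequence[ShollProfile]],
                     max_radius_um: float | None = None) -> pd.DataFrame:
    """Tidy long table (group, cell, radius_um, intersections), zero-padded
    so every cell covers the same radius grid."""
    if max_radius_um is None:
        max_radius_um = max(
            p.radii_um[-1] if len(p.radii_um) else 0.0
            for ps in profiles_by_group.values()
            for p in ps
        )
    rows = []
    for group, profiles in profiles_by_group.items():
        for ci, prof in enumerate(profiles):
            dr = prof.radii_um[1] - prof.radii_um[0] if len(prof.radii_um) > 1 else 1.0
            radii = np.arange(dr, max_radius_um + 0.5 * dr, dr)
            counts = np.zeros(len(radii), dtype=int)
            m = min(len(counts), len(prof.intersections))
            counts[:m] = prof.intersections[:m]
            label = prof.label or f"{group}_{ci}"
            for r, c in zip(radii, counts):
                rows.append((group, label, float(r), int(c)))
    return pd.DataFrame(rows, columns=["group", "cell", "radius_um", "intersections"])


def compare_groups(profiles_by_group: Mapping[str, Sequence[ShollProfile]],
                   max_radius_um: float | None = None):
    """Per-radius group means +- SEM and a two-way ANOVA (group x radius).

    The ANOVA treats group and shell radius as crossed categorical factors
    with one observation per cell per radius, the standard way Sholl
    profiles of two genotypes or treatments are compared.

    Returns (summary_df, anova_df).
    """
    groups = {g: list(ps) for g, ps in profiles_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, ps in groups.items():
        if len(ps) < 2:
            raise ValueError(f"group {g!r} needs at least two cells")
    long = profiles_to_long(groups, max_radius_um=max_radius_um)
    summary = (
        long.groupby(["group", "radius_um"])["intersections"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
        .reset_index()
    )
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("intersections ~ C(group) * C(radius_um)", data=long).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(
        index={
            "C(group)": "group",
            "C(radius_um)": "radius",
            "C(group):C(radius_um)": "group:radius",
            "Residual": "residual",
        }
    )
    return summary, anova
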