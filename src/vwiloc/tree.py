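"""Branch-structured vessel centerline trees with per-point radii (mm)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SEGMENT_NAMES = ("BA", "LVA", "RVA", "LMCA", "RMCA", "LICA", "RICA")


@dataclass
class Branch:
    """An ordered polyline of 3-D points (mm) with per-point radii (mm)."""

    points: np.ndarray          # (N, 3) mm
    radii: np.ndarray           # (N,) mm, > 0
    parent: int = -1            # index of parent branch, -1 for roots

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.radii = np.atleast_1d(np.asarray(self.radii, float))
        if self.points.shape[0] != self.radii.shape[0]:
            raise ValueError("points/radii length mismatch")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length (mm) at each point, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def length(self) -> float:
        return float(self.arc_lengths()[-1])


@dataclass
class VesselTree:
    branches: list[Branch] = field(default_factory=list)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def all_points(self) -> np.ndarray:
        if not self.branches:
            return np.zeros((0, 3))
        return np.concatenate([b.points for b in self.branches], axis=0)

    def all_radii(self) -> np.ndarray:
        if not self.branches:
            return np.zeros((0,))
        return np.concatenate([b.radii for b in self.branches])

    def densified_points(self, step: float) -> np.ndarray:
        """Resample every branch at arc-length steps <= ``step`` mm."""
        out = []
        for b in self.branches:
            out.append(densify_polyline(b.points, step)[0])
        if not out:
            return np.zeros((0, 3))
        return np.concatenate(out, axis=0)

    def map_points(self, fn) -> "VesselTree":
        """Apply a point mapping ``(N,3)->(N,3)`` to every branch."""
        return VesselTree(
            [Branch(fn(b.points), b.radii.copy(), b.parent) for b in self.branches]
        )

    def translate(self, t) -> "VesselTree":
        t = np.asarray(t, float)
        return self.map_points(lambda p: p + t)


def densify_polyline(points: np.ndarray, step: float, radii: np.ndarray | None = None):
    """Resample a polyline at uniform arc-length increments <= ``step``.

    Returns ``(points, radii)``; radii are linearly interpolated when given,
    otherwise ``None`` is returned in their place.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if points.shape[0] < 2:
        return points.copy(), (None if radii is None else np.asarray(radii, float).copy())
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1].copy(), (None if radii is None else np.asarray(radii, float)[:1].copy())
    n = max(2, int(np.ceil(total / step)) + 1)
    su = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(su, s, points[:, c]) for c in range(3)])
    r = None if radii is None else np.interp(su, s, np.asarray(radii, float))
    return out, r


@dataclass
class SegmentROI:
    """A named clinical segment: an arc-length window on one branch.

    ``bbox`` is the axis-aligned physical box (mm) enclosing the segment's
    centerline points plus a margin.
    """

    name: str
    branch_id: int
    span: tuple[float, float]                      # start/end arc length, mm
    bbox: tuple[np.ndarray, np.ndarray]            # (lo, hi) mm corners

    def __post_init__(self):
        if self.name not in SEGMENT_NAMES:
            raise ValueError(f"unknown segment name {self.name!r}; expected one of {SEGMENT_NAMES}")
        if self.span[1] <= self.span[0]:
            raise ValueError("segment span must have positive length")
        self.bbox = (np.asarray(self.bbox[0], float), np.asarray(self.bbox[1], float))


def segment_points(tree: VesselTree, seg: SegmentROI, step: float = 0.5) -> np.ndarray:
    """Densified centerline points of ``tree`` within the segment's span."""
    b = tree.branches[seg.branch_id]
    pts, _ = densify_polyline(b.points, step, b.radii)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    keep = (s >= seg.span[0]) & (s <= seg.span[1])
    return pts[keep]


def make_segment(tree: VesselTree, name: str, branch_id: int, span, margin: float = 3.0) -> SegmentROI:
    """Build a SegmentROI whose bbox encloses the windowed centerline + margin."""
    seg = SegmentROI(name, branch_id, (float(span[0]), float(span[1])),
                     (np.zeros(3), np.ones(3)))
    pts = segment_points(tree, seg)
    if pts.shape[0] == 0:
        raise ValueError(f"segment {name}: span {span} outside branch arc length")
    seg.bbox = (pts.min(axis=0) - margin, pts.max(axis=0) + margin)
    return seg


# --- JSON serialization -----------------------------------------------------

def tree_to_dict(tree: VesselTree) -> dict:
    return {
        "branches": [
            {
                "points": np.column_stack([b.points, b.radii]).tolist(),
                "parent": int(b.parent),
            }
            for b in tree.branches
        ]
    }


def tree_from_dict(d: dict) -> VesselTree:
    branches = []
    for bd in d["branches"]:
        arr = np.asarray(bd["points"], float).reshape(-1, 4)
        branches.append(Branch(arr[:, :3], arr[:, 3], int(bd.get("parent", -1))))
    return VesselTree(branches)


def save_tree(tree: VesselTree, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(tree)))


def load_tree(path: str | Path) -> VesselTree:
    return tree_from_dict(json.loads(Path(path).read_text()))


def save_tree_vtk(tree: VesselTree, path: str | Path) -> None:
    """Write the tree as legacy ASCII VTK polylines (viewable in ParaView)."""
    pts = tree.all_points()
    lines = []
    off = 0
    for b in tree.branches:
        lines.append([b.n_points] + list(range(off, off + b.n_points)))
        off += b.n_points
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nvessel tree\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {pts.shape[0]} float\n")
        for p in pts:
            f.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        total = sum(len(l) for l in lines)
        f.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            f.write(" ".join(str(i) for i in l) + "\n")
        f.write(f"POINT_DATA {pts.shape[0]}\nSCALARS radius float 1\nLOOKUP_TABLE default\n")
        for r in tree.all_radii():
            f.write(f"{r:.4f}\n")
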