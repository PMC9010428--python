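"""Synthetic paired VWI/MRA cohorts with known vessel trees and deformations.

Real black-blood vessel-wall imaging shows a dark lumen inside a thin bright
wall over a heterogeneous, bias-field-modulated background; time-of-flight
angiography shows a bright lumen on a suppressed background.  This module
renders both contrasts from a common randomly-grown vessel tree on one grid,
and produces cohorts of "subjects" as smooth random deformations of a hidden
template, so registration and refinement can be validated against known
ground-truth fields without any clinical data.

Default grid: 48 x 96 x 80 voxels at 2.2 mm isotropic (the working resolution
the refinement network consumes); a full-resolution 0.55 mm mode exists for
crop/rescale round-trip checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
from scipy.ndimage import gaussian_filter, zoom
from scipy.spatial import cKDTree

from .core import DisplacementField, ImageVolume, VolumeGeometry
from .tree import Branch, SegmentROI, VesselTree, make_segment, densify_polyline
from .warp import invert_points, resample_image, warp_tree

DEFAULT_GEOMETRY = VolumeGeometry((48, 96, 80), (2.2, 2.2, 2.2))
FULLRES_SPACING = 0.55

#: (name, rank of branch by length, relative arc-length window)
DEFAULT_SEGMENT_PLAN = (
    ("BA", 0, (0.15, 0.40)),
    ("RVA", 0, (0.55, 0.80)),
    ("LMCA", 1, (0.30, 0.60)),
    ("RICA", 2, (0.30, 0.60)),
)


class PhantomParameterError(ValueError):
    pass


@dataclass
class PhantomCase:
    """One synthetic subject: paired volumes, its tree, and (if derived from a
    template) the pull-back field that generated it."""

    vwi: ImageVolume
    mra: ImageVolume
    tree: VesselTree
    true_dvf_from_template: DisplacementField | None = None
    segments: list[SegmentROI] = field(default_factory=list)
    case_id: str = "template"

    def __post_init__(self):
        if self.vwi.geometry != self.mra.geometry:
            raise PhantomParameterError("vwi and mra must share one geometry")

    @property
    def geometry(self) -> VolumeGeometry:
        return self.vwi.geometry


# ---------------------------------------------------------------------------
# Vessel tree growth

def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _rotate_towards(d, target, frac):
    return _unit((1 - frac) * d + frac * _unit(target))


def _grow_branch(rng, start, direction, length, r0, r1, lo, hi, max_turn=0.12):
    """Curvature-bounded random walk from ``start``; steered back inside the box."""
    step = 1.5
    n = max(3, int(length / step))
    pts = [np.asarray(start, float)]
    d = _unit(np.asarray(direction, float))
    center = (lo + hi) / 2
    for i in range(n):
        # random small turn
        turn = rng.normal(0, max_turn, 3)
        d = _unit(d + turn)
        p = pts[-1] + d * step
        # steer toward the box centre when close to a face
        margin = np.minimum(p - lo, hi - p)
        if margin.min() < 6.0:
            d = _rotate_towards(d, center - p, 0.4)
            p = pts[-1] + d * step
        p = np.clip(p, lo, hi)
        pts.append(p)
    pts = np.asarray(pts)
    radii = np.clip(np.linspace(r0, r1, pts.shape[0]), 0.8, 2.5)
    return pts, radii


def make_vessel_tree(seed: int, n_branches: int, field_extent) -> VesselTree:
    """Grow a random smooth vessel tree inside a physical box of ``field_extent`` mm.

    The first branch is a root (parent -1); later branches bifurcate from a
    point on an existing branch with reduced radius.  Radii lie in
    [0.8, 2.5] mm and taper toward the tips.
    """
    if n_branches < 1:
        raise PhantomParameterError("n_branches must be >= 1")
    extent = np.asarray(field_extent, float)
    if np.any(extent < 12.0):
        raise PhantomParameterError(
            f"field extent {extent} too small to contain a branch (need >= 12 mm per axis)"
        )
    rng = np.random.default_rng(seed)
    lo = np.full(3, 3.0)
    hi = extent - 3.0
    diag = float(np.linalg.norm(hi - lo))

    branches: list[Branch] = []
    # root: start near the centre of the lowest face of the longest axis
    ax = int(np.argmax(extent))
    start = (lo + hi) / 2
    start[ax] = lo[ax]
    d0 = np.zeros(3)
    d0[ax] = 1.0
    pts, radii = _grow_branch(rng, start, d0, 0.7 * diag, 2.4, 1.5, lo, hi)
    branches.append(Branch(pts, radii, -1))

    for b in range(1, n_branches):
        parent = int(rng.integers(0, len(branches)))
        pb = branches[parent]
        j = int(rng.integers(pb.n_points // 4, max(pb.n_points // 4 + 1, 3 * pb.n_points // 4)))
        attach = pb.points[j]
        pdir = _unit(pb.points[min(j + 1, pb.n_points - 1)] - pb.points[max(j - 1, 0)])
        # branch off at ~40-60 degrees
        perp = _unit(np.cross(pdir, rng.normal(size=3)))
        ang = rng.uniform(0.7, 1.0)
        d0 = _unit(np.cos(ang) * pdir + np.sin(ang) * perp)
        r_attach = float(pb.radii[j])
        length = rng.uniform(0.25, 0.45) * diag
        pts, radii = _grow_branch(rng, attach, d0, length,
                                  max(1.3, 0.8 * r_attach), 1.15, lo, hi)
        branches.append(Branch(pts, radii, parent))
    return VesselTree(branches)


# ---------------------------------------------------------------------------
# Rendering

VWI_BACKGROUND = 60.0
VWI_LUMEN_FACTOR = 0.15
VWI_WALL_FACTOR = 1.5
WALL_OUTER_FACTOR = 1.3     # wall ring spans radius * [1.0, 1.3]
MRA_LUMEN = 100.0
DEFAULT_NOISE_SD = 4.0


def _subgrid(geom: VolumeGeometry, factor: int) -> VolumeGeometry:
    sp = tuple(s / factor for s in geom.spacing)
    org = tuple(o - s / 2 + sub / 2 for o, s, sub in zip(geom.origin, geom.spacing, sp))
    return VolumeGeometry(tuple(n * factor for n in geom.dims), sp, org)


def _block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    n1, n2, n3 = (s // factor for s in arr.shape)
    return arr.reshape(n1, factor, n2, factor, n3, factor).mean(axis=(1, 3, 5))


def _tube_weights(tree: VesselTree, geom: VolumeGeometry, supersample: int = 2):
    """Partial-volume lumen and wall-ring occupancy per voxel.

    Rasterized on a ``supersample``-times finer subgrid (sharp indicator with
    a one-subvoxel antialiasing ramp) and block-averaged, so millimetre-scale
    tubes survive coarse grids as fractional-intensity tracks.  A voxel all of
    whose subsamples lie outside the tube gets exactly zero lumen weight.
    """
    sub = _subgrid(geom, supersample)
    step = 0.5 * min(sub.spacing)
    pts, rads = [], []
    for b in tree.branches:
        p, r = densify_polyline(b.points, step, b.radii)
        pts.append(p)
        rads.append(r)
    pts = np.concatenate(pts, axis=0)
    rads = np.concatenate(rads)
    kd = cKDTree(pts)
    centers = sub.voxel_centers().reshape(-1, 3)
    dist, idx = kd.query(centers, workers=-1)
    dist = dist.reshape(sub.dims)
    rad = rads[idx].reshape(sub.dims)
    edge = min(sub.spacing)
    w_lumen = np.clip((rad - dist) / edge, 0.0, 1.0)
    w_wall = np.clip((WALL_OUTER_FACTOR * rad - dist) / edge, 0.0, 1.0) - w_lumen
    if supersample > 1:
        w_lumen = _block_mean(w_lumen, supersample)
        w_wall = _block_mean(w_wall, supersample)
    return w_lumen, w_wall


def sample_bias_field(seed: int, geom: VolumeGeometry, max_log: float = 0.2) -> np.ndarray:
    """Multiplicative MR-style bias: exp of a random second-order polynomial,
    scaled so the modulation stays within ``exp(+-max_log)`` (~ +-20%)."""
    rng = np.random.default_rng(seed)
    axes = [np.linspace(-1, 1, n) for n in geom.dims]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    terms = [X, Y, Z, X * Y, X * Z, Y * Z, X**2, Y**2, Z**2]
    coeff = rng.normal(size=len(terms))
    poly = sum(c * t for c, t in zip(coeff, terms))
    m = np.abs(poly).max()
    if m > 0:
        poly = poly * (max_log / m)
    return np.exp(poly)


def _background_texture(seed: int, geom: VolumeGeometry,
                        scales_mm: tuple = (10.0, 4.0),
                        rel_amps: tuple = (0.16, 0.08)) -> np.ndarray:
    """Smooth multiplicative anatomy surrogate.

    Two spatial scales: coarse lobe-level intensity variation plus a finer
    parenchymal texture, mirroring the multi-scale structure real brain
    tissue presents to a registration metric.
    """
    rng = np.random.default_rng(seed)
    tex = np.zeros(geom.dims)
    for sigma_mm, rel_amp in zip(scales_mm, rel_amps):
        noise = rng.normal(size=geom.dims)
        sig = [sigma_mm / s for s in geom.spacing]
        comp = gaussian_filter(noise, sig)
        sd = comp.std()
        if sd > 0:
            tex += comp / sd * rel_amp
    return 1.0 + tex


def render_pair(tree: VesselTree, geom: VolumeGeometry, noise_sd: float = DEFAULT_NOISE_SD,
                seed: int = 0, bias: bool = True) -> tuple[ImageVolume, ImageVolume]:
    """Rasterize a vessel tree into a (VWI, MRA) pair on ``geom``.

    MRA: bright lumen (distance-to-centerline <= local radius) on a zero
    background.  VWI: heterogeneous mid-gray background with a dark lumen and
    a thin brighter wall ring, modulated by a smooth bias field.  Gaussian
    noise of ``noise_sd`` is added to both; with ``noise_sd=0`` the MRA
    background is exactly zero outside the tubes.
    """
    lo, hi = geom.physical_box()
    pts = tree.all_points()
    if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
        raise PhantomParameterError("tree does not fit inside the volume geometry")
    rng = np.random.default_rng(seed)
    w_lumen, w_wall = _tube_weights(tree, geom)

    mra_vals = MRA_LUMEN * w_lumen
    if noise_sd > 0:
        mra_vals = mra_vals + rng.normal(0, noise_sd, geom.dims)

    base = VWI_BACKGROUND * _background_texture(seed + 1, geom)
    bias_field = sample_bias_field(seed + 2, geom) if bias else 1.0
    vwi_vals = (
        base * (1 - w_wall - w_lumen)
        + VWI_BACKGROUND * VWI_WALL_FACTOR * w_wall
        + VWI_BACKGROUND * VWI_LUMEN_FACTOR * w_lumen
    ) * bias_field
    if noise_sd > 0:
        vwi_vals = vwi_vals + rng.normal(0, noise_sd, geom.dims)

    return ImageVolume(geom, vwi_vals), ImageVolume(geom, mra_vals)


def centerline_contrast_fraction(case: PhantomCase, mode: str, smooth_vox: float = 0.8,
                                 ring_vox: float = 1.8, n_dirs: int = 8) -> float:
    """Fraction of centerline points that are cross-sectional intensity extrema.

    For each densified centerline point, the smoothed image is compared at the
    point against the mean over a ring of offsets in the plane orthogonal to
    the local tangent (``ring_vox`` voxels away): MRA points should be local
    maxima, VWI points local minima.
    """
    img = case.mra if mode == "mra" else case.vwi
    geom = img.geometry
    sm = ImageVolume(geom, gaussian_filter(img.values, smooth_vox))
    sign = 1.0 if mode == "mra" else -1.0
    off = ring_vox * min(geom.spacing)
    ok = total = 0
    for b in case.tree.branches:
        pts, _ = densify_polyline(b.points, 2.0, b.radii)
        if pts.shape[0] < 3:
            continue
        tangents = np.gradient(pts, axis=0)
        for p, t in zip(pts[1:-1], tangents[1:-1]):
            if not geom.contains_point(p, margin_vox=ring_vox + 1):
                continue
            t = _unit(t)
            u = _unit(np.cross(t, [0.17, 0.46, 0.87]))
            v = np.cross(t, u)
            angles = np.linspace(0, 2 * np.pi, n_dirs, endpoint=False)
            ring = p + off * (np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v))
            ok += sign * (sm.sample(p[None])[0] - sm.sample(ring).mean()) > 0
            total += 1
    return ok / max(total, 1)


# ---------------------------------------------------------------------------
# Deformations and cohorts

def sample_smooth_dvf(seed: int, geom: VolumeGeometry, amplitude: float = 3.0,
                      knot_spacing: float = 24.0) -> DisplacementField:
    """A smooth random displacement field with max magnitude == ``amplitude`` mm.

    Random coefficients on a coarse knot grid are cubic-interpolated to the
    target grid and rescaled so the largest vector magnitude equals
    ``amplitude``.  For ``amplitude`` well below half the knot spacing the
    field is invertible (no non-positive Jacobian determinants).
    """
    if amplitude < 0:
        raise PhantomParameterError("amplitude must be >= 0")
    if amplitude == 0:
        return DisplacementField.zero(geom)
    rng = np.random.default_rng(seed)
    extent = geom.extent
    knots = [max(2, int(np.ceil(extent[a] / knot_spacing)) + 1) for a in range(3)]
    coeff = rng.normal(size=(*knots, 3))
    vec = np.empty(geom.dims + (3,))
    for c in range(3):
        factors = [geom.dims[a] / knots[a] for a in range(3)]
        vec[..., c] = zoom(coeff[..., c], factors, order=3, mode="nearest",
                           grid_mode=True)
    mag = np.linalg.norm(vec, axis=-1).max()
    vec *= amplitude / mag
    return DisplacementField(geom, vec)


def make_subject(template: PhantomCase, dvf: DisplacementField,
                 case_id: str = "subject") -> PhantomCase:
    """Warp a template case through a pull-back field.

    Volumes are resampled at ``p + d(p)``; tree points are mapped by the
    field's numerical inverse so tree and images stay consistent.  Raises if
    the field is not invertible on the grid.
    """
    if dvf.geometry != template.geometry:
        raise PhantomParameterError("dvf must live on the template geometry")
    if not np.allclose(dvf.vectors, 0) and dvf.negative_jacobian_count() > 0:
        raise PhantomParameterError("deformation is not invertible (negative Jacobians)")
    vwi = resample_image(template.vwi, dvf, pad="nearest")
    mra = resample_image(template.mra, dvf, pad="nearest")
    tree = warp_tree(template.tree, dvf)
    case = PhantomCase(vwi, mra, tree, dvf, [], case_id)
    case.segments = _segments_for_tree(tree)
    return case


def _segments_for_tree(tree: VesselTree, plan=DEFAULT_SEGMENT_PLAN, margin: float = 3.0):
    order = np.argsort([-b.length() for b in tree.branches])
    segs = []
    for name, rank, (f0, f1) in plan:
        bid = int(order[rank % len(order)])
        L = tree.branches[bid].length()
        segs.append(make_segment(tree, name, bid, (f0 * L, f1 * L), margin))
    return segs


@dataclass
class CohortParams:
    geometry: VolumeGeometry = DEFAULT_GEOMETRY
    n_branches: int = 4
    amplitude: float = 3.0
    knot_spacing: float = 24.0
    noise_sd: float = DEFAULT_NOISE_SD
    tree_margin: float = 8.0


def make_template(seed: int, params: CohortParams = CohortParams()) -> PhantomCase:
    """The hidden cohort template: clean render (no bias, no noise)."""
    geom = params.geometry
    extent = np.asarray(geom.origin) + geom.extent - params.tree_margin
    tree = make_vessel_tree(seed, params.n_branches, extent)
    vwi, mra = render_pair(tree, geom, noise_sd=0.0, seed=seed, bias=False)
    case = PhantomCase(vwi, mra, tree, None, [], "template")
    case.segments = _segments_for_tree(tree)
    return case


def make_cohort(n_subjects: int, seed: int, params: CohortParams = CohortParams()
                ) -> list[PhantomCase]:
    """Generate ``n_subjects`` cases from one hidden template.

    Each subject is the template warped by an independent smooth field, with
    independently re-seeded bias field and additive noise, so subjects share
    anatomy (warped background texture and vessels) but differ in deformation
    and appearance.  The stored ``true_dvf_from_template`` is the pull-back
    field used for the warp.
    """
    if n_subjects < 2:
        raise PhantomParameterError("a cohort needs at least 2 subjects")
    template = make_template(seed, params)
    geom = params.geometry
    rng = np.random.default_rng(seed + 1)
    subjects = []
    for i in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        dvf = sample_smooth_dvf(sub_seed, geom, params.amplitude, params.knot_spacing)
        case = make_subject(template, dvf, case_id=f"subj{i:03d}")
        nrng = np.random.default_rng(sub_seed + 1)
        bias = sample_bias_field(sub_seed + 2, geom)
        vwi = case.vwi.values * bias
        mra = case.mra.values.copy()
        if params.noise_sd > 0:
            vwi = vwi + nrng.normal(0, params.noise_sd, geom.dims)
            mra = mra + nrng.normal(0, params.noise_sd, geom.dims)
        case.vwi = ImageVolume(geom, vwi)
        case.mra = ImageVolume(geom, mra)
        subjects.append(case)
    return subjects


def save_cohort(cases: list[PhantomCase], out_dir: str | Path) -> None:
    """Write volumes as NIfTI, trees as JSON, and a cohort manifest."""
    from .core import save_dvf, save_image
    from .tree import save_tree

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for case in cases:
        cid = case.case_id
        save_image(case.vwi, out / f"{cid}_vwi.nii.gz")
        save_image(case.mra, out / f"{cid}_mra.nii.gz")
        save_tree(case.tree, out / f"{cid}_tree.json")
        entry = {"id": cid, "vwi": f"{cid}_vwi.nii.gz", "mra": f"{cid}_mra.nii.gz",
                 "tree": f"{cid}_tree.json",
                 "segments": [
                     {"name": s.name, "branch_id": s.branch_id, "span": list(s.span),
                      "bbox": [s.bbox[0].tolist(), s.bbox[1].tolist()]}
                     for s in case.segments
                 ]}
        if case.true_dvf_from_template is not None:
            save_dvf(case.true_dvf_from_template, out / f"{cid}_truedvf.nii.gz")
            entry["true_dvf"] = f"{cid}_truedvf.nii.gz"
        manifest.append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
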