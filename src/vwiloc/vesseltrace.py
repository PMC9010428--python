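"""Hessian-based tubular filtering and seed-grown centerline extraction.

Bright tubes in an angiographic volume are detected with the scale-space
Hessian: at Gaussian scale sigma (mm) the two cross-sectional eigenvalues of
the scale-normalized Hessian are large and negative while the along-tube
eigenvalue is small.  With eigenvalues sorted by magnitude
``|l1| <= |l2| <= |l3|``:

* ``tubeness = sqrt(|l2 * l3|)`` when ``l2 < 0`` and ``l3 < 0``, else 0;
* ``roundness = |l2| / |l3|`` in [0, 1] (1 for circular tubes, small for
  plates); candidates below a minimum roundness of 0.2 are rejected.

Centerlines are traced by stepping along the minor-eigenvector direction with
re-centering to the cross-sectional tubeness maximum, starting from seed
points; the tube radius scale is found recursively from a 1.5 mm candidate
downwards until a tubular cross-section is detected.  Whole trees grow over a
few scans by re-seeding from endpoints and lateral offsets of traced tubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom
from scipy.spatial import cKDTree

from .core import GeometryError, ImageVolume, VolumeGeometry
from .tree import Branch, VesselTree

MIN_ROUNDNESS = 0.2
RADIUS_START_MM = 1.5
RADIUS_FLOOR_MM = 0.3
RADIUS_SHRINK = 0.75


@dataclass
class TubeCandidate:
    point: np.ndarray            # mm
    radius_scale: float          # mm
    roundness: float             # in [0, 1]
    tubeness: float              # >= 0 (0 when the bright-tube sign test fails)
    direction: np.ndarray = field(default_factory=lambda: np.zeros(3))  # minor eigenvector


@dataclass
class TraceParams:
    roundness_min: float = MIN_ROUNDNESS
    radius_start: float = RADIUS_START_MM
    radius_floor: float = RADIUS_FLOOR_MM
    radius_shrink: float = RADIUS_SHRINK
    #: tubeness acceptance threshold as a fraction of the volume's robust
    #: intensity range (the filter is scale-normalized, so responses share
    #: the intensity scale)
    tubeness_rel_threshold: float = 0.10
    step_frac: float = 0.5               # step = step_frac * min spacing
    max_steps: int = 4000
    recenter_iters: int = 2
    #: lateral seed-perturbation radius, voxels
    perturb_vox: float = 2.0
    #: resample to this spacing before filtering when coarser (mm)
    upsample_spacing: float = 1.0
    #: smallest usable filter scale in voxels (sub-voxel Gaussian derivatives
    #: are numerically meaningless)
    min_scale_vox: float = 0.7


DEFAULT_TRACE_PARAMS = TraceParams()


class _HessianCache:
    """Per-scale Gaussian-Hessian component volumes with trilinear lookup."""

    _PAIRS = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))

    def __init__(self, vol: ImageVolume):
        self.vol = vol
        self.geom = vol.geometry
        self._comps: dict[float, np.ndarray] = {}

    def components(self, scale_mm: float) -> np.ndarray:
        key = round(float(scale_mm), 6)
        if key not in self._comps:
            sig = [scale_mm / s for s in self.geom.spacing]
            comps = np.empty((6,) + self.geom.dims)
            for c, (a, b) in enumerate(self._PAIRS):
                order = [0, 0, 0]
                order[a] += 1
                order[b] += 1
                comps[c] = gaussian_filter(self.vol.values, sig, order=tuple(order))
            comps *= scale_mm**2                     # gamma=2 scale normalization
            self._comps[key] = comps
        return self._comps[key]

    def hessians_at(self, points: np.ndarray, scale_mm: float) -> np.ndarray:
        """Symmetric 3x3 Hessians at world points (N, 3)."""
        comps = self.components(scale_mm)
        idx = self.geom.world_to_index(np.atleast_2d(points)).T
        vals = np.stack(
            [map_coordinates(comps[c], idx, order=1, mode="nearest") for c in range(6)]
        )
        H = np.empty((vals.shape[1], 3, 3))
        H[:, 0, 0], H[:, 0, 1], H[:, 0, 2] = vals[0], vals[1], vals[2]
        H[:, 1, 1], H[:, 1, 2], H[:, 2, 2] = vals[3], vals[4], vals[5]
        H[:, 1, 0], H[:, 2, 0], H[:, 2, 1] = vals[1], vals[2], vals[4]
        return H


def _eigen_features(H: np.ndarray):
    """(tubeness, roundness, minor eigenvector) per Hessian, bright-tube sign test."""
    w, v = np.linalg.eigh(H)                      # ascending eigenvalues
    order = np.argsort(np.abs(w), axis=1)
    n = w.shape[0]
    ar = np.arange(n)[:, None]
    w_sorted = w[ar, order]                       # |l1| <= |l2| <= |l3|
    l2, l3 = w_sorted[:, 1], w_sorted[:, 2]
    bright = (l2 < 0) & (l3 < 0)
    tube = np.where(bright, np.sqrt(np.abs(l2 * l3)), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        roundness = np.where(np.abs(l3) > 0, np.abs(l2) / np.abs(l3), 0.0)
    minor = v[ar.squeeze(), :, order[:, 0]]       # eigenvector of smallest |l|
    return tube, roundness, minor


def robust_range(vol: ImageVolume) -> float:
    """Intensity range between the bright foreground and the typical voxel.

    Vessels occupy well under 1% of an angiographic volume, so percentile
    spans miss them entirely; instead the maximum of a lightly smoothed copy
    (robust to isolated hot voxels) minus the median is used.
    """
    sm = gaussian_filter(vol.values, 1.0)
    return float(sm.max() - np.median(sm))


def tube_measure(vol_or_cache, point, radius_scale: float) -> TubeCandidate:
    """Evaluate the tubular filter at one world point and scale (mm)."""
    cache = vol_or_cache if isinstance(vol_or_cache, _HessianCache) else _HessianCache(vol_or_cache)
    if radius_scale <= 0:
        raise ValueError("radius_scale must be positive")
    point = np.asarray(point, float)
    if not cache.geom.contains_point(point):
        raise GeometryError(f"point {point} lies outside the volume grid")
    H = cache.hessians_at(point[None], radius_scale)
    tube, roundness, minor = _eigen_features(H)
    return TubeCandidate(point, float(radius_scale), float(roundness[0]),
                         float(tube[0]), minor[0])


def _scale_schedule(params: TraceParams, min_spacing: float = 0.0) -> list[float]:
    floor = max(params.radius_floor, params.min_scale_vox * min_spacing)
    scales, s = [], params.radius_start
    while s >= floor:
        scales.append(s)
        s *= params.radius_shrink
    return scales


def _best_scale(cache: _HessianCache, point, params: TraceParams, threshold: float):
    """Recursive radius estimation: shrink from ``radius_start`` until a
    tubular cross-section (roundness and tubeness tests) is found."""
    for s in _scale_schedule(params, min(cache.geom.spacing)):
        cand = tube_measure(cache, point, s)
        if cand.roundness >= params.roundness_min and cand.tubeness >= threshold:
            return cand
    return None


def _recenter(cache, point, direction, scale, params, threshold):
    """Move to the cross-sectional tubeness maximum near ``point``."""
    u = np.cross(direction, [0.17, 0.46, 0.87])
    nu = np.linalg.norm(u)
    if nu == 0:
        u = np.cross(direction, [1.0, 0.0, 0.0])
        nu = np.linalg.norm(u)
    u /= nu
    v = np.cross(direction, u)
    best_pt, best_tube = np.asarray(point, float), -np.inf
    for _ in range(params.recenter_iters):
        r = 0.6 * scale
        offs = [np.zeros(3)]
        for rad in (0.5 * r, r):
            for ang in np.linspace(0, 2 * np.pi, 8, endpoint=False):
                offs.append(rad * (np.cos(ang) * u + np.sin(ang) * v))
        pts = best_pt + np.asarray(offs)
        inside = np.array([cache.geom.contains_point(p, 1.0) for p in pts])
        if not inside.any():
            break
        pts = pts[inside]
        tube, roundness, _ = _eigen_features(cache.hessians_at(pts, scale))
        k = int(np.argmax(tube))
        if tube[k] > best_tube:
            best_tube, best_pt = tube[k], pts[k]
    return best_pt, best_tube


@dataclass
class Trace:
    points: np.ndarray            # (N, 3) mm, empty for no trace
    radii: np.ndarray
    endpoints: tuple = ()

    @property
    def empty(self) -> bool:
        return self.points.shape[0] == 0


def _march(cache, start, direction, scale, params, threshold):
    pts, rads = [], []
    p = np.asarray(start, float)
    d = np.asarray(direction, float)
    step = params.step_frac * min(cache.geom.spacing)
    s = scale
    for k in range(params.max_steps):
        q = p + step * d
        if not cache.geom.contains_point(q, 1.0):
            break
        q, _ = _recenter(cache, q, d, s, params, threshold)
        cand = tube_measure(cache, q, s)
        refresh = (k % 15 == 14) or cand.tubeness < threshold \
            or cand.roundness < params.roundness_min
        if refresh:
            # radius may be tapering or growing: re-run the recursive
            # scale estimate at this point
            best = _best_scale(cache, q, params, threshold)
            if best is None:
                if cand.tubeness < threshold or cand.roundness < params.roundness_min:
                    break
            else:
                s, cand = best.radius_scale, best
        nd = cand.direction
        if np.dot(nd, d) < 0:
            nd = -nd
        # direction continuity guard: reject near-orthogonal flips
        if np.dot(nd, d) < 0.3:
            break
        d = nd
        p = q
        pts.append(p.copy())
        rads.append(s)
    return pts, rads


def traverse_ridge(vol_or_cache, seed, radius_start: float | None = None,
                   params: TraceParams = DEFAULT_TRACE_PARAMS,
                   threshold: float | None = None) -> Trace:
    """Trace one centerline through ``seed``, both directions.

    Returns an empty :class:`Trace` when no radius scale passes the roundness
    and tubeness tests at the seed.
    """
    cache = vol_or_cache if isinstance(vol_or_cache, _HessianCache) else _HessianCache(vol_or_cache)
    if radius_start is not None:
        params = replace(params, radius_start=radius_start)
    if threshold is None:
        threshold = params.tubeness_rel_threshold * robust_range(cache.vol)
    seed = np.asarray(seed, float)
    if not cache.geom.contains_point(seed):
        raise GeometryError(f"seed {seed} lies outside the volume grid")
    best = _best_scale(cache, seed, params, threshold)
    if best is None:
        return Trace(np.zeros((0, 3)), np.zeros(0))
    p0, _ = _recenter(cache, seed, best.direction, best.radius_scale, params, threshold)
    cand0 = tube_measure(cache, p0, best.radius_scale)
    d0 = cand0.direction if np.linalg.norm(cand0.direction) > 0 else best.direction
    fwd_p, fwd_r = _march(cache, p0, d0, best.radius_scale, params, threshold)
    bwd_p, bwd_r = _march(cache, p0, -d0, best.radius_scale, params, threshold)
    pts = bwd_p[::-1] + [p0] + fwd_p
    rads = bwd_r[::-1] + [best.radius_scale] + fwd_r
    pts = np.asarray(pts).reshape(-1, 3)
    rads = np.asarray(rads, float)
    endpoints = (pts[0].copy(), pts[-1].copy()) if pts.shape[0] > 1 else ()
    return Trace(pts, rads, endpoints)


def upsample_for_tracing(vol: ImageVolume, target_spacing: float) -> ImageVolume:
    """Linear resample to ``target_spacing`` when the grid is coarser."""
    sp = np.asarray(vol.geometry.spacing)
    if np.all(sp <= target_spacing):
        return vol
    factors = sp / target_spacing
    vals = zoom(vol.values, factors, order=1, mode="nearest", grid_mode=True)
    new_sp = sp / factors
    org = np.asarray(vol.geometry.origin) - sp / 2 + new_sp / 2
    return ImageVolume(VolumeGeometry(vals.shape, tuple(new_sp), tuple(org)), vals)


def default_seed_grid(vol: ImageVolume, percentile: float = 99.0,
                      stride_vox: int = 4) -> np.ndarray:
    """Automatic seeding: strided voxels above an intensity percentile."""
    thr = np.percentile(vol.values, percentile)
    idx = np.argwhere(vol.values >= thr)
    idx = idx[np.all(idx % stride_vox == 0, axis=1)]
    return vol.geometry.index_to_world(idx) if idx.size else np.zeros((0, 3))


def grow_vessel_tree(vol: ImageVolume, seeds, n_scans: int = 3,
                     params: TraceParams = DEFAULT_TRACE_PARAMS,
                     auto_upsample: bool = True) -> VesselTree:
    """Grow a vessel tree from seed points over ``n_scans`` scanning rounds.

    After each traced tube, its endpoints plus lateral offsets of points along
    the tube (to catch bifurcations) become candidate seeds for the next scan.
    Voxels already claimed by a traced tube are skipped, so branches are not
    duplicated.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    work = upsample_for_tracing(vol, params.upsample_spacing) if auto_upsample else vol
    cache = _HessianCache(work)
    threshold = params.tubeness_rel_threshold * robust_range(work)
    # cheap brightness pre-screen: tube seeds must sit on bright voxels
    sm = gaussian_filter(work.values, 1.0)
    sm_vol = ImageVolume(work.geometry, sm)
    seed_floor = float(np.median(sm) + 0.25 * (sm.max() - np.median(sm)))
    min_sp = min(work.geometry.spacing)
    claim_dist = 1.5 * min_sp          # dedup: a trace must be mostly this far from claimed tubes
    seed_claim = 1.0 * min_sp          # seeds this close to a claimed tube are skipped
    perturb = params.perturb_vox * min_sp

    branches: list[Branch] = []
    claimed_pts: list[np.ndarray] = []
    claimed_rad: list[np.ndarray] = []
    kd = None
    all_rad = np.zeros(0)
    queue = [np.asarray(s, float) for s in np.atleast_2d(seeds)] if len(np.atleast_2d(seeds)) else []

    def claimed(p):
        if kd is None:
            return False
        d, j = kd.query(p)
        # inside (or hugging) an already-traced tube of local radius r
        return d < max(seed_claim, 0.9 * all_rad[j])

    for _ in range(n_scans):
        next_queue = []
        for seed in queue:
            if not work.geometry.contains_point(seed, 1.0) or claimed(seed):
                continue
            if sm_vol.sample(seed[None])[0] < seed_floor:
                continue
            trace = traverse_ridge(cache, seed, params=params, threshold=threshold)
            if trace.empty or trace.points.shape[0] < 4:
                continue
            # trim away the portions duplicating already-claimed tubes and
            # keep contiguous unclaimed runs as candidate branches
            if kd is None:
                runs = [np.arange(trace.points.shape[0])]
                d = None
            else:
                d, _ = kd.query(trace.points)
                fresh = d >= claim_dist
                runs, cur = [], []
                for i, fl in enumerate(fresh):
                    if fl:
                        cur.append(i)
                    elif cur:
                        runs.append(np.asarray(cur))
                        cur = []
                if cur:
                    runs.append(np.asarray(cur))
            for run in runs:
                if run.size < 4:
                    continue
                pts_r = trace.points[run]
                rad_r = np.maximum(trace.radii[run], 0.31)
                parent = -1
                if kd is not None:
                    # junction: branch owning the claimed point next to the run
                    dq, jq = kd.query(pts_r)
                    edge = int(np.argmin(dq))
                    if dq[edge] < 2.0 * claim_dist:
                        flat = np.cumsum([b.n_points for b in branches])
                        parent = int(np.searchsorted(flat, jq[edge], side="right"))
                branches.append(Branch(pts_r, rad_r, parent))
                claimed_pts.append(pts_r)
                claimed_rad.append(rad_r)
                kd = cKDTree(np.concatenate(claimed_pts, axis=0))
                all_rad = np.concatenate(claimed_rad)
                # re-seed: endpoints and lateral offsets along the tube
                ends = [pts_r[0], pts_r[-1]]
                cand = list(ends)
                sub = pts_r[:: max(1, pts_r.shape[0] // 16)]
                axes = [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
                diag = [[a, b, c] for a in (-1, 1) for b in (-1, 1) for c in (-1, 1)]
                dirs = np.array(axes + diag, float)
                dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
                for p in list(sub) + ends:
                    for dvec in dirs:
                        cand.append(p + perturb * dvec)
                next_queue.extend(cand)
        queue = next_queue
        if not queue:
            break
    return VesselTree(branches)
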