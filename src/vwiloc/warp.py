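"""Resampling images and mapping points through dense displacement fields.

A :class:`~vwiloc.core.DisplacementField` ``d`` is stored in the pull-back
convention: the warped image reads the moving image at ``p + d(p)``.  A point
``y`` living in the *moving* frame therefore appears in the target frame at
the ``p`` solving ``p + d(p) = y``, which is found by fixed-point iteration.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .core import DisplacementField, ImageVolume, VolumeGeometry
from .tree import VesselTree


class FieldInversionError(RuntimeError):
    """Raised when the fixed-point field inversion fails to converge."""

    def __init__(self, bad_idx):
        self.bad_idx = np.asarray(bad_idx)
        super().__init__(
            f"displacement-field inversion did not converge at {self.bad_idx.size} points"
        )


def resample_image(moving: ImageVolume, dvf: DisplacementField, order: int = 1,
                   pad: str = "constant") -> ImageVolume:
    """Pull the moving image onto the field's target grid.

    ``pad="constant"`` fills zero outside the moving grid; ``pad="nearest"``
    clamps to the boundary (used by the phantom generator so warped subjects
    carry no artificial zero rims).
    """
    geom = dvf.geometry
    pts = geom.voxel_centers() + dvf.vectors            # p + d(p)
    idx = (pts - np.asarray(moving.geometry.origin)) / np.asarray(moving.geometry.spacing)
    vals = map_coordinates(
        moving.values, [idx[..., 0], idx[..., 1], idx[..., 2]],
        order=order, mode=pad, cval=0.0,
    )
    return ImageVolume(geom, vals)


def invert_points(dvf: DisplacementField, points: np.ndarray,
                  tol_vox: float = 0.05, max_iter: int = 80,
                  max_bad_frac: float = 0.01, damping: float = 0.5) -> np.ndarray:
    """Map moving-frame points into the target frame by inverting the field.

    Solves ``p + d(p) = y`` per point with the damped residual iteration
    ``p <- p - damping * (p + d(p) - y)``, which stays contractive for
    fields with Jacobian eigenvalues up to ``2 / damping``.  Points keep the
    iterate with the smallest residual; if more than ``max_bad_frac`` of
    them end farther than one voxel from their target,
    :class:`FieldInversionError` is raised.
    """
    y = np.atleast_2d(np.asarray(points, float))
    # iterate well past the contract tolerance; linear convergence makes the
    # extra digits nearly free
    tol = min(tol_vox * min(dvf.geometry.spacing), 1e-7)
    vox = min(dvf.geometry.spacing)
    p = y.copy()
    best_p = y.copy()
    best_res = np.full(y.shape[0], np.inf)
    active = np.ones(y.shape[0], dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        r = p[active] + dvf.sample(p[active]) - y[active]
        rn = np.linalg.norm(r, axis=1)
        idx = np.where(active)[0]
        better = rn < best_res[idx]
        best_res[idx[better]] = rn[better]
        best_p[idx[better]] = p[idx[better]]
        done = rn < tol
        active[idx[done]] = False
        p[idx[~done]] -= damping * r[~done]
    bad = best_res > vox
    if bad.sum() > max_bad_frac * y.shape[0]:
        raise FieldInversionError(np.where(bad)[0])
    return best_p


def warp_tree(tree: VesselTree, dvf: DisplacementField) -> VesselTree:
    """Warp a moving-frame vessel tree into the field's target frame."""
    return tree.map_points(lambda pts: invert_points(dvf, pts))


def warp_points_forward(dvf: DisplacementField, points: np.ndarray) -> np.ndarray:
    """Map target-frame points into the moving frame: ``y = p + d(p)``."""
    p = np.atleast_2d(np.asarray(points, float))
    return p + dvf.sample(p)
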