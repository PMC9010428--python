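"""Stage one: rigid/affine alignment, mutual-information atlas ranking,
low-complexity B-spline deformable registration, and composition into a dense
displacement field on the target grid.

Registration is mutual-information driven over a multi-resolution pyramid
(SimpleITK).  The deformable model is a cubic B-spline with control points
every 12 voxels by default, optimized coarse-to-fine over three levels, with
an optional cap on coefficient magnitudes as complexity control.  The affine
and B-spline transforms compose in pull-back convention:
``d(p) = T_affine(T_bspline(p)) - p`` evaluated at every target voxel centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

from .core import DisplacementField, GeometryError, ImageVolume, VolumeGeometry
from .tree import VesselTree
from .warp import resample_image, warp_tree


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# SimpleITK interop.  Arrays are [i, j, k] with world = origin + idx*spacing;
# sitk's GetImageFromArray expects [z, y, x], hence the transposes.

def to_sitk(img: ImageVolume) -> sitk.Image:
    s = sitk.GetImageFromArray(np.ascontiguousarray(img.values.transpose(2, 1, 0)))
    s.SetSpacing(img.geometry.spacing)
    s.SetOrigin(img.geometry.origin)
    return s


def from_sitk(s: sitk.Image) -> ImageVolume:
    vals = sitk.GetArrayFromImage(s).transpose(2, 1, 0)
    geom = VolumeGeometry(vals.shape, tuple(s.GetSpacing()), tuple(s.GetOrigin()))
    return ImageVolume(geom, np.asarray(vals, float))


@dataclass
class AffineTransform:
    """Physical-space affine map ``T(p) = A (p - c) + c + t`` (mm)."""

    matrix: np.ndarray                       # 3x3
    translation: np.ndarray                  # mm
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        self.center = np.asarray(self.center, float).reshape(3)
        if np.linalg.cond(self.matrix) > 1e6:
            raise RegistrationError("affine matrix is numerically singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        return (p - self.center) @ self.matrix.T + self.center + self.translation

    def to_sitk(self) -> sitk.AffineTransform:
        t = sitk.AffineTransform(3)
        t.SetMatrix(self.matrix.ravel().tolist())
        t.SetCenter(self.center.tolist())
        t.SetTranslation(self.translation.tolist())
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "AffineTransform":
        t = sitk.AffineTransform(
            sitk.CompositeTransform(t).GetNthTransform(0)
            if isinstance(t, sitk.CompositeTransform) else t
        ) if not isinstance(t, sitk.AffineTransform) else t
        m = np.asarray(t.GetMatrix()).reshape(3, 3)
        return cls(m, np.asarray(t.GetTranslation()), np.asarray(t.GetCenter()))

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "translation": self.translation.tolist(),
                "center": self.center.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.asarray(d["matrix"]), np.asarray(d["translation"]),
                   np.asarray(d["center"]))


@dataclass
class BSplineTransform:
    """A (possibly multi-level-refined) cubic B-spline deformation."""

    transform: sitk.BSplineTransform
    knot_spacing_vox: int = 12
    levels: int = 3

    def __post_init__(self):
        if self.knot_spacing_vox < 4:
            raise RegistrationError("knot spacing must be >= 4 voxels (low-DOF contract)")

    @property
    def coefficients(self) -> np.ndarray:
        """Control-point displacement coefficients, shape (3, ...) mm."""
        params = np.asarray(self.transform.GetParameters())
        return params.reshape(3, -1)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        return np.array([self.transform.TransformPoint(tuple(q)) for q in p])

    def cap_coefficients(self, cap_mm: float) -> None:
        params = np.clip(np.asarray(self.transform.GetParameters()), -cap_mm, cap_mm)
        self.transform.SetParameters(params.tolist())


@dataclass(frozen=True)
class BSplineLayer:
    """One layer of the coarse-to-fine B-spline cascade."""

    knot_spacing_vox: int
    iterations: int
    shrink: tuple = (3,)
    smooth: tuple = (0.0,)


@dataclass
class RegistrationParams:
    """Knobs for the MI-driven registrations.

    The deformable model is a three-layer cascade of B-spline grids
    (knot spacing halving per layer); each layer is optimized with bounded
    L-BFGS-B on a full-sampling Mattes MI objective at a coarsened image
    resolution.  ``coeff_cap_mm`` bounds every control-point coefficient,
    keeping the displacement estimate low-complexity and fold-free.
    """

    bins: int = 128
    metric: str = "mi"            # deformable-layer metric: "mi" | "corr" | "ms"
    seed: int = 1234
    # rigid/affine stage
    rigid_shrink: tuple = (4, 2)
    rigid_smooth: tuple = (1.0, 0.0)
    rigid_iterations: int = 40
    rigid_learning_rate: float = 1.0
    rigid_sampling: float | None = None   # None = all voxels (deterministic)
    # deformable cascade (knot spacings in voxels of the fixed grid)
    layers: tuple = (
        BSplineLayer(24, 8, (4,), (1.0,)),
        BSplineLayer(12, 8, (4,), (1.0,)),
        BSplineLayer(6, 8, (3,), (0.0,)),
    )
    coeff_cap_mm: float = 8.0
    maxeval_factor: float = 1.2

    def fast(self) -> "RegistrationParams":
        """Coarser preset for ranking sweeps and cross-validation harnesses."""
        return replace(
            self,
            rigid_sampling=0.5, rigid_iterations=30,
            layers=(
                BSplineLayer(12, 6, (4,), (1.0,)),
                BSplineLayer(6, 6, (3,), (0.0,)),
            ),
        )


DEFAULT_PARAMS = RegistrationParams()


def _check_images(fixed: ImageVolume, moving: ImageVolume):
    for name, img in (("fixed", fixed), ("moving", moving)):
        if np.ptp(img.values) == 0:
            raise RegistrationError(f"{name} image is constant; MI is undefined")
    flo, fhi = fixed.geometry.physical_box()
    mlo, mhi = moving.geometry.physical_box()
    if np.any(fhi < mlo) or np.any(mhi < flo):
        raise RegistrationError("fixed and moving extents do not overlap")


def _base_method(params: RegistrationParams) -> sitk.ImageRegistrationMethod:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=params.bins)
    if params.rigid_sampling is None:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(params.rigid_sampling, params.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetShrinkFactorsPerLevel(list(params.rigid_shrink))
    reg.SetSmoothingSigmasPerLevel(list(params.rigid_smooth))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    return reg


def rigid_register(fixed: ImageVolume, moving: ImageVolume, mode: str = "rigid",
                   params: RegistrationParams = DEFAULT_PARAMS) -> AffineTransform:
    """Maximize MI over a multi-resolution pyramid; offsets start at zero.

    ``mode="rigid"`` (rotation + translation) suits intra-subject MRA-VWI
    alignment; ``mode="affine"`` suits inter-subject VWI-VWI alignment.
    """
    _check_images(fixed, moving)
    f, m = to_sitk(fixed), to_sitk(moving)
    if mode == "rigid":
        tx = sitk.Euler3DTransform()
    elif mode == "affine":
        tx = sitk.AffineTransform(3)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    center = np.asarray(fixed.geometry.origin) + fixed.geometry.extent / 2
    tx.SetCenter(center.tolist())
    def fresh_tx():
        t = sitk.Euler3DTransform() if mode == "rigid" else sitk.AffineTransform(3)
        t.SetCenter(center.tolist())
        return t

    last_err = None
    lr0 = params.rigid_learning_rate
    for lr in (lr0, lr0 / 4, lr0 / 16):
        tx = fresh_tx()
        reg = _base_method(params)
        reg.SetOptimizerAsGradientDescentLineSearch(
            learningRate=lr,
            numberOfIterations=params.rigid_iterations,
            convergenceMinimumValue=1e-7, convergenceWindowSize=10,
            lineSearchUpperLimit=2.0,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetInitialTransform(tx, inPlace=True)
        try:
            reg.Execute(f, m)
            last_err = None
            break
        except RuntimeError as e:
            # line search can march a hard pair out of overlap; retry gently
            last_err = e
    if last_err is not None:
        # optimizer failure on a non-degenerate pair: fall back to the
        # centered identity rather than abort the whole pipeline
        tx = fresh_tx()
    if mode == "rigid":
        m3 = np.asarray(tx.GetMatrix()).reshape(3, 3)
        return AffineTransform(m3, np.asarray(tx.GetTranslation()), center)
    return AffineTransform.from_sitk(tx)


def resample_through_affine(moving: ImageVolume, affine: AffineTransform,
                            target_geom: VolumeGeometry) -> ImageVolume:
    ref = sitk.Image(target_geom.dims, sitk.sitkFloat64)
    ref.SetSpacing(target_geom.spacing)
    ref.SetOrigin(target_geom.origin)
    out = sitk.Resample(to_sitk(moving), ref, affine.to_sitk(), sitk.sitkLinear, 0.0)
    return from_sitk(out)


def mutual_information(a: ImageVolume, b: ImageVolume, bins: int = 32) -> float:
    """Histogram mutual information (nats) between co-gridded volumes."""
    if a.geometry != b.geometry:
        raise GeometryError("volumes must share a geometry; resample first")
    h, _, _ = np.histogram2d(a.values.ravel(), b.values.ravel(), bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


@dataclass
class AtlasRanking:
    scores: dict[int, float]                  # atlas id -> MI (nats) after alignment
    selected: list[int]                       # top-k ids, descending score

    def __post_init__(self):
        svals = [self.scores[i] for i in self.selected]
        assert all(svals[i] >= svals[i + 1] for i in range(len(svals) - 1))


def rank_atlases(target_vwi: ImageVolume, atlas_vwis: list[ImageVolume], k: int = 3,
                 mode: str = "rigid",
                 params: RegistrationParams = DEFAULT_PARAMS) -> AtlasRanking:
    """Rigidly align every atlas to the target and rank by post-alignment MI.

    Ties break toward the lower atlas id.  ``k`` is clamped to the number of
    atlases.
    """
    if not atlas_vwis:
        raise RegistrationError("empty atlas list")
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = {}
    for i, atlas in enumerate(atlas_vwis):
        tr = rigid_register(target_vwi, atlas, mode=mode, params=params)
        warped = resample_through_affine(atlas, tr, target_vwi.geometry)
        scores[i] = mutual_information(target_vwi, warped, params.bins)
    order = sorted(scores, key=lambda i: (-scores[i], i))
    return AtlasRanking(scores, order[: min(k, len(atlas_vwis))])


def _fit_bspline_layer(f: sitk.Image, m: sitk.Image, layer: BSplineLayer,
                       params: RegistrationParams,
                       moving_initial: sitk.Transform | None) -> sitk.BSplineTransform:
    dims = np.asarray(f.GetSize())
    cells = np.maximum(1, np.round((dims - 1) / layer.knot_spacing_vox).astype(int))
    tx = sitk.BSplineTransformInitializer(f, [int(c) for c in cells], order=3)
    reg = sitk.ImageRegistrationMethod()
    if params.metric == "mi":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=params.bins)
    elif params.metric == "corr":
        reg.SetMetricAsCorrelation()
    elif params.metric == "ms":
        reg.SetMetricAsMeanSquares()
    else:
        raise ValueError(f"unknown metric {params.metric!r}")
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetShrinkFactorsPerLevel(list(layer.shrink))
    reg.SetSmoothingSigmasPerLevel(list(layer.smooth))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    cap = params.coeff_cap_mm
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7,
        numberOfIterations=layer.iterations,
        maximumNumberOfFunctionEvaluations=int(layer.iterations * params.maxeval_factor),
        lowerBound=-cap, upperBound=cap,
    )
    if moving_initial is not None:
        reg.SetMovingInitialTransform(moving_initial)
    reg.SetInitialTransform(tx, inPlace=True)
    try:
        reg.Execute(f, m)
    except RuntimeError as e:                            # pragma: no cover
        raise RegistrationError(str(e)) from e
    return tx


def _as_field_transform(transforms, geom: VolumeGeometry) -> sitk.Transform:
    """Flatten a pull-back chain into one displacement-field transform."""
    comp = sitk.CompositeTransform(3)
    for t in transforms:
        comp.AddTransform(t)
    filt = sitk.TransformToDisplacementFieldFilter()
    filt.SetSize(geom.dims)
    filt.SetOutputSpacing(geom.spacing)
    filt.SetOutputOrigin(geom.origin)
    return sitk.DisplacementFieldTransform(filt.Execute(comp))


def bspline_register(fixed: ImageVolume, moving: ImageVolume, init: AffineTransform,
                     params: RegistrationParams = DEFAULT_PARAMS) -> list[BSplineTransform]:
    """Low-complexity deformable registration on top of an affine pre-alignment.

    Runs the coarse-to-fine cascade of ``params.layers``; every layer is a
    cubic B-spline grid refined against the composition of all previous
    stages, so the finest grid only models what the coarser ones could not.
    Returns the cascade as a list ordered coarse to fine.
    """
    _check_images(fixed, moving)
    f, m = to_sitk(fixed), to_sitk(moving)
    geom = fixed.geometry
    chain: list[sitk.Transform] = [init.to_sitk()]
    out: list[BSplineTransform] = []
    for layer in params.layers:
        prev = _as_field_transform(chain, geom)
        tx = _fit_bspline_layer(f, m, layer, params, prev)
        # pull-back order: the new layer acts first, the earlier chain after
        chain = chain + [tx]
        out.append(BSplineTransform(tx, layer.knot_spacing_vox, len(params.layers)))
    return out


def compose_to_dvf(affine: AffineTransform, bspline, target_geom: VolumeGeometry
                   ) -> DisplacementField:
    """Dense pull-back field ``d(p) = T_affine(T_bspline(p)) - p`` on the grid.

    ``bspline`` may be ``None`` (affine only), a single
    :class:`BSplineTransform`, or the coarse-to-fine cascade list returned by
    :func:`bspline_register`; deformable corrections are expressed in the
    affinely pre-aligned frame and therefore applied before the affine.
    """
    comp = sitk.CompositeTransform(3)
    comp.AddTransform(affine.to_sitk())
    if bspline is not None:
        stages = bspline if isinstance(bspline, (list, tuple)) else [bspline]
        for b in stages:                      # added later => applied earlier
            comp.AddTransform(b.transform)
    filt = sitk.TransformToDisplacementFieldFilter()
    filt.SetSize(target_geom.dims)
    filt.SetOutputSpacing(target_geom.spacing)
    filt.SetOutputOrigin(target_geom.origin)
    fld = filt.Execute(comp)
    vec = sitk.GetArrayFromImage(fld).transpose(2, 1, 0, 3)
    return DisplacementField(target_geom, np.asarray(vec, float))


def resample_with_dvf(moving, dvf: DisplacementField):
    """Warp an image (linear, zero-padded) or a vessel tree (numerically
    inverted point mapping) onto the field's target grid."""
    if isinstance(moving, ImageVolume):
        return resample_image(moving, dvf)
    if isinstance(moving, VesselTree):
        return warp_tree(moving, dvf)
    raise TypeError(f"cannot warp object of type {type(moving).__name__}")


def affine_footprint_mask(affine: AffineTransform, atlas_geom: VolumeGeometry,
                          target_geom: VolumeGeometry) -> ImageVolume:
    """Binary mask of target voxels whose affine image lands inside the atlas
    physical box (the warped-box "parallelogram" ROI)."""
    pts = affine.apply(target_geom.voxel_centers().reshape(-1, 3))
    lo, hi = atlas_geom.physical_box()
    eps = 1e-6
    inside = np.all((pts >= lo - eps) & (pts <= hi + eps), axis=1)
    return ImageVolume(target_geom, inside.reshape(target_geom.dims).astype(float))


def register_pair(target_vwi: ImageVolume, atlas_vwi: ImageVolume,
                  params: RegistrationParams = DEFAULT_PARAMS,
                  mode: str = "affine"):
    """Full stage one for one (atlas, target) pair.

    Returns ``(affine, bsplines, dvf, roi_mask)`` with the dense pull-back
    field and the affine footprint ("parallelogram") mask on the target grid.
    """
    aff = rigid_register(target_vwi, atlas_vwi, mode=mode, params=params)
    bsps = bspline_register(target_vwi, atlas_vwi, aff, params=params)
    dvf = compose_to_dvf(aff, bsps, target_vwi.geometry)
    mask = affine_footprint_mask(aff, atlas_vwi.geometry, target_vwi.geometry)
    return aff, bsps, dvf, mask
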