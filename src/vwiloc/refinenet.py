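"""Stage two: attention-gated residual 3-D U-Net regressing the DVF residual.

The network corrects the stage-one displacement field: given either the field
itself (DVF2dDVF wiring) or the image pair (IM2dDVF wiring) plus an auxiliary
attention input, it predicts the residual between the stage-one field and the
MRA-derived "ground-truth" field, inside the affine-footprint ROI.

Architecture (common to both wirings): encoder of residual blocks (two 3x3x3
convolutions with a voxel-wise skip from the block input) with max-pooling by
2 between levels; filters start at 16 and double per level; decoder with
kernel-2 up-convolutions, attention-gated skip concatenations and residual
blocks; a final 1x1x1 convolution (zero-initialized, no activation) recovers
the three-channel residual.  ReLU follows every other convolution.  The
auxiliary attention input is average-pooled alongside the encoder and feeds
the gate ``alpha = sigmoid(psi(relu(Wx x + Wh h + Wg g)))`` at each skip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DisplacementField, GeometryError, ImageVolume, VolumeGeometry
from .nn import autodiff as ad
from .atlasreg import AffineTransform, RegistrationParams, bspline_register, compose_to_dvf

DVF_SCALE_MM = 10.0     # displacement channels are divided by this for the net


class TrainingError(RuntimeError):
    pass


@dataclass
class NetConfig:
    levels: int = 4
    base_filters: int = 16
    conv_kernel: int = 3
    upconv_kernel: int = 2
    main_channels: int = 3
    attention_channels: int = 4
    out_channels: int = 3

    @property
    def encoder_filters(self) -> tuple:
        return tuple(self.base_filters * 2**l for l in range(self.levels))


def _he(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class _ResBlock:
    """conv3-relu-conv3 with a voxel-wise skip from the block input."""

    def __init__(self, rng, cin, cout, tag):
        self.W1 = ad.Param(_he(rng, (cout, cin, 3, 3, 3), cin * 27), f"{tag}.W1")
        self.b1 = ad.Param(np.zeros(cout, np.float32), f"{tag}.b1")
        self.W2 = ad.Param(_he(rng, (cout, cout, 3, 3, 3), cout * 27), f"{tag}.W2")
        self.b2 = ad.Param(np.zeros(cout, np.float32), f"{tag}.b2")
        self.proj = None
        if cin != cout:
            self.proj = ad.Param(_he(rng, (cout, cin), cin), f"{tag}.proj")

    def params(self):
        ps = [self.W1, self.b1, self.W2, self.b2]
        return ps + [self.proj] if self.proj is not None else ps

    def __call__(self, x):
        h = ad.relu(ad.conv3(x, self.W1, self.b1))
        h = ad.conv3(h, self.W2, self.b2)
        skip = x if self.proj is None else ad.conv1(x, self.proj)
        return ad.relu(ad.add(h, skip))


class _AttentionGate:
    """Additive gate over skip features x, decoder signal h, attention g."""

    def __init__(self, rng, cx, ch, cg, tag):
        ci = max(cx // 2, 4)
        self.Wx = ad.Param(_he(rng, (ci, cx), cx), f"{tag}.Wx")
        self.Wh = ad.Param(_he(rng, (ci, ch), ch), f"{tag}.Wh")
        self.Wg = ad.Param(_he(rng, (ci, cg), cg), f"{tag}.Wg")
        self.bi = ad.Param(np.zeros(ci, np.float32), f"{tag}.bi")
        self.psi = ad.Param(_he(rng, (1, ci), ci), f"{tag}.psi")
        self.bpsi = ad.Param(np.zeros(1, np.float32), f"{tag}.bpsi")
        self.inter_channels = ci

    def params(self):
        return [self.Wx, self.Wh, self.Wg, self.bi, self.psi, self.bpsi]

    def alpha(self, x, h, g):
        s = ad.add(ad.add(ad.conv1(x, self.Wx), ad.conv1(h, self.Wh)),
                   ad.conv1(g, self.Wg, self.bi))
        return ad.sigmoid(ad.conv1(ad.relu(s), self.psi, self.bpsi))

    def __call__(self, x, h, g):
        return ad.mul(self.alpha(x, h, g), x)


class AttentionResUNet:
    """The common refinement network; see module docstring."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        filt = cfg.encoder_filters
        self.encoders = []
        cin = cfg.main_channels
        for l, c in enumerate(filt):
            self.encoders.append(_ResBlock(rng, cin, c, f"enc{l}"))
            cin = c
        self.upconvs, self.gates, self.decoders = [], [], []
        for l in range(cfg.levels - 2, -1, -1):
            cdeep = filt[l + 1]
            c = filt[l]
            W = ad.Param(_he(rng, (c, cdeep, 2, 2, 2), cdeep * 8), f"up{l}.W")
            b = ad.Param(np.zeros(c, np.float32), f"up{l}.b")
            self.upconvs.append((W, b))
            self.gates.append(_AttentionGate(rng, c, c, cfg.attention_channels, f"gate{l}"))
            self.decoders.append(_ResBlock(rng, 2 * c, c, f"dec{l}"))
        # zero-initialized head: the network starts as the identity correction
        self.head_W = ad.Param(np.zeros((cfg.out_channels, filt[0]), np.float32), "head.W")
        self.head_b = ad.Param(np.zeros(cfg.out_channels, np.float32), "head.b")

    def params(self) -> list[ad.Param]:
        ps = []
        for e in self.encoders:
            ps += e.params()
        for (W, b), g, d in zip(self.upconvs, self.gates, self.decoders):
            ps += [W, b] + g.params() + d.params()
        return ps + [self.head_W, self.head_b]

    def forward(self, main: np.ndarray, attention: np.ndarray) -> ad.Var:
        cfg = self.cfg
        dims = np.asarray(main.shape[1:])
        if np.any(dims % 2 ** (cfg.levels - 1)):
            raise GeometryError(
                f"spatial dims {tuple(dims)} not divisible by {2**(cfg.levels-1)}"
            )
        x = ad.Var(main)
        a = ad.Var(attention)
        # encoder, keeping skip features per level
        skips = []
        attn = [a]
        for l, enc in enumerate(self.encoders):
            x = enc(x)
            skips.append(x)
            if l < cfg.levels - 1:
                x = ad.maxpool2(x)
                attn.append(ad.avgpool2(attn[-1]))
        # decoder with gated skips
        d = skips[-1]
        for i, l in enumerate(range(cfg.levels - 2, -1, -1)):
            W, b = self.upconvs[i]
            d = ad.upconv2(d, W, b)
            gated = self.gates[i](skips[l], d, attn[l])
            d = self.decoders[i](ad.concat(gated, d))
        return ad.conv1(d, self.head_W, self.head_b)

    def predict(self, main: np.ndarray, attention: np.ndarray) -> np.ndarray:
        return self.forward(main, attention).v

    def describe(self) -> dict:
        """Programmatic architecture audit."""
        cfg = self.cfg
        return {
            "encoder_filters": list(cfg.encoder_filters),
            "conv_kernel": cfg.conv_kernel,
            "upconv_kernel": cfg.upconv_kernel,
            "head_kernel": 1,
            "out_channels": cfg.out_channels,
            "n_attention_gates": len(self.gates),
            "n_residual_blocks": len(self.encoders) + len(self.decoders),
            "residual_add_per_block": True,
            "head_activation": None,
            "hidden_activation": "relu",
            "head_zero_initialized": bool(
                np.all(self.head_W.v == 0) and np.all(self.head_b.v == 0)
            ),
            "n_parameters": int(sum(p.v.size for p in self.params())),
        }


def build_network(cfg: NetConfig = NetConfig(), seed: int = 0) -> AttentionResUNet:
    return AttentionResUNet(cfg, seed)


# ---------------------------------------------------------------------------
# Loss (numpy surface, shared with the evaluation stack)

def masked_mse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean over masked voxels of squared component differences (mm^2).

    ``pred``/``target`` are (X, Y, Z, 3) residual fields or (3, X, Y, Z)
    channel stacks; ``mask`` is a binary volume.
    """
    p = np.asarray(pred, float)
    t = np.asarray(target, float)
    if p.shape[0] == 3 and p.ndim == 4 and p.shape != t.shape:
        raise GeometryError("pred/target shapes differ")
    m = np.asarray(mask, bool)
    if not m.any():
        raise ValueError("mask selects no voxels")
    if p.ndim == 4 and p.shape[-1] == 3:        # (X,Y,Z,3)
        res = ((p - t) ** 2).sum(axis=-1)
    else:                                        # (3,X,Y,Z)
        res = ((p - t) ** 2).sum(axis=0)
    if res.shape != m.shape:
        raise GeometryError("mask shape does not match fields")
    return float(res[m].mean())


# ---------------------------------------------------------------------------
# Crop / rescale between acquisition and working grids

@dataclass(frozen=True)
class CropRescaleSpec:
    """Center-crop (zero-padding where the crop exceeds the input) followed by
    an integer-factor rescale to the working grid."""

    crop_dims: tuple = (192, 384, 320)
    out_dims: tuple = (48, 96, 80)

    @property
    def factors(self) -> tuple:
        f = tuple(c // o for c, o in zip(self.crop_dims, self.out_dims))
        if any(c % o for c, o in zip(self.crop_dims, self.out_dims)):
            raise GeometryError("crop dims must be integer multiples of output dims")
        return f


def _crop_pad(values: np.ndarray, crop_dims, comp_axis: bool):
    in_dims = values.shape[:3]
    out_shape = tuple(crop_dims) + values.shape[3:]
    out = np.zeros(out_shape, dtype=values.dtype)
    src, dst = [], []
    for a in range(3):
        n, c = in_dims[a], crop_dims[a]
        if c > 2 * n:
            raise GeometryError(f"crop {c} exceeds twice the input size {n} on axis {a}")
        if n >= c:
            start = (n - c) // 2
            src.append(slice(start, start + c))
            dst.append(slice(0, c))
        else:
            pad = (c - n) // 2
            src.append(slice(0, n))
            dst.append(slice(pad, pad + n))
    out[tuple(dst)] = values[tuple(src)]
    offset = [(in_dims[a] - crop_dims[a]) / 2 for a in range(3)]   # voxels, may be negative
    return out, offset


def crop_and_rescale(obj, mode: str, spec: CropRescaleSpec = CropRescaleSpec()):
    """Map a full-resolution volume/field/mask onto the working grid.

    Images are block-averaged, masks nearest-sampled, displacement fields
    linearly interpolated; field vectors are in mm and therefore keep their
    values across the resolution change.
    """
    from scipy.ndimage import zoom as ndzoom

    if mode not in ("image", "field", "mask"):
        raise ValueError(f"unknown mode {mode!r}")
    is_field = isinstance(obj, DisplacementField)
    values = obj.vectors if is_field else obj.values
    geom = obj.geometry
    cropped, offset = _crop_pad(values, spec.crop_dims, is_field)
    f = spec.factors
    if mode == "image":
        n1, n2, n3 = spec.out_dims
        out_vals = cropped.reshape(n1, f[0], n2, f[1], n3, f[2]).mean(axis=(1, 3, 5))
    elif mode == "mask":
        idx = [np.arange(n) * f[a] + f[a] // 2 for a, n in enumerate(spec.out_dims)]
        out_vals = cropped[np.ix_(*idx)]
    else:
        factors = [o / c for o, c in zip(spec.out_dims, spec.crop_dims)] + [1.0]
        out_vals = ndzoom(cropped, factors, order=1, mode="nearest", grid_mode=True)
    new_spacing = tuple(geom.spacing[a] * f[a] for a in range(3))
    new_origin = tuple(
        geom.origin[a] + (offset[a] + (f[a] - 1) / 2) * geom.spacing[a] for a in range(3)
    )
    out_geom = VolumeGeometry(spec.out_dims, new_spacing, new_origin)
    if is_field:
        return DisplacementField(out_geom, out_vals)
    return ImageVolume(out_geom, out_vals)


def upscale_field(field: DisplacementField, full_geom: VolumeGeometry,
                  spec: CropRescaleSpec = CropRescaleSpec()) -> DisplacementField:
    """Inverse of :func:`crop_and_rescale` for fields: linear interpolation of
    the working-grid field at every full-grid voxel centre (edge-clamped
    outside the crop); vector values stay in mm."""
    from scipy.ndimage import map_coordinates

    pts = full_geom.voxel_centers()
    idx = (pts - np.asarray(field.geometry.origin)) / np.asarray(field.geometry.spacing)
    out = np.empty(full_geom.dims + (3,))
    for c in range(3):
        out[..., c] = map_coordinates(
            field.vectors[..., c], [idx[..., 0], idx[..., 1], idx[..., 2]],
            order=1, mode="nearest",
        )
    return DisplacementField(full_geom, out)


# ---------------------------------------------------------------------------
# Training data

@dataclass
class RefinementSample:
    """One (atlas, target) training/inference example on the working grid."""

    main_input: np.ndarray          # (C, X, Y, Z) float32
    attention_input: np.ndarray     # (Ca, X, Y, Z) float32
    roi_mask: np.ndarray            # (X, Y, Z) binary
    target_residual: DisplacementField | None   # gt - stage1, mm
    stage1_dvf: DisplacementField
    wiring: str
    dvf_scale: float = DVF_SCALE_MM


def _zscore(v: np.ndarray, mask: np.ndarray) -> np.ndarray:
    sel = v[mask] if mask.any() else v
    sd = sel.std()
    return (v - sel.mean()) / (sd if sd > 0 else 1.0)


def assemble_sample(target_vwi: ImageVolume, warped_atlas_vwi: ImageVolume,
                    stage1_dvf: DisplacementField, roi_mask: ImageVolume,
                    gt_dvf: DisplacementField | None, wiring: str) -> RefinementSample:
    """Build network inputs for one pair in the requested wiring.

    DVF2dDVF: main = stage-one DVF (3 ch, scaled) + ROI mask; attention =
    z-scored target VWI + (target - warped atlas) difference.  IM2dDVF: main =
    target VWI + warped atlas VWI + ROI mask; attention = stage-one DVF (3 ch,
    scaled) + difference.  Intensities are z-scored within the ROI; DVF
    channels are divided by ``DVF_SCALE_MM`` and unscaled on output.
    """
    geom = target_vwi.geometry
    for other in (warped_atlas_vwi.geometry, stage1_dvf.geometry, roi_mask.geometry):
        if other != geom:
            raise GeometryError("all sample channels must share one geometry")
    mask = roi_mask.values > 0.5
    tv = _zscore(target_vwi.values, mask).astype(np.float32)
    av = _zscore(warped_atlas_vwi.values, mask).astype(np.float32)
    diff = (tv - av).astype(np.float32)
    dvf_ch = (stage1_dvf.vectors / DVF_SCALE_MM).transpose(3, 0, 1, 2).astype(np.float32)
    mask_ch = mask.astype(np.float32)[None]
    if wiring == "DVF2dDVF":
        main = np.concatenate([dvf_ch, mask_ch], axis=0)
        attention = np.stack([tv, diff], axis=0)
    elif wiring == "IM2dDVF":
        main = np.concatenate([tv[None], av[None], mask_ch], axis=0)
        attention = np.concatenate([dvf_ch, diff[None]], axis=0)
    else:
        raise ValueError(f"unknown wiring {wiring!r}")
    residual = None
    if gt_dvf is not None:
        if gt_dvf.geometry != geom:
            raise GeometryError("gt field must share the sample geometry")
        residual = DisplacementField(geom, gt_dvf.vectors - stage1_dvf.vectors)
    return RefinementSample(main, attention, mask, residual, stage1_dvf, wiring)


def net_config_for(sample: RefinementSample, levels: int = 4,
                   base_filters: int = 16) -> NetConfig:
    return NetConfig(levels=levels, base_filters=base_filters,
                     main_channels=sample.main_input.shape[0],
                     attention_channels=sample.attention_input.shape[0])


#: MRA-to-MRA ground-truth registration: same-modality bright-vessel images,
#: so plain correlation drives the match (and is cheaper than fine-binned MI)
GT_PARAMS = RegistrationParams(metric="corr")


def ground_truth_dvf(atlas_mra: ImageVolume, target_mra: ImageVolume,
                     init: AffineTransform,
                     params: RegistrationParams = GT_PARAMS) -> DisplacementField:
    """Training-time reference field from MRA-to-MRA deformable registration.

    Only trustworthy near vessels, where the angiographic contrast drives the
    match; that is exactly where the warped atlas tree lives.
    """
    bsps = bspline_register(target_mra, atlas_mra, init, params=params)
    return compose_to_dvf(init, bsps, target_mra.geometry)


# ---------------------------------------------------------------------------
# Training and inference

def train_refiner(samples: list[RefinementSample], cfg: NetConfig | None = None,
                  epochs: int = 200, seed: int = 0, lr: float = 1e-3,
                  verbose: bool = False):
    """Train the refinement network; deterministic for a fixed seed.

    Batch size is one sample (one optimizer step per sample); the loss trace
    records the mean per-epoch masked MSE of the scaled residual.
    """
    if not samples:
        raise TrainingError("need at least one training sample")
    if cfg is None:
        cfg = net_config_for(samples[0])
    net = AttentionResUNet(cfg, seed=seed)
    opt = ad.Adam(net.params(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    trace = []
    scaled_targets = [
        (s.target_residual.vectors / s.dvf_scale).transpose(3, 0, 1, 2).astype(np.float32)
        for s in samples
    ]
    for epoch in range(epochs):
        order = rng.permutation(len(samples))
        losses = []
        for i in order:
            s = samples[i]
            out = net.forward(s.main_input, s.attention_input)
            loss = ad.masked_mse(out, scaled_targets[i], s.roi_mask)
            if not np.isfinite(loss.v):
                raise TrainingError(f"loss diverged at epoch {epoch}")
            opt.zero_grad()
            ad.backward(loss)
            opt.step()
            losses.append(float(loss.v))
        trace.append(float(np.mean(losses)))
        if verbose and (epoch % 20 == 0 or epoch == epochs - 1):
            print(f"epoch {epoch:4d}  loss {trace[-1]:.6f}")
    return net, trace


def predict_residual(net: AttentionResUNet, sample: RefinementSample):
    """Predict the residual field (mm) and the corrected stage-one field."""
    out = net.predict(sample.main_input, sample.attention_input)
    vec = out.transpose(1, 2, 3, 0).astype(float) * sample.dvf_scale
    geom = sample.stage1_dvf.geometry
    ddvf = DisplacementField(geom, vec)
    corrected = DisplacementField(geom, sample.stage1_dvf.vectors + vec)
    return ddvf, corrected
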