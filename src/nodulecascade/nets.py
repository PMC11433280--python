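"""The three subnetworks of the nodule cascade.

* **Coarse Seg-net** — DeepLabv3+-style encoder/decoder: an aligned-Xception
  backbone in which *every* down-sampling step is a stride-2 depthwise
  separable convolution (no max pooling anywhere), an atrous spatial
  pyramid, a low-level-fusion decoder, and a 1x1 single-channel sigmoid
  head bilinearly upsampled to the input size.
* **Fine Seg-net** — identical structure, initialised as a parameter copy
  of a coarse model, plus a *Fine-layer* that area-downsamples the coarse
  probability map to the deepest feature grid, concatenates it as an extra
  channel and fuses with 1x1 conv + batch-norm + ReLU.
* **Class-net** — Xception-style classifier whose exit flow keeps full
  stride-16 resolution (the final down-sampling stage is removed) with its
  last two separable convolutions dilated (rate 2, padding 2), ending in
  global average pooling and a single sigmoid malignancy unit.  It accepts
  4-channel input (RGB patch + coarse mask); the fourth input-kernel slice
  is initialised as the mean of the three RGB slices.

Every model is fully configurable in width (``width_multiplier``) and
middle-flow depth so the same code runs desk-scale on CPU.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, avg_pool2d, bilinear_resize, concat, no_grad

__all__ = [
    "BackboneSpec",
    "ClassNetSpec",
    "XceptionBackbone",
    "CoarseSegNet",
    "FineSegNet",
    "FineLayer",
    "ClassNet",
    "build_backbone",
    "build_coarse_segnet",
    "build_fine_segnet",
    "build_classnet",
    "init_fourth_channel",
    "save_checkpoint",
    "load_checkpoint",
]

# base (width_multiplier = 1) channel plan of the aligned-Xception flows
_STEM = (32, 64)
_ENTRY = (128, 256, 728)
_EXIT = (1024, 1536, 2048)
_ASPP_OUT = 256
_DECODER_LOW = 48
_DECODER_MID = 256


@dataclass(frozen=True)
class BackboneSpec:
    """Configuration of the segmentation backbone.

    width_multiplier scales every channel count (floor 8); output_stride
    is the input/deepest-feature resolution ratio; dilation_rates are the
    atrous pyramid rates; middle_repeats is the number of middle-flow
    residual blocks (16 in the full-scale reference topology).
    """

    width_multiplier: float = 1.0
    output_stride: int = 16
    dilation_rates: tuple[int, ...] = (6, 12, 18)
    input_channels: int = 3
    middle_repeats: int = 16

    def __post_init__(self):
        if self.output_stride not in (8, 16):
            raise ValueError("output_stride must be 8 or 16")
        if not 0 < self.width_multiplier <= 1:
            raise ValueError("width_multiplier must be in (0, 1]")
        if self.middle_repeats < 1:
            raise ValueError("middle_repeats must be >= 1")

    def ch(self, base: int) -> int:
        return max(8, int(round(base * self.width_multiplier)))


@dataclass(frozen=True)
class ClassNetSpec:
    """Configuration of the classifier.

    input_channels is 4 when the coarse mask is concatenated to the RGB
    patch, 3 otherwise.  dilated_exit keeps the exit flow at stride 16
    with its last two separable convolutions dilated (rate 2, padding 2).
    """

    input_channels: int = 4
    dilated_exit: bool = True
    num_classes: int = 1
    width_multiplier: float = 1.0
    middle_repeats: int = 16

    def __post_init__(self):
        if self.input_channels not in (3, 4):
            raise ValueError("input_channels must be 3 or 4")
        if self.num_classes != 1:
            raise ValueError("single sigmoid malignancy unit only")
        if not 0 < self.width_multiplier <= 1:
            raise ValueError("width_multiplier must be in (0, 1]")

    def ch(self, base: int) -> int:
        return max(8, int(round(base * self.width_multiplier)))


def _conv_bn_relu(cin, cout, k, stride=1, padding=0, dilation=1):
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, stride=stride, padding=padding,
                  dilation=dilation, bias=False),
        nn.BatchNorm2d(cout), nn.ReLU())


def _sep_bn_relu(cin, cout, stride=1, dilation=1):
    return nn.Sequential(
        nn.SeparableConv2d(cin, cout, 3, stride=stride, dilation=dilation),
        nn.BatchNorm2d(cout), nn.ReLU())


class _XBlock(nn.Module):
    """Residual block of three separable convolutions.

    Down-sampling, when requested, is done by a stride on the *last*
    separable convolution — the stride-2 depthwise separable convolution
    that replaces max pooling in the aligned backbone.
    """

    def __init__(self, cin: int, cout: int, stride: int = 1, dilation: int = 1):
        super().__init__()
        self.sep1 = _sep_bn_relu(cin, cout, dilation=dilation)
        self.sep2 = _sep_bn_relu(cout, cout, dilation=dilation)
        self.sep3 = nn.Sequential(
            nn.SeparableConv2d(cout, cout, 3, stride=stride, dilation=dilation),
            nn.BatchNorm2d(cout))
        if stride != 1 or cin != cout:
            self.skip = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False),
                nn.BatchNorm2d(cout))
        else:
            self.skip = nn.Identity()
        self.relu = nn.ReLU()

    def forward(self, x):
        return self.relu(self.sep3(self.sep2(self.sep1(x))) + self.skip(x))


class XceptionBackbone(nn.Module):
    """Aligned-Xception feature extractor without any max pooling.

    ``forward`` returns ``(deep, low)``: the deepest feature map at
    ``output_stride`` and the stride-4 low-level map used by the decoder.
    """

    def __init__(self, spec: BackboneSpec):
        super().__init__()
        self.spec = spec
        ch = spec.ch
        s3 = 2 if spec.output_stride == 16 else 1
        exit_dil = 2 if spec.output_stride == 16 else 4
        self.stem1 = _conv_bn_relu(spec.input_channels, ch(_STEM[0]), 3,
                                   stride=2, padding=1)
        self.stem2 = _conv_bn_relu(ch(_STEM[0]), ch(_STEM[1]), 3, padding=1)
        self.block1 = _XBlock(ch(_STEM[1]), ch(_ENTRY[0]), stride=2)
        self.block2 = _XBlock(ch(_ENTRY[0]), ch(_ENTRY[1]), stride=2)
        self.block3 = _XBlock(ch(_ENTRY[1]), ch(_ENTRY[2]), stride=s3)
        mid_dil = 1 if spec.output_stride == 16 else 2
        self.middle = nn.ModuleList([
            _XBlock(ch(_ENTRY[2]), ch(_ENTRY[2]), dilation=mid_dil)
            for _ in range(spec.middle_repeats)])
        self.exit_block = _XBlock(ch(_ENTRY[2]), ch(_EXIT[0]), dilation=exit_dil)
        self.exit_sep1 = _sep_bn_relu(ch(_EXIT[0]), ch(_EXIT[1]), dilation=exit_dil)
        self.exit_sep2 = _sep_bn_relu(ch(_EXIT[1]), ch(_EXIT[2]), dilation=exit_dil)
        self.out_channels = ch(_EXIT[2])
        self.low_channels = ch(_ENTRY[0])

    def forward(self, x):
        x = self.stem2(self.stem1(x))
        low = self.block1(x)
        x = self.block3(self.block2(low))
        for blk in self.middle:
            x = blk(x)
        x = self.exit_sep2(self.exit_sep1(self.exit_block(x)))
        return x, low


class _ASPP(nn.Module):
    """Atrous spatial pyramid: 1x1 + three dilated 3x3 branches + image pool."""

    def __init__(self, cin: int, cout: int, rates: tuple[int, ...]):
        super().__init__()
        self.branch0 = _conv_bn_relu(cin, cout, 1)
        self.branches = nn.ModuleList([
            _sep_bn_relu(cin, cout, dilation=r) for r in rates])
        self.image_pool = _conv_bn_relu(cin, cout, 1)
        self.project = _conv_bn_relu(cout * (2 + len(rates)), cout, 1)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        feats = [self.branch0(x)] + [b(x) for b in self.branches]
        pooled = x.mean(axis=(2, 3), keepdims=True)
        feats.append(bilinear_resize(self.image_pool(pooled), (h, w)))
        return self.project(concat(feats, axis=1))


class _Decoder(nn.Module):
    def __init__(self, deep_c: int, low_c: int, low_proj: int, mid_c: int):
        super().__init__()
        self.low_proj = _conv_bn_relu(low_c, low_proj, 1)
        self.fuse1 = _sep_bn_relu(deep_c + low_proj, mid_c)
        self.fuse2 = _sep_bn_relu(mid_c, mid_c)
        self.out_channels = mid_c

    def forward(self, deep, low):
        deep = bilinear_resize(deep, (low.shape[2], low.shape[3]))
        x = concat([deep, self.low_proj(low)], axis=1)
        return self.fuse2(self.fuse1(x))


class CoarseSegNet(nn.Module):
    """Encoder -> atrous pyramid -> decoder -> 1x1 sigmoid head."""

    def __init__(self, spec: BackboneSpec):
        super().__init__()
        self.spec = spec
        self.backbone = XceptionBackbone(spec)
        self.aspp = _ASPP(self.backbone.out_channels, spec.ch(_ASPP_OUT),
                          spec.dilation_rates)
        self.decoder = _Decoder(spec.ch(_ASPP_OUT), self.backbone.low_channels,
                                spec.ch(_DECODER_LOW), spec.ch(_DECODER_MID))
        self.head = nn.Conv2d(self.decoder.out_channels, 1, 1, bias=True)

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        h, w = x.shape[2], x.shape[3]
        deep, low = self.backbone(x)
        deep = self.aspp(deep)
        feat = self.decoder(deep, low)
        return bilinear_resize(self.head(feat).sigmoid(), (h, w))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode probability maps for a numpy batch."""
        self.eval()
        with no_grad():
            return self.forward(Tensor(x)).numpy()


class FineLayer(nn.Module):
    """Fuse the coarse probability map into the deepest encoder features.

    The full-resolution coarse mask is area-downsampled to the feature
    grid, concatenated as one extra channel, and fused back to the
    original channel count by 1x1 conv -> batch-norm -> ReLU.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels
        self.fuse = nn.Sequential(nn.Conv2d(channels + 1, channels, 1, bias=False),
                                  nn.BatchNorm2d(channels), nn.ReLU())

    def forward(self, deep, coarse_mask):
        coarse_mask = coarse_mask if isinstance(coarse_mask, Tensor) else Tensor(coarse_mask)
        fh, mh = deep.shape[2], coarse_mask.shape[2]
        if mh % fh:
            raise ValueError(f"mask height {mh} not a multiple of feature height {fh}")
        mask_ds = avg_pool2d(coarse_mask, mh // fh)
        if mask_ds.shape[2:] != deep.shape[2:]:
            raise ValueError("mask and feature grids do not align after resize")
        return self.fuse(concat([deep, mask_ds], axis=1))


class FineSegNet(nn.Module):
    """Coarse Seg-net structure plus the Fine-layer; takes (image, coarse mask)."""

    def __init__(self, spec: BackboneSpec):
        super().__init__()
        self.spec = spec
        self.backbone = XceptionBackbone(spec)
        self.fine_layer = FineLayer(self.backbone.out_channels)
        self.aspp = _ASPP(self.backbone.out_channels, spec.ch(_ASPP_OUT),
                          spec.dilation_rates)
        self.decoder = _Decoder(spec.ch(_ASPP_OUT), self.backbone.low_channels,
                                spec.ch(_DECODER_LOW), spec.ch(_DECODER_MID))
        self.head = nn.Conv2d(self.decoder.out_channels, 1, 1, bias=True)

    def forward(self, x, coarse_mask):
        x = x if isinstance(x, Tensor) else Tensor(x)
        h, w = x.shape[2], x.shape[3]
        deep, low = self.backbone(x)
        deep = self.fine_layer(deep, coarse_mask)
        deep = self.aspp(deep)
        feat = self.decoder(deep, low)
        return bilinear_resize(self.head(feat).sigmoid(), (h, w))

    def predict(self, x: np.ndarray, coarse_mask: np.ndarray) -> np.ndarray:
        self.eval()
        with no_grad():
            return self.forward(Tensor(x), Tensor(coarse_mask)).numpy()


class ClassNet(nn.Module):
    """Benign/malignant classifier with a full-resolution dilated exit flow."""

    def __init__(self, spec: ClassNetSpec):
        super().__init__()
        self.spec = spec
        ch = spec.ch
        self.stem1 = _conv_bn_relu(spec.input_channels, ch(_STEM[0]), 3,
                                   stride=2, padding=1)
        self.stem2 = _conv_bn_relu(ch(_STEM[0]), ch(_STEM[1]), 3, padding=1)
        self.block1 = _XBlock(ch(_STEM[1]), ch(_ENTRY[0]), stride=2)
        self.block2 = _XBlock(ch(_ENTRY[0]), ch(_ENTRY[1]), stride=2)
        self.block3 = _XBlock(ch(_ENTRY[1]), ch(_ENTRY[2]), stride=2)
        self.middle = nn.ModuleList([
            _XBlock(ch(_ENTRY[2]), ch(_ENTRY[2])) for _ in range(spec.middle_repeats)])
        # reference exit flow ends with a stride-2 (pooling) stage; here it
        # is removed, and the last two separable convolutions compensate
        # with dilation 2 / padding 2
        exit_stride = 1 if spec.dilated_exit else 2
        dil = 2 if spec.dilated_exit else 1
        self.exit_block = _XBlock(ch(_ENTRY[2]), ch(_EXIT[0]), stride=exit_stride)
        self.exit_sep1 = nn.Sequential(
            nn.SeparableConv2d(ch(_EXIT[0]), ch(_EXIT[1]), 3, dilation=dil,
                               padding=dil),
            nn.BatchNorm2d(ch(_EXIT[1])), nn.ReLU())
        self.exit_sep2 = nn.Sequential(
            nn.SeparableConv2d(ch(_EXIT[1]), ch(_EXIT[2]), 3, dilation=dil,
                               padding=dil),
            nn.BatchNorm2d(ch(_EXIT[2])), nn.ReLU())
        self.pool = nn.GlobalAvgPool2d()
        self.fc = nn.Linear(ch(_EXIT[2]), 1)

    def features(self, x):
        """Last-convolution feature map (pre-pooling), used by Grad-CAM."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        x = self.stem2(self.stem1(x))
        x = self.block3(self.block2(self.block1(x)))
        for blk in self.middle:
            x = blk(x)
        return self.exit_sep2(self.exit_sep1(self.exit_block(x)))

    def forward(self, x, return_features: bool = False):
        feat = self.features(x)
        score = self.fc(self.pool(feat)).sigmoid().reshape(-1)
        if return_features:
            return score, feat
        return score

    def predict(self, x: np.ndarray) -> np.ndarray:
        self.eval()
        with no_grad():
            return self.forward(Tensor(x)).numpy()


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_backbone(spec: BackboneSpec, seed: int = 0) -> XceptionBackbone:
    model = XceptionBackbone(spec)
    model.init_weights(np.random.default_rng(seed))
    return model


def build_coarse_segnet(spec: BackboneSpec, seed: int = 0) -> CoarseSegNet:
    model = CoarseSegNet(spec)
    model.init_weights(np.random.default_rng(seed))
    return model


def build_fine_segnet(spec: BackboneSpec, coarse: CoarseSegNet | None = None, *,
                      allow_fresh_init: bool = False, seed: int = 0) -> FineSegNet:
    """Fine Seg-net sharing structure and initial parameters with ``coarse``.

    Every parameter the two structures have in common is copied from the
    coarse model (subsequent training lets them diverge); only the
    Fine-layer is freshly initialised.  Passing no coarse model requires
    ``allow_fresh_init=True``.
    """
    if coarse is None and not allow_fresh_init:
        raise ValueError("fine net needs a coarse reference "
                         "(or allow_fresh_init=True)")
    model = FineSegNet(spec)
    model.init_weights(np.random.default_rng(seed))
    if coarse is not None:
        if coarse.spec != spec:
            raise ValueError(f"spec mismatch: coarse built with {coarse.spec}")
        shared = coarse.state_dict()
        own = dict(model.named_parameters())
        own_buf = dict(model.named_buffers())
        for name, value in shared.items():
            if name in own:
                own[name].data = value.copy()
            elif name in own_buf:
                own_buf[name][...] = value
    return model


def init_fourth_channel(weights: np.ndarray) -> np.ndarray:
    """Extend a 3-input-channel kernel bank to 4 channels.

    The added slice is the elementwise mean of the three RGB slices; the
    RGB slices themselves are unchanged.
    """
    w = np.asarray(weights)
    if w.ndim != 4 or w.shape[1] != 3:
        raise ValueError(f"expected (Cout, 3, kh, kw) weights, got {w.shape}")
    mean = w.mean(axis=1, keepdims=True)
    return np.concatenate([w, mean], axis=1)


def build_classnet(spec: ClassNetSpec, seed: int = 0) -> ClassNet:
    """Build Class-net; with 4-channel input the first convolution draws its
    RGB kernels first and derives the mask channel as their mean."""
    model = ClassNet(spec)
    model.init_weights(np.random.default_rng(seed))
    if spec.input_channels == 4:
        conv = model.stem1._seq[0]
        rng = np.random.default_rng(seed + 1)
        rgb = nn._trunc_normal(rng, (conv.cout, 3, 3, 3), np.sqrt(2.0 / 27))
        conv.weight.data = init_fourth_channel(rgb)
    return model


def load_rgb_stem(model: ClassNet, rgb_weights: np.ndarray) -> None:
    """Load 3-channel reference stem weights into a (possibly 4-channel)
    Class-net, preserving the RGB kernels exactly."""
    conv = model.stem1._seq[0]
    if model.spec.input_channels == 4:
        conv.weight.data = init_fourth_channel(rgb_weights)
    else:
        conv.weight.data = np.asarray(rgb_weights, np.float32).copy()


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_KINDS = {"coarse": (CoarseSegNet, BackboneSpec),
          "fine": (FineSegNet, BackboneSpec),
          "class": (ClassNet, ClassNetSpec)}


def save_checkpoint(path, model: nn.Module, meta: dict | None = None) -> None:
    """Write weights plus the full build spec; loads refuse a different spec."""
    kind = {CoarseSegNet: "coarse", FineSegNet: "fine", ClassNet: "class"}[type(model)]
    spec_dict = dataclasses.asdict(model.spec)
    header = json.dumps({"kind": kind, "spec": spec_dict, "meta": meta or {}})
    np.savez(path, __header__=np.array(header), **model.state_dict())


def load_checkpoint(path, expected_spec=None) -> tuple[nn.Module, dict]:
    """Rebuild the model stored at ``path``.

    ``expected_spec`` (a BackboneSpec/ClassNetSpec) is checked against the
    stored spec; a mismatch is an error.
    Returns ``(model, meta)``.
    """
    with np.load(path, allow_pickle=False) as archive:
        header = json.loads(str(archive["__header__"]))
        state = {k: archive[k] for k in archive.files if k != "__header__"}
    cls, spec_cls = _KINDS[header["kind"]]
    spec = header["spec"]
    if "dilation_rates" in spec:
        spec["dilation_rates"] = tuple(spec["dilation_rates"])
    spec = spec_cls(**spec)
    if expected_spec is not None and spec != expected_spec:
        raise ValueError(f"checkpoint spec {spec} does not match requested "
                         f"{expected_spec}")
    if cls is FineSegNet:
        model = FineSegNet(spec)
    else:
        model = cls(spec)
    model.load_state_dict(state)
    model.eval()
    return model, header["meta"]
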