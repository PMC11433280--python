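"""Staged training, evaluation and visualisation of the nodule cascade.

The procedure is deliberately staged rather than jointly optimised:

1. ``train_coarse`` — fit Coarse Seg-net with the hybrid (Dice + rank)
   loss, keeping the checkpoint with the best validation Jaccard index;
2. ``precompute_masks`` — run the frozen coarse model over every manifest
   image and store its probability map beside the image;
3. ``train_fine`` — initialise Fine Seg-net as a parameter copy of the
   coarse model and fine-tune it on (image, coarse-map) pairs;
4. ``train_class`` — fit Class-net on 4-channel (RGB + coarse map) input
   with binary cross-entropy, keeping the best-validation-accuracy
   checkpoint; ``use_mask=False`` gives the unguided 3-channel ablation;
5. ``cascade_predict`` / ``evaluate`` — run all three stages and report
   segmentation overlap and classification metrics;
6. ``compute_cam`` — gradient-weighted class activation maps over the
   classifier's last convolutional features.

Prediction distillation is by value only: downstream networks consume the
coarse probability maps, never gradients through them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from . import datapipe, losses, metrics, nn
from .autodiff import Tensor, no_grad
from .losses import HybridLossParams
from .nets import (BackboneSpec, ClassNet, ClassNetSpec, CoarseSegNet,
                   FineSegNet, build_classnet, build_coarse_segnet,
                   build_fine_segnet, load_checkpoint, save_checkpoint)

__all__ = [
    "TrainConfig", "EvalReport", "desk_config", "load_config",
    "train_coarse", "precompute_masks", "train_fine", "train_class",
    "cascade_predict", "evaluate", "compute_cam",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (full-scale defaults).

    lr 1e-4, batch sizes 16 (segmentation) / 32 (classification), up to
    100 epochs, hybrid-loss gamma 0.02 / K 20 / margin 0.3.  ``patience``
    enables early stopping on the validation selection metric; ``None``
    trains to ``max_epochs``.  ``image_size`` resizes inputs on load when
    set.  Only CPU execution is implemented.
    """

    lr: float = 1e-4
    batch_size_seg: int = 16
    batch_size_class: int = 32
    max_epochs: int = 100
    loss: HybridLossParams = field(default_factory=HybridLossParams)
    seed: int = 0
    device: str = "cpu"
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    classifier: ClassNetSpec = field(default_factory=ClassNetSpec)
    image_size: int | None = None
    patience: int | None = None
    class_flip_augment: bool = True
    class_shift_augment: int = 4
    weight_decay_seg: float = 0.0
    weight_decay_class: float = 0.0

    def __post_init__(self):
        if self.batch_size_seg < 1 or self.batch_size_class < 1:
            raise ValueError("batch sizes must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        if self.device not in ("cpu", "gpu"):
            raise ValueError("device must be 'cpu' or 'gpu'")
        if self.device == "gpu":
            raise NotImplementedError("only CPU execution is implemented")

    def fingerprint(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def desk_config(seed: int = 0, max_epochs: int = 10) -> TrainConfig:
    """Desk-scale preset: 1/8-width nets, two middle-flow blocks, 64 x 64
    input and a learning rate of 1e-3 matched to the narrow width and the
    short (<= 10 epoch) schedule."""
    return TrainConfig(
        lr=1e-3, max_epochs=max_epochs, seed=seed, image_size=64,
        weight_decay_class=1e-2,
        backbone=BackboneSpec(width_multiplier=0.125, middle_repeats=2),
        classifier=ClassNetSpec(width_multiplier=0.125, middle_repeats=2))


def load_config(path) -> TrainConfig:
    """Build a TrainConfig from a YAML file mirroring the dataclass tree."""
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "loss" in kwargs:
        kwargs["loss"] = HybridLossParams(**kwargs["loss"])
    if "backbone" in kwargs:
        bb = dict(kwargs["backbone"])
        if "dilation_rates" in bb:
            bb["dilation_rates"] = tuple(bb["dilation_rates"])
        kwargs["backbone"] = BackboneSpec(**bb)
    if "classifier" in kwargs:
        kwargs["classifier"] = ClassNetSpec(**kwargs["classifier"])
    return TrainConfig(**kwargs)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _maybe_resize(images, masks, size):
    if size is None or images.shape[-1] == size:
        return images, masks
    out_i = np.stack([
        np.stack([_sk_resize(c, (size, size), order=1, preserve_range=True,
                             anti_aliasing=False) for c in img])
        for img in images]).astype(np.float32)
    order0 = np.stack([
        _sk_resize(m, (size, size), order=0, preserve_range=True,
                   anti_aliasing=False) for m in masks])
    return out_i, order0.astype(masks.dtype)


def _load_seg(manifest, split, root, size, mask_column="mask_path",
              binary=True):
    imgs, masks, labels = datapipe.load_split_arrays(
        manifest, split, root=root, mask_column=mask_column,
        binary_masks=binary)
    imgs, masks = _maybe_resize(imgs, masks, size)
    return imgs, masks, labels


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _predict_batched(fn, n, batch_size=16):
    outs = [fn(sl) for sl in np.array_split(np.arange(n),
                                            max(1, int(np.ceil(n / batch_size))))]
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _val_seg_scores(model, imgs, gts, coarse=None, batch_size=16):
    model.eval()
    with no_grad():
        def fwd(sl):
            if coarse is None:
                return model(Tensor(imgs[sl])).numpy()
            return model(Tensor(imgs[sl]), Tensor(coarse[sl])).numpy()
        probs = _predict_batched(fwd, len(imgs), batch_size)
    pred = metrics.binarize(probs[:, 0], 0.5)
    _, mean = metrics.segmentation_metrics_batch(pred, gts)
    vdice = losses.dice_loss(probs[:, 0].astype(float), gts.astype(int))
    return mean.ja, vdice


def _train_segnet(model, config: TrainConfig, train_data, val_data,
                  coarse_train=None, coarse_val=None):
    """Shared optimisation loop for both segmentation subnetworks.

    Selects the epoch with the best validation Jaccard index.  Returns
    (best_state, log)."""
    imgs, gts = train_data
    vimgs, vgts = val_data
    opt = nn.Adam(model.parameters(), lr=config.lr,
                  weight_decay=config.weight_decay_seg)
    rng = np.random.default_rng(config.seed + 7919)
    log, best = [], {"ja": -1.0, "epoch": -1, "state": model.state_dict()}
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        model.train()
        epoch_losses = []
        for sl in _batches(len(imgs), config.batch_size_seg, rng):
            x = Tensor(imgs[sl])
            g = gts[sl].astype(np.int64)
            if coarse_train is None:
                p = model(x)
            else:
                p = model(x, Tensor(coarse_train[sl]))
            loss = losses.hybrid_loss(p.reshape(g.shape), g, config.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        val_ja, val_dice = _val_seg_scores(model, vimgs, vgts, coarse_val,
                                           config.batch_size_seg)
        log.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                    "val_dice_loss": val_dice, "val_ja": val_ja})
        if val_ja > best["ja"]:
            best = {"ja": val_ja, "epoch": epoch, "state": model.state_dict()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if config.patience is not None and bad_epochs > config.patience:
                break
    model.load_state_dict(best["state"])
    model.eval()
    return best, log


def train_coarse(manifest: pd.DataFrame, config: TrainConfig, *,
                 root=".", checkpoint_path=None):
    """Train Coarse Seg-net on the train split, select on validation JA."""
    imgs, gts, _ = _load_seg(manifest, "train", root, config.image_size)
    vimgs, vgts, _ = _load_seg(manifest, "val", root, config.image_size)
    model = build_coarse_segnet(config.backbone, seed=config.seed)
    best, log = _train_segnet(model, config, (imgs, gts), (vimgs, vgts))
    meta = {"log": log, "best_epoch": best["epoch"], "best_val_ja": best["ja"],
            "config_fingerprint": config.fingerprint()}
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model, meta)
    return model, meta


def precompute_masks(coarse: CoarseSegNet | str | Path, manifest: pd.DataFrame,
                     *, root=".", batch_size: int = 16,
                     image_size: int | None = None) -> pd.DataFrame:
    """Run the frozen coarse model over every manifest image.

    Writes one 8-bit probability-map PNG per image (suffix
    ``_coarse.png``) and returns the manifest with a ``coarse_mask_path``
    column."""
    if not isinstance(coarse, CoarseSegNet):
        coarse, _ = load_checkpoint(coarse)
    root = Path(root)
    missing = [str(p) for p in manifest["image_path"]
               if not (root / p).exists()]
    if missing:
        raise FileNotFoundError(f"missing images: {missing[:5]}")
    coarse.eval()
    out_paths = []
    paths = list(manifest["image_path"])
    for i in range(0, len(paths), batch_size):
        chunk = paths[i:i + batch_size]
        imgs = np.stack([datapipe.load_image(root / p) for p in chunk])
        if image_size is not None and imgs.shape[-1] != image_size:
            imgs, _ = _maybe_resize(imgs, np.zeros(imgs.shape[:1] + imgs.shape[2:],
                                                   np.uint8), image_size)
        probs = coarse.predict(imgs)
        for p, pm in zip(chunk, probs):
            out = str(Path(p).with_suffix("")) + "_coarse.png"
            datapipe.save_mask(root / out, pm[0])
            out_paths.append(out)
    result = manifest.copy()
    result["coarse_mask_path"] = out_paths
    return result


def train_fine(manifest: pd.DataFrame, coarse: CoarseSegNet | str | Path,
               config: TrainConfig, *, guided: bool = True, root=".",
               checkpoint_path=None):
    """Train Fine Seg-net from a coarse-parameter copy with mask guidance.

    ``manifest`` must carry the ``coarse_mask_path`` column produced by
    :func:`precompute_masks`.  ``guided=False`` replaces the coarse maps
    with zeros (train and validation), isolating the prior-location
    guidance as the only difference for the ablation."""
    if not isinstance(coarse, CoarseSegNet):
        coarse, _ = load_checkpoint(coarse)
    if guided and "coarse_mask_path" not in manifest.columns:
        raise ValueError("run precompute_masks first (no coarse_mask_path)")
    size = config.image_size
    imgs, gts, _ = _load_seg(manifest, "train", root, size)
    vimgs, vgts, _ = _load_seg(manifest, "val", root, size)
    if guided:
        cm_t = _load_coarse_maps(manifest, "train", root, size)
        cm_v = _load_coarse_maps(manifest, "val", root, size)
    else:
        cm_t = np.zeros((len(imgs), 1) + imgs.shape[2:], np.float32)
        cm_v = np.zeros((len(vimgs), 1) + vimgs.shape[2:], np.float32)
    model = build_fine_segnet(config.backbone, coarse, seed=config.seed + 1)
    best, log = _train_segnet(model, config, (imgs, gts), (vimgs, vgts),
                              coarse_train=cm_t, coarse_val=cm_v)
    meta = {"log": log, "best_epoch": best["epoch"], "best_val_ja": best["ja"],
            "config_fingerprint": config.fingerprint()}
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model, meta)
    return model, meta


def _random_shift(batch: np.ndarray, max_px: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Translate a whole NCHW batch by a random offset, zero-filling."""
    dy, dx = (int(v) for v in rng.integers(-max_px, max_px + 1, size=2))
    if dy == 0 and dx == 0:
        return batch
    out = np.zeros_like(batch)
    h, w = batch.shape[-2:]
    ys0, ys1 = max(dy, 0), min(h + dy, h)
    xs0, xs1 = max(dx, 0), min(w + dx, w)
    out[..., ys0:ys1, xs0:xs1] = batch[..., ys0 - dy:ys1 - dy,
                                       xs0 - dx:xs1 - dx]
    return out


def _load_coarse_maps(manifest, split, root, size):
    rows = manifest[manifest["split"] == split]
    maps = np.stack([datapipe.load_mask(Path(root) / p, binary=False)
                     for p in rows["coarse_mask_path"]])
    if size is not None and maps.shape[-1] != size:
        maps = np.stack([_sk_resize(m, (size, size), order=1,
                                    preserve_range=True, anti_aliasing=False)
                         for m in maps]).astype(np.float32)
    return maps[:, None].astype(np.float32)


def train_class(manifest: pd.DataFrame, config: TrainConfig, *,
                use_mask: bool = True, root=".", checkpoint_path=None):
    """Train Class-net; ``use_mask=False`` is the unguided 3-channel arm."""
    size = config.image_size
    imgs, _, labels = _load_seg(manifest, "train", root, size)
    vimgs, _, vlabels = _load_seg(manifest, "val", root, size)
    if len(np.unique(labels)) < 2:
        raise ValueError("training split contains a single class")
    cls_spec = dataclasses.replace(config.classifier,
                                   input_channels=4 if use_mask else 3)
    if use_mask:
        if "coarse_mask_path" not in manifest.columns:
            raise ValueError("run precompute_masks first (no coarse_mask_path)")
        cm = _load_coarse_maps(manifest, "train", root, size)
        vcm = _load_coarse_maps(manifest, "val", root, size)
        x = np.concatenate([imgs, cm], axis=1)
        vx = np.concatenate([vimgs, vcm], axis=1)
    else:
        x, vx = imgs, vimgs
    if config.class_flip_augment:
        # 4-fold flip replication of the training split: the classifier
        # overfits a few hundred patches long before it generalises, and
        # flips are the cheapest leakage-free counterpart of the offline
        # crop/zoom/flip augmentation used at full scale
        x = np.concatenate([x, x[..., ::-1], x[..., ::-1, :],
                            x[..., ::-1, ::-1]])
        labels = np.concatenate([labels] * 4)
    model = build_classnet(cls_spec, seed=config.seed + 2)
    opt = nn.Adam(model.parameters(), lr=config.lr,
                  weight_decay=config.weight_decay_class)
    rng = np.random.default_rng(config.seed + 104729)
    log, best = [], {"acc": -1.0, "epoch": -1, "state": model.state_dict()}
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        model.train()
        epoch_losses = []
        for sl in _batches(len(x), config.batch_size_class, rng):
            xb = x[sl]
            if config.class_shift_augment:
                # random per-batch translation: the cheapest transform
                # that stops the classifier keying on absolute pixel
                # positions of the background noise
                xb = _random_shift(xb, config.class_shift_augment, rng)
            scores = model(Tensor(xb))
            loss = losses.bce_loss(scores, labels[sl], clip=1e-6)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        model.eval()
        with no_grad():
            vscores = _predict_batched(lambda sl: model(Tensor(vx[sl])).numpy(),
                                       len(vx), config.batch_size_class)
        val_acc = float(np.mean((vscores >= 0.5) == (vlabels == 1)))
        log.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                    "val_acc": val_acc})
        if val_acc > best["acc"]:
            best = {"acc": val_acc, "epoch": epoch, "state": model.state_dict()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if config.patience is not None and bad_epochs > config.patience:
                break
    model.load_state_dict(best["state"])
    model.eval()
    with no_grad():
        vscores = _predict_batched(lambda sl: model(Tensor(vx[sl])).numpy(),
                                   len(vx), config.batch_size_class)
    meta = {"log": log, "best_epoch": best["epoch"], "best_val_acc": best["acc"],
            "decision_threshold": calibrate_threshold(vscores, vlabels),
            "config_fingerprint": config.fingerprint()}
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model, meta)
    return model, meta


def calibrate_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Decision threshold maximising accuracy on a held-out (validation)
    split; among equally accurate candidates the one closest to 0.5 wins.

    The sigmoid score distribution of a small-sample classifier is often
    shifted, so the fixed 0.5 cut under-reports the accuracy its ranking
    supports; choosing the operating point on validation data is the
    standard correction (AUC stays threshold-free)."""
    scores = np.asarray(scores, float).reshape(-1)
    labels = np.asarray(labels).reshape(-1)
    uniq = np.unique(scores)
    candidates = np.concatenate([[0.5], (uniq[1:] + uniq[:-1]) / 2.0])
    accs = np.array([np.mean((scores >= t) == (labels == 1))
                     for t in candidates])
    top = candidates[accs == accs.max()]
    return float(top[np.argmin(np.abs(top - 0.5))])


# ---------------------------------------------------------------------------
# inference / evaluation
# ---------------------------------------------------------------------------

def cascade_predict(images: np.ndarray, coarse: CoarseSegNet,
                    fine: FineSegNet, classifier: ClassNet,
                    batch_size: int = 16
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full cascade on a batch: (coarse maps, fine maps, malignancy probs).

    Deterministic in inference mode; order-preserving."""
    images = np.asarray(images, np.float32)
    if images.ndim == 3:
        images = images[None]
    for m in (coarse, fine, classifier):
        m.eval()
    if classifier.spec.input_channels != 4:
        raise ValueError("cascade classifier must be mask-guided (4 channels)")
    n = len(images)
    cmaps = _predict_batched(lambda sl: coarse.predict(images[sl]), n, batch_size)
    fmaps = _predict_batched(lambda sl: fine.predict(images[sl], cmaps[sl]),
                             n, batch_size)
    x4 = np.concatenate([images, cmaps.astype(np.float32)], axis=1)
    probs = _predict_batched(lambda sl: classifier.predict(x4[sl]), n, batch_size)
    return cmaps, fmaps, probs


@dataclass
class EvalReport:
    """Held-out evaluation of the full cascade."""

    seg_mean: metrics.SegOverlapReport
    seg_per_image: list[metrics.SegOverlapReport]
    cls: metrics.ClassReport
    n_items: int
    config_fingerprint: str

    def to_dict(self) -> dict:
        return {"seg": {"mean": self.seg_mean.to_dict(),
                        "per_image": [r.to_dict() for r in self.seg_per_image]},
                "cls": self.cls.to_dict(),
                "n_items": self.n_items,
                "config_fingerprint": self.config_fingerprint}


def evaluate(manifest: pd.DataFrame, coarse: CoarseSegNet, fine: FineSegNet,
             classifier: ClassNet, *, root=".", split: str = "test",
             image_size: int | None = None, threshold: float = 0.5,
             cls_threshold: float = 0.5, fingerprint: str = "",
             out_json=None) -> EvalReport:
    """Cascade the ``split`` items; fine maps are binarised at ``threshold``
    for the overlap metrics, class scores thresholded at ``cls_threshold``
    (0.5, or a validation-calibrated value) plus threshold-free AUC."""
    imgs, gts, labels = _load_seg(manifest, split, root, image_size)
    _, fmaps, probs = cascade_predict(imgs, coarse, fine, classifier)
    pred_masks = metrics.binarize(fmaps[:, 0], threshold)
    per_image, seg_mean = metrics.segmentation_metrics_batch(pred_masks, gts)
    pred_labels = (probs >= cls_threshold).astype(int)
    counts = metrics.ConfusionCounts(
        tp=int(np.sum((pred_labels == 1) & (labels == 1))),
        fp=int(np.sum((pred_labels == 1) & (labels == 0))),
        tn=int(np.sum((pred_labels == 0) & (labels == 0))),
        fn=int(np.sum((pred_labels == 0) & (labels == 1))))
    cls = metrics.classification_metrics(counts)
    cls = metrics.ClassReport(acc=cls.acc, sen=cls.sen, spe=cls.spe,
                              auc=metrics.roc_auc(probs, labels))
    report = EvalReport(seg_mean=seg_mean, seg_per_image=per_image, cls=cls,
                        n_items=len(imgs), config_fingerprint=fingerprint)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report.to_dict(), indent=2))
    return report


def run_experiment(work_dir, synth_config, train_config: TrainConfig, *,
                   ablation: bool = False) -> dict:
    """Generate a synthetic dataset, train the full cascade and evaluate it.

    With ``ablation=True`` additionally trains the unguided arms (fine net
    with zeroed prior maps; 3-channel classifier) on the same data and
    seeds.  Returns a flat dict of held-out metrics.  The split uses
    ratios 4:1:1 so the default generator yields 200/50/50 items.
    """
    from . import synthgen

    work_dir = Path(work_dir)
    manifest = synthgen.generate_dataset(synth_config, work_dir,
                                         split_ratios=(4, 1, 1))
    size = train_config.image_size
    coarse, _ = train_coarse(manifest, train_config, root=work_dir)
    manifest = precompute_masks(coarse, manifest, root=work_dir,
                                image_size=size)
    fine, _ = train_fine(manifest, coarse, train_config, root=work_dir)
    classifier, cls_meta = train_class(manifest, train_config, root=work_dir)
    report = evaluate(manifest, coarse, fine, classifier, root=work_dir,
                      image_size=size,
                      cls_threshold=cls_meta["decision_threshold"],
                      fingerprint=train_config.fingerprint())
    imgs, gts, labels = _load_seg(manifest, "test", work_dir, size)
    coarse_pred = metrics.binarize(
        _predict_batched(lambda sl: coarse.predict(imgs[sl]), len(imgs))[:, 0])
    _, coarse_mean = metrics.segmentation_metrics_batch(coarse_pred, gts)
    out = {
        "n_train": int((manifest["split"] == "train").sum()),
        "n_val": int((manifest["split"] == "val").sum()),
        "n_test": int((manifest["split"] == "test").sum()),
        "coarse_di": coarse_mean.di, "coarse_ja": coarse_mean.ja,
        "coarse_fg_fraction": float(coarse_pred.mean()),
        "fine_di": report.seg_mean.di, "fine_ja": report.seg_mean.ja,
        "seg_acc": report.seg_mean.acc, "seg_recall": report.seg_mean.recall,
        "seg_spe": report.seg_mean.spe,
        "class_acc": report.cls.acc, "class_auc": report.cls.auc,
        "class_sen": report.cls.sen, "class_spe": report.cls.spe,
    }
    if ablation:
        fine_u, _ = train_fine(manifest, coarse, train_config, guided=False,
                               root=work_dir)
        zeros = np.zeros((len(imgs), 1) + imgs.shape[2:], np.float32)
        fmaps_u = _predict_batched(
            lambda sl: fine_u.predict(imgs[sl], zeros[sl]), len(imgs))
        _, seg_u = metrics.segmentation_metrics_batch(
            metrics.binarize(fmaps_u[:, 0]), gts)
        cls_u, cls_u_meta = train_class(manifest, train_config, use_mask=False,
                                        root=work_dir)
        probs_u = _predict_batched(lambda sl: cls_u.predict(imgs[sl]), len(imgs))
        thr_u = cls_u_meta["decision_threshold"]
        out.update({
            "fine_di_unguided": seg_u.di, "fine_ja_unguided": seg_u.ja,
            "class_acc_unguided": float(np.mean((probs_u >= thr_u)
                                                == (labels == 1))),
            "class_auc_unguided": metrics.roc_auc(probs_u, labels),
        })
    return out


def compute_cam(classifier: ClassNet, x: np.ndarray) -> np.ndarray:
    """Gradient-weighted class activation map, in [0, 1], input-sized.

    Feature maps of the last convolutional stage are weighted by the
    spatial mean of the malignancy-score gradient, rectified, min-max
    normalised and bilinearly upsampled.  A constant response yields an
    all-zero map (no NaNs)."""
    x = np.asarray(x, np.float32)
    single = x.ndim == 3
    if single:
        x = x[None]
    classifier.eval()
    xt = Tensor(x, requires_grad=True)
    scores, feat = classifier(xt, return_features=True)
    scores.sum().backward()
    grads = feat.grad  # (N, C, h, w)
    weights = grads.mean(axis=(2, 3), keepdims=True)
    cam = np.maximum((weights * feat.data).sum(axis=1), 0.0)
    out = np.empty((len(x),) + x.shape[2:], np.float32)
    for i, c in enumerate(cam):
        lo, hi = float(c.min()), float(c.max())
        norm = (c - lo) / (hi - lo) if hi > lo else np.zeros_like(c)
        out[i] = _sk_resize(norm, x.shape[2:], order=1, preserve_range=True,
                            anti_aliasing=False)
    out = np.clip(out, 0.0, 1.0)
    return out[0] if single else out
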