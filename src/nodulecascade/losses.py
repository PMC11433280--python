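"""Training losses for the segmentation and classification subnetworks.

The segmentation subnetworks are optimised with a *hybrid loss*

    L_seg = L_Dice + gamma * L_Rank

combining the overlap-oriented Dice loss with a pairwise *rank loss* that
performs online hard-pixel mining: after each forward pass the background
pixels and the nodule (foreground) pixels of every image are ranked
separately by prediction error, the ``K`` worst offenders of each region
are kept, and a hinge penalty forces every selected foreground probability
to exceed every selected background probability by at least ``margin``:

    L_Rank = (1 / (K0 * K1)) * sum_i sum_j max(0, H_i^0 - H_j^1 + margin)

where ``H^0`` are the selected background probabilities (error = P, target
is 0), ``H^1`` the selected foreground probabilities (error = 1 - P), and
``K0, K1 <= K`` the effective region sizes after truncation.  Regions with
fewer than ``K`` pixels contribute all of them and the normalisation uses
the actual ``K0 * K1``.  An image with an empty foreground or background
contributes a rank loss of exactly 0.  Selection is a hard choice carrying
no gradient; gradients flow only through the selected probabilities.

The classification subnetwork uses plain binary cross-entropy.

All public functions are polymorphic: given numpy arrays they validate
their inputs and return floats; given autodiff :class:`~nodulecascade.autodiff.Tensor`
predictions they return a ``Tensor`` suitable for ``backward()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

__all__ = [
    "HybridLossParams",
    "HardPixelSet",
    "dice_loss",
    "select_hard_pixels",
    "rank_loss",
    "hybrid_loss",
    "bce_loss",
]


@dataclass(frozen=True)
class HybridLossParams:
    """Hyper-parameters of the hybrid segmentation loss.

    gamma
        Mixing weight of the rank term (>= 0).  Default 0.02.
    k
        Number of hard pixels selected per region per image (>= 1).
        Default 20.
    margin
        Required gap between selected foreground and background
        probabilities, in [0, 1).  Default 0.3.
    epsilon
        Dice smoothing constant (> 0).  Default 1e-6.
    """

    gamma: float = 0.02
    k: int = 20
    margin: float = 0.3
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 <= self.margin < 1:
            raise ValueError("margin must be in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class HardPixelSet:
    """Hard pixels of one image, sorted by descending prediction error."""

    background_probs: np.ndarray = field(default_factory=lambda: np.empty(0))
    foreground_probs: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# shape / value plumbing
# ---------------------------------------------------------------------------

def _flatten_pair(p_data: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Normalise (H,W) | (N,H,W) | (N,1,H,W) masks to (N, H*W)."""
    g = np.asarray(g)
    if p_data.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p_data.shape} vs mask {g.shape}")
    if g.ndim in (1, 2):
        g = g[None]  # single image (flat or H x W)
    elif g.ndim == 4 and g.shape[1] == 1:
        g = g[:, 0]
    elif g.ndim != 3:
        raise ValueError(f"expected 1-4 dims, got {g.ndim}")
    return g.reshape(g.shape[0], -1), g.shape


def _validate_probs(p: np.ndarray) -> None:
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("probability map has values outside [0, 1]")


def _validate_binary(g: np.ndarray) -> None:
    if not np.isin(g, (0, 1)).all():
        raise ValueError("mask is not binary")


def _reshape_like(t: Tensor, flat_shape0: int) -> Tensor:
    return t.reshape(flat_shape0, -1)


# ---------------------------------------------------------------------------
# Dice loss
# ---------------------------------------------------------------------------

def dice_loss(p, g, epsilon: float = 1e-6):
    """Soft Dice loss ``1 - 2*sum(P*G) / (sum(P + G) + eps)``.

    Computed per image and averaged over the batch.  ``p`` may be a numpy
    array (returns float) or a ``Tensor`` (returns a differentiable
    ``Tensor``).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if isinstance(p, Tensor):
        gf, _ = _flatten_pair(np.asarray(p.data), g)
        _validate_binary(gf)
        n = gf.shape[0]
        pf = _reshape_like(p, n)
        gt = Tensor(gf.astype(p.data.dtype))
        inter = (pf * gt).sum(axis=1)
        denom = (pf + gt).sum(axis=1) + epsilon
        return (1.0 - (2.0 * inter) / denom).mean()
    p = np.asarray(p, dtype=float)
    gf, _ = _flatten_pair(p, g)
    _validate_probs(p)
    _validate_binary(gf)
    pf = p.reshape(gf.shape)
    inter = (pf * gf).sum(axis=1)
    denom = (pf + gf).sum(axis=1) + epsilon
    return float(np.mean(1.0 - 2.0 * inter / denom))


# ---------------------------------------------------------------------------
# rank loss
# ---------------------------------------------------------------------------

def _hard_indices(p_flat: np.ndarray, g_flat: np.ndarray, k: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Flat indices of the <=k hardest background / foreground pixels.

    Hardness is |P - G|: for background pixels the error is P, for
    foreground pixels 1 - P.  Ties are broken by row-major scan order
    (stable sort on the flattened image).
    """
    bg = np.flatnonzero(g_flat == 0)
    fg = np.flatnonzero(g_flat == 1)
    # stable argsort on -error keeps scan order among ties
    bg_sorted = bg[np.argsort(-p_flat[bg], kind="stable")][:k]
    fg_sorted = fg[np.argsort(p_flat[fg], kind="stable")][:k]
    return bg_sorted, fg_sorted


def select_hard_pixels(p, g, k: int) -> HardPixelSet:
    """Select the ``k`` highest-error pixels of each region of one image.

    Returns the selected probabilities sorted by descending error
    (background: descending P; foreground: ascending P).  Regions smaller
    than ``k`` return all their pixels; an absent region yields an empty
    list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    p = np.asarray(getattr(p, "data", p), dtype=float).reshape(-1)
    g = np.asarray(g).reshape(-1)
    if p.shape != g.shape:
        raise ValueError("shape mismatch between prediction and mask")
    _validate_probs(p)
    _validate_binary(g)
    bg_idx, fg_idx = _hard_indices(p, g, k)
    return HardPixelSet(background_probs=p[bg_idx], foreground_probs=p[fg_idx])


def rank_loss(p, g, k: int = 20, margin: float = 0.3):
    """Pairwise hinge over the hard-pixel sets, averaged over the batch.

    For each image, with selected background probabilities ``H^0`` (size
    K0) and foreground probabilities ``H^1`` (size K1):

        (1/(K0*K1)) * sum_{i,j} max(0, H_i^0 - H_j^1 + margin)

    Returns 0 for images where either region is empty.  Value lies in
    ``[0, 1 + margin]``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= margin < 1:
        raise ValueError("margin must be in [0, 1)")
    tensor_mode = isinstance(p, Tensor)
    p_data = np.asarray(p.data if tensor_mode else p, dtype=float)
    gf, _ = _flatten_pair(p_data, g)
    _validate_binary(gf)
    if not tensor_mode:
        _validate_probs(p_data)
    n = gf.shape[0]
    pf_data = p_data.reshape(n, -1)
    if tensor_mode:
        p_flat_t = _reshape_like(p, n)

    per_image = []
    for i in range(n):
        bg_idx, fg_idx = _hard_indices(pf_data[i], gf[i], k)
        k0, k1 = len(bg_idx), len(fg_idx)
        if k0 == 0 or k1 == 0:
            per_image.append(Tensor(np.zeros(())) if tensor_mode else 0.0)
            continue
        if tensor_mode:
            row = p_flat_t[i]
            h0 = row[bg_idx].reshape(k0, 1)
            h1 = row[fg_idx].reshape(1, k1)
            hinge = (h0 - h1 + margin).maximum(0.0)
            per_image.append(hinge.sum() * (1.0 / (k0 * k1)))
        else:
            h0 = pf_data[i][bg_idx][:, None]
            h1 = pf_data[i][fg_idx][None, :]
            per_image.append(float(np.maximum(0.0, h0 - h1 + margin).sum()
                                   / (k0 * k1)))
    if tensor_mode:
        total = per_image[0]
        for t in per_image[1:]:
            total = total + t
        return total * (1.0 / n)
    return float(np.mean(per_image))


def hybrid_loss(p, g, params: HybridLossParams = HybridLossParams()):
    """Dice + gamma * rank.  With ``gamma = 0`` this is exactly the Dice loss."""
    d = dice_loss(p, g, params.epsilon)
    if params.gamma == 0.0:
        return d
    return d + params.gamma * rank_loss(p, g, params.k, params.margin)


# ---------------------------------------------------------------------------
# classification loss
# ---------------------------------------------------------------------------

def bce_loss(scores, labels, clip: float | None = None):
    """Mean binary cross-entropy ``-[y log s + (1-y) log(1-s)]``.

    ``clip`` (Tensor mode only) squeezes scores into
    ``[clip, 1 - clip]`` by an affine map for numerical safety during
    training; the numpy path computes the textbook value exactly.
    """
    y = np.asarray(labels, dtype=float).reshape(-1)
    if y.size == 0:
        raise ValueError("empty input")
    _validate_binary(y)
    if isinstance(scores, Tensor):
        s = scores.reshape(-1)
        if s.data.shape != y.shape:
            raise ValueError("scores/labels length mismatch")
        if clip:
            s = s * (1.0 - 2.0 * clip) + clip
        yt = Tensor(y)
        ll = yt * s.log() + (1.0 - yt) * (1.0 - s).log()
        return -ll.mean()
    s = np.asarray(scores, dtype=float).reshape(-1)
    if s.shape != y.shape:
        raise ValueError("scores/labels length mismatch")
    if s.size and (s.min() <= 0.0 or s.max() >= 1.0):
        raise ValueError("scores must lie strictly inside (0, 1)")
    return float(-np.mean(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)))
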