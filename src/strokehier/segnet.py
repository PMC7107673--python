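"""Encoder–decoder fully convolutional network for hyperdense-MCA-sign
segmentation, reused as a per-patient deep feature extractor.

The architecture is U-Net-like: an encoder of stride-1 3x3 convolutions
(ReLU, 'same' padding) with 2x2 max pooling between scales and channel
doubling, a bottleneck block whose activation maps feed a global-max-pooling
feature head, and a decoder of nearest-neighbour upsampling plus convolutions
with skip connections from the matching encoder scale. At the default
full-scale configuration (128x128 input, depth 5, base 32) the bottleneck
holds 1024 maps of 4x4, so the feature head emits 1024 values per input.

Training uses the Tversky loss — an asymmetric overlap loss generalising Dice
with separate false-positive (alpha) and false-negative (beta) weights — and
per-batch hard-negative mining that keeps every lesion-positive patch but only
the highest-loss negatives, to counter the extreme foreground/background
imbalance of small intravascular lesions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nn import (Adam, Conv2D, maxpool2, maxpool2_backward, relu, relu_backward,
                  sigmoid, upsample2, upsample2_backward)
from .preprocess import ROIStack

__all__ = [
    "SegNetConfig",
    "SegTrainConfig",
    "DeepFeatures",
    "SegNet",
    "build_network",
    "tversky_loss",
    "tversky_loss_grad",
    "mine_hard_negatives",
    "train_segmenter",
    "select_representative_slice",
    "extract_features",
    "center_crop",
    "dice_score",
    "TINY_PROFILE",
    "PAPER_PROFILE",
]


@dataclass
class SegNetConfig:
    """Architecture hyperparameters.

    ``bottleneck_channels`` defaults to ``base_channels * 2**depth``, which at
    the full-scale profile (depth 5, base 32) is 1024; intermediate encoder
    stages double from ``base_channels``. The bottleneck spatial size is
    ``input_size / 2**depth`` (4x4 at both shipped profiles).
    """

    input_size: int = 128
    depth: int = 5
    base_channels: int = 32
    bottleneck_channels: int | None = None
    in_channels: int = 1
    head_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}"
            )
        if self.bottleneck_channels is None:
            self.bottleneck_channels = self.base_channels * 2**self.depth

    @property
    def bottleneck_size(self) -> int:
        return self.input_size // 2**self.depth

    def fingerprint(self) -> str:
        return (f"in{self.input_size}-d{self.depth}-b{self.base_channels}"
                f"-bn{self.bottleneck_channels}-c{self.in_channels}")


# shipped profiles: full-scale mirrors the study architecture; tiny is the
# desk/CI configuration (64x64 centre-crop input)
PAPER_PROFILE = dict(input_size=128, depth=5, base_channels=32)
TINY_PROFILE = dict(input_size=64, depth=4, base_channels=8)


@dataclass
class SegTrainConfig:
    """Optimisation settings. The study-scale defaults are Adam at 1e-5
    (first-moment decay 0.9), 200 epochs, batch 16; desk-scale runs override
    the learning rate and epoch count."""

    learning_rate: float = 1e-5
    beta1: float = 0.9
    epochs: int = 200
    batch_size: int = 16
    tversky_alpha: float = 0.3
    tversky_beta: float = 0.7
    # smoothing must stay small: a large constant flattens the loss for
    # lesion-positive patches while keeping a constant false-positive push on
    # empty patches, which drives the output to zero everywhere
    smooth: float = 1e-6
    hard_negative_ratio: int = 3
    # global gradient-norm clip; overlap losses produce occasional spikes
    # that can destroy an already-converged net late in training
    grad_clip: float = 5.0
    # return the weights of the epoch with the best training-positive Dice
    # rather than the last one. The mined Tversky loss itself cannot arbitrate
    # this: with small smoothing an all-zero (collapsed) output scores empty
    # patches as perfect and can undercut a genuinely segmenting net
    keep_best: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.tversky_alpha <= 0 or self.tversky_beta <= 0:
            raise ValueError("tversky weights must be positive")


@dataclass
class DeepFeatures:
    """Per-patient pooled bottleneck feature vector."""

    patient_id: str
    values: np.ndarray
    source_slice: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


class SegNet:
    """The network. Build via :func:`build_network`; input scaling (division
    by the window ceiling) is the caller's responsibility — training and
    extraction helpers in this module handle it."""

    def __init__(self, config: SegNetConfig, rng: np.random.Generator,
                 dtype=np.float32):
        self.config = config
        self.dtype = dtype
        d, base = config.depth, config.base_channels
        chans = [base * 2**i for i in range(d)]
        bn = config.bottleneck_channels
        self.enc = []
        cin = config.in_channels
        for c in chans:
            self.enc.append(Conv2D(cin, c, 3, rng, dtype))
            cin = c
        self.bott1 = Conv2D(chans[-1], bn, 3, rng, dtype)
        self.bott2 = Conv2D(bn, bn, 3, rng, dtype)
        self.up_convs = []
        self.merge_convs = []
        prev = bn
        for i in reversed(range(d)):
            self.up_convs.append(Conv2D(prev, chans[i], 3, rng, dtype))
            self.merge_convs.append(Conv2D(2 * chans[i], chans[i], 3, rng, dtype))
            prev = chans[i]
        self.head = Conv2D(chans[0], 1, 1, rng, dtype)
        self.head.b[:] = config.head_bias
        self.trained = False
        self.loss_history: list[float] = []
        self._tape: dict | None = None

    # -- forward / backward -------------------------------------------------

    def layers(self) -> list[Conv2D]:
        return self.enc + [self.bott1, self.bott2] + self.up_convs + self.merge_convs + [self.head]

    def forward(self, x: np.ndarray, keep_tape: bool = False) -> np.ndarray:
        """x: (N, 1, H, W) scaled to ~[0, 1]. Returns per-pixel probabilities."""
        cfg = self.config
        if x.shape[2] != cfg.input_size or x.shape[3] != cfg.input_size:
            raise ValueError(f"expected {cfg.input_size}x{cfg.input_size} input, got {x.shape[2:]}")
        tape: dict = {"skip_masks": [], "pool": [], "up_in_shapes": [],
                      "up_masks": [], "merge_masks": [], "skip_chans": []}
        h = x.astype(self.dtype, copy=False)
        skips = []
        for conv in self.enc:
            h, m = relu(conv.forward(h))
            tape["skip_masks"].append(m)
            skips.append(h)
            shape = h.shape
            h, idx = maxpool2(h)
            tape["pool"].append((idx, shape))
        h, m1 = relu(self.bott1.forward(h))
        tape["bott1_mask"] = m1
        h, m2 = relu(self.bott2.forward(h))
        tape["bott2_mask"] = m2
        self._features = h.max(axis=(2, 3))  # global max pool over each map
        d = cfg.depth
        for j, i in enumerate(reversed(range(d))):
            tape["up_in_shapes"].append(h.shape)
            h = upsample2(h)
            h, m = relu(self.up_convs[j].forward(h))
            tape["up_masks"].append(m)
            tape["skip_chans"].append(h.shape[1])
            h = np.concatenate([h, skips[i]], axis=1)
            h, m = relu(self.merge_convs[j].forward(h))
            tape["merge_masks"].append(m)
        # clip logits so float32 sigmoid never saturates to an exact 0/1,
        # which would zero the gradient irrecoverably
        logits = np.clip(self.head.forward(h), -25.0, 25.0)
        probs = sigmoid(logits)
        if keep_tape:
            tape["probs"] = probs
            self._tape = tape
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dprobs; requires the
        preceding forward(..., keep_tape=True)."""
        tape = self._tape
        if tape is None:
            raise RuntimeError("backward() requires forward(keep_tape=True) first")
        p = tape["probs"]
        g = (dprobs * p * (1.0 - p)).astype(self.dtype, copy=False)  # sigmoid backward
        g = self.head.backward(g)
        d = self.config.depth
        dskips: list[np.ndarray | None] = [None] * d
        for j in range(d - 1, -1, -1):
            i = d - 1 - j  # encoder scale matched by decoder step j
            g = relu_backward(g, tape["merge_masks"][j])
            g = self.merge_convs[j].backward(g)
            nch = tape["skip_chans"][j]
            g_up, g_skip = g[:, :nch], g[:, nch:]
            dskips[i] = g_skip
            g_up = relu_backward(g_up, tape["up_masks"][j])
            g_up = self.up_convs[j].backward(g_up)
            g = upsample2_backward(g_up)
        g = relu_backward(g, tape["bott2_mask"])
        g = self.bott2.backward(g)
        g = relu_backward(g, tape["bott1_mask"])
        g = self.bott1.backward(g)
        for i in range(d - 1, -1, -1):
            idx, shape = tape["pool"][i]
            g = maxpool2_backward(g, idx, shape)
            g = g + dskips[i]
            g = relu_backward(g, tape["skip_masks"][i])
            g = self.enc[i].backward(g)
        self._tape = None

    def features(self, x: np.ndarray) -> np.ndarray:
        """Global-max-pooled bottleneck vector(s), shape (N, bottleneck_channels)."""
        self.forward(x)
        return self._features.copy()


def build_network(config: SegNetConfig | None = None, seed: int = 0,
                  dtype=np.float32) -> SegNet:
    """Construct a network with He-normal initial weights."""
    config = config or SegNetConfig()
    return SegNet(config, np.random.default_rng([seed, 0x5e9]), dtype)


# ---------------------------------------------------------------------------
# Loss and mining
# ---------------------------------------------------------------------------

def _tversky_terms(pred: np.ndarray, truth: np.ndarray):
    axes = tuple(range(1, pred.ndim))
    tp = (pred * truth).sum(axis=axes)
    fp = (pred * (1.0 - truth)).sum(axis=axes)
    fn = ((1.0 - pred) * truth).sum(axis=axes)
    return tp, fp, fn


def tversky_loss(pred: np.ndarray, truth: np.ndarray, alpha: float = 0.3,
                 beta: float = 0.7, eps: float = 1e-6) -> np.ndarray | float:
    """1 - Tversky index with soft (probabilistic) counts.

    TI = (TP + eps) / (TP + alpha*FP + beta*FN + eps). alpha = beta = 0.5
    recovers the soft Dice loss. Accepts a single map or a batch (leading
    axis); batches return a per-sample vector.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    single = pred.ndim == 2
    if single:
        pred, truth = pred[None], truth[None]
    tp, fp, fn = _tversky_terms(pred, truth)
    ti = (tp + eps) / (tp + alpha * fp + beta * fn + eps)
    loss = 1.0 - ti
    return float(loss[0]) if single else loss


def tversky_loss_grad(pred: np.ndarray, truth: np.ndarray, alpha: float = 0.3,
                      beta: float = 0.7, eps: float = 1e-6) -> np.ndarray:
    """dLoss/dpred for a batch, per-sample losses unreduced."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    tp, fp, fn = _tversky_terms(pred, truth)
    num = tp + eps
    den = tp + alpha * fp + beta * fn + eps
    shape = (-1,) + (1,) * (pred.ndim - 1)
    num, den = num.reshape(shape), den.reshape(shape)
    # dTP/dp = t, dFP/dp = 1-t, dFN/dp = -t
    dden = truth + alpha * (1.0 - truth) - beta * truth
    dti = (truth * den - num * dden) / (den * den)
    return -dti


def mine_hard_negatives(losses: np.ndarray, is_positive: np.ndarray,
                        ratio: int = 3) -> np.ndarray:
    """Boolean keep-mask: all positive patches, plus the ``ratio x n_pos``
    hardest (highest-loss) negatives — all of them if fewer exist. A batch
    with no positives keeps its single hardest negative so a training step
    always has data."""
    losses = np.asarray(losses, dtype=np.float64)
    is_positive = np.asarray(is_positive, dtype=bool)
    keep = is_positive.copy()
    neg_idx = np.flatnonzero(~is_positive)
    n_keep = ratio * int(is_positive.sum())
    if is_positive.sum() == 0 and neg_idx.size:
        n_keep = 1
    if neg_idx.size and n_keep > 0:
        order = neg_idx[np.argsort(-losses[neg_idx], kind="stable")]
        keep[order[:n_keep]] = True
    return keep


def _clip_gradients(net: SegNet, max_norm: float) -> None:
    total = 0.0
    for layer in net.layers():
        for _, g in layer.params_and_grads():
            total += float((g * g).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / norm
        for layer in net.layers():
            for _, g in layer.params_and_grads():
                g *= scale


def center_crop(patch: np.ndarray, size: int) -> np.ndarray:
    """Centre crop a 2-D patch to size x size (used by the tiny profile)."""
    r, c = patch.shape
    r0, c0 = (r - size) // 2, (c - size) // 2
    return patch[r0:r0 + size, c0:c0 + size]


def _prepare(patches: np.ndarray, config: SegNetConfig, scale: float) -> np.ndarray:
    out = np.stack([center_crop(np.asarray(p, dtype=np.float64), config.input_size)
                    for p in patches])
    return out[:, None] / scale


def train_segmenter(
    patches,
    masks,
    net_config: SegNetConfig | None = None,
    train_config: SegTrainConfig | None = None,
    intensity_scale: float = 80.0,
    max_restarts: int = 6,
    min_train_dice: float = 0.5,
) -> SegNet:
    """Train a segmenter on (patch, mask) pairs.

    Patches larger than the network input are centre-cropped; intensities are
    scaled by the window ceiling. Refuses to train without at least one
    lesion-positive mask. Deterministic given ``train_config.seed`` (weight
    init and shuffling use separate substreams of that seed).
    """
    net_config = net_config or SegNetConfig()
    train_config = train_config or SegTrainConfig()
    masks_arr = np.stack([center_crop(np.asarray(m, dtype=np.float64), net_config.input_size)
                          for m in masks])
    if not masks_arr.any():
        raise ValueError("refusing to train: no positive masks in training data")
    x = _prepare(patches, net_config, intensity_scale)
    is_pos = masks_arr.reshape(len(masks_arr), -1).any(axis=1)
    pos_idx = np.flatnonzero(is_pos)
    neg_idx = np.flatnonzero(~is_pos)
    n = len(x)
    n_batches = max(1, int(np.ceil(n / train_config.batch_size)))
    a, b = train_config.tversky_alpha, train_config.tversky_beta

    def _positive_train_dice(net: SegNet) -> float:
        """Mean hard Dice over the lesion-positive training patches."""
        scores = []
        for start in range(0, len(pos_idx), train_config.batch_size):
            sel = pos_idx[start:start + train_config.batch_size]
            pred = net.forward(x[sel])[:, 0] >= 0.5
            for k, patch_pred in zip(sel, pred):
                scores.append(dice_score(patch_pred, masks_arr[k] > 0.5))
        return float(np.mean(scores))

    def _predicts_on_positives(net: SegNet, level: float = 0.5) -> bool:
        for start in range(0, len(pos_idx), train_config.batch_size):
            sel = pos_idx[start:start + train_config.batch_size]
            if (net.forward(x[sel])[:, 0] >= level).any():
                return True
        return False

    # the overlap loss has degenerate attractors (all-zero output saturating
    # the sigmoid, or indiscriminate over-prediction); some data/init
    # combinations fall into them, so an attempt whose best training-positive
    # Dice stays poor is retried from a fresh init substream. All-zero
    # collapse shows up within the first few epochs and is aborted cheaply;
    # the best attempt overall is returned either way.
    check_epoch = max(3, min(6, train_config.epochs // 4))
    overall_net, overall_dice = None, -1.0
    # restart attempts vary the learning rate as well as the init: which basin
    # an attempt lands in depends on both, and no single rate suits every
    # phantom draw
    lr_cycle = (1.0, 0.5, 2.0, 0.25, 1.0, 0.5, 2.0)
    for attempt in range(max_restarts + 1):
        net = SegNet(net_config, np.random.default_rng([train_config.seed, 1, attempt]))
        shuffle_rng = np.random.default_rng([train_config.seed, 2, attempt])
        lr = train_config.learning_rate * lr_cycle[attempt % len(lr_cycle)]
        opt = Adam(net.layers(), lr=lr, beta1=train_config.beta1)
        best_dice, best_state = -1.0, None
        aborted = False
        for epoch in range(train_config.epochs):
            if (epoch == check_epoch and attempt < max_restarts
                    and not _predicts_on_positives(net, level=0.2)):
                aborted = True
                break
            # stratify batches so each sees lesion-positive patches when any
            # exist; hard-negative mining then balances within the batch
            pos_perm = shuffle_rng.permutation(pos_idx)
            neg_perm = shuffle_rng.permutation(neg_idx)
            pos_chunks = np.array_split(pos_perm, n_batches)
            neg_chunks = np.array_split(neg_perm, n_batches)
            epoch_losses = []
            for pc, nc in zip(pos_chunks, neg_chunks):
                sel = np.concatenate([pc, nc])
                if sel.size == 0:
                    continue
                xb, mb, pb = x[sel], masks_arr[sel], is_pos[sel]
                probs = net.forward(xb, keep_tape=True)[:, 0]
                losses = tversky_loss(probs, mb, a, b, eps=train_config.smooth)
                keep = mine_hard_negatives(losses, pb, train_config.hard_negative_ratio)
                grads = tversky_loss_grad(probs, mb, a, b, eps=train_config.smooth)
                grads[~keep] = 0.0
                grads /= max(int(keep.sum()), 1)
                opt.zero_grad()
                net.backward(grads[:, None])
                if train_config.grad_clip > 0:
                    _clip_gradients(net, train_config.grad_clip)
                opt.step()
                epoch_losses.append(float(losses[keep].mean()))
            epoch_loss = float(np.mean(epoch_losses))
            net.loss_history.append(epoch_loss)
            if train_config.keep_best:
                eval_dice = _positive_train_dice(net)
                if eval_dice > best_dice:
                    best_dice = eval_dice
                    best_state = [(layer.W.copy(), layer.b.copy())
                                  for layer in net.layers()]
        if train_config.keep_best and best_state is not None:
            for layer, (W, b) in zip(net.layers(), best_state):
                layer.W[...] = W
                layer.b[...] = b
        attempt_dice = best_dice if train_config.keep_best else _positive_train_dice(net)
        if attempt_dice > overall_dice:
            overall_net, overall_dice = net, attempt_dice
        if not aborted and attempt_dice >= min_train_dice:
            break
        if attempt < max_restarts:
            warnings.warn(
                f"segmentation training degenerated (attempt {attempt + 1}, "
                f"train Dice {max(attempt_dice, 0.0):.2f}); restarting",
                stacklevel=2)
    net = overall_net
    net.trained = True
    return net


# ---------------------------------------------------------------------------
# Slice selection and feature extraction
# ---------------------------------------------------------------------------

def select_representative_slice(areas) -> int:
    """Index (0-based within the candidate range) of the slice carrying the
    largest predicted lesion area; the middle (third) slice when every area is
    zero; earliest index on ties."""
    areas = np.asarray(areas, dtype=np.float64)
    if np.all(areas == 0):
        return 2
    return int(np.argmax(areas))


def predict_patches(net: SegNet, patches, intensity_scale: float = 80.0,
                    threshold: float = 0.5) -> np.ndarray:
    """Binary predicted masks for a list of patches."""
    x = _prepare(patches, net.config, intensity_scale)
    probs = net.forward(x)[:, 0]
    return probs >= threshold


def extract_features(net: SegNet, stack: ROIStack, intensity_scale: float = 80.0,
                     threshold: float = 0.5) -> DeepFeatures:
    """Per-patient feature vector from the 12-patch candidate stack.

    The representative slice is the one with the largest predicted lesion area
    over its two hemisphere patches (middle slice when nothing is predicted);
    both patches of that slice run through the global-max-pool feature head
    and the per-channel elementwise maximum is returned, so the vector is
    invariant to which hemisphere carries the lesion.
    """
    if not net.trained:
        raise ValueError("network is untrained; train before extracting features")
    preds = predict_patches(net, stack.patches, intensity_scale, threshold)
    slices = sorted({s for s, _ in stack.provenance})
    areas = []
    for s in slices:
        idx = [k for k, (ps, _) in enumerate(stack.provenance) if ps == s]
        areas.append(sum(int(preds[k].sum()) for k in idx))
    chosen = select_representative_slice(areas)
    idx = [k for k, (ps, _) in enumerate(stack.provenance) if ps == slices[chosen]]
    x = _prepare([stack.patches[k] for k in idx], net.config, intensity_scale)
    feats = net.features(x)
    return DeepFeatures(patient_id=stack.patient_id, values=feats.max(axis=0),
                        source_slice=slices[chosen])


def dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Hard Dice overlap; defined as 1 when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (pred & truth).sum() / denom)
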