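"""2D lung segmentation on scout-like projections.

Two segmenters are provided:

* a residual dilated convolutional network (20 trunk layers, a residual
  connection every two layers, per-block dilation factors) trained with a
  combined Dice + cross-entropy loss — the learned pipeline;
* a deterministic classical segmenter that detects lungs as attenuation
  deficits inside the body outline — an independent, training-free
  reference used as fallback and as an oracle in end-to-end checks.

Both produce a :class:`~scoutrange.core.Mask2D` sharing the projection's
row -> z affine, so downstream range conversion is identical either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.measure import label

from .core import Mask2D, Projection2D
from .nn import Adam, SegNet, dice_bce_loss
from .phantom import PhantomConfig, generate_phantom, sample_config
from .projection import (
    ScoutGeometry,
    apply_magnification,
    normalize_resize,
    project_mask,
    project_volume,
)

__all__ = [
    "SegModelConfig",
    "TrainReport",
    "build_model",
    "train",
    "predict_mask",
    "classical_segment",
    "dice",
    "make_dataset",
    "save_model",
    "load_model",
]


@dataclass
class SegModelConfig:
    """Architecture and training hyper-parameters of the 2D network.

    The trunk has ``n_conv_layers`` 3x3 convolutions with a residual
    connection every ``residual_span`` layers and one dilation factor per
    block; ``channels`` is the trunk width and ``internal_stride`` the
    resolution reduction inside the trunk (see :class:`~scoutrange.nn.SegNet`).
    Defaults are sized for single-CPU training on synthetic scout images.
    """

    n_conv_layers: int = 20
    residual_span: int = 2
    dilation_schedule: tuple = (1, 1, 2, 2, 4, 4, 8, 8, 4, 2)
    channels: int = 8
    internal_stride: int = 2
    input_size: int = 256
    loss: str = "sum"  # dice | cross_entropy | sum
    lr: float = 1e-3
    epochs: int = 10
    batch_size: int = 4
    seed: int = 0
    split: tuple = (0.8, 0.2, 0.0)  # train / validation / test fractions

    def validate(self) -> None:
        if self.n_conv_layers % 2 != 0:
            raise ValueError("layer count must be even")
        if any(d < 1 for d in self.dilation_schedule):
            raise ValueError("dilation factors must be >= 1")
        if self.loss not in ("dice", "cross_entropy", "sum"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.n_conv_layers % self.residual_span != 0:
            raise ValueError("layer count must be a multiple of the residual span")


@dataclass
class TrainReport:
    """Per-epoch training record."""

    split: tuple
    train_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    final_val_dice: float = float("nan")
    seed: int = 0
    n_train: int = 0
    n_val: int = 0
    n_test: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def build_model(config: SegModelConfig | None = None) -> SegNet:
    """Instantiate the residual dilated network from its configuration."""
    config = config or SegModelConfig()
    config.validate()
    return SegNet(
        config.n_conv_layers,
        config.residual_span,
        config.channels,
        config.dilation_schedule,
        seed=config.seed,
        internal_stride=config.internal_stride,
    )


def _stack(dataset) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([p.pixels for p, _ in dataset]).astype(np.float32)
    masks = np.stack([m.pixels for _, m in dataset]).astype(np.float32)
    return imgs, masks


def _mean_dice(model: SegNet, imgs: np.ndarray, masks: np.ndarray,
               batch: int = 8, threshold: float = 0.5) -> float:
    scores = []
    for i in range(0, len(imgs), batch):
        probs = model.predict_proba(imgs[i:i + batch])
        for p, t in zip(probs >= threshold, masks[i:i + batch] > 0.5):
            scores.append(_dice_arrays(p, t))
    return float(np.mean(scores))


def train(
    model: SegNet,
    dataset,
    config: SegModelConfig | None = None,
) -> tuple[SegNet, TrainReport]:
    """Train (or fine-tune) the network on (projection, mask) pairs.

    The dataset is split into disjoint train/validation(/test) subsets by
    the configured fractions, shuffled deterministically by the config
    seed.  Calling with a previously trained model continues from its
    weights, which is how scout-view fine-tuning is done.  With
    ``epochs=0`` the model is returned unchanged and the report carries the
    initial validation Dice.
    """
    config = config or SegModelConfig()
    config.validate()
    if len(dataset) < 20:
        raise ValueError("need at least 20 image/mask pairs")
    for p, m in dataset:
        if p.pixels.shape != m.pixels.shape:
            raise ValueError("projection/mask shape mismatch in dataset")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(dataset))
    n = len(dataset)
    n_train = int(round(config.split[0] * n))
    n_val = int(round(config.split[1] * n))
    if n_train == 0 or n_val == 0:
        raise ValueError("train and validation splits must be nonempty")
    train_idx = order[:n_train]
    val_idx = order[n_train:n_train + n_val]
    test_idx = order[n_train + n_val:]

    imgs, masks = _stack(dataset)
    report = TrainReport(
        split=tuple(config.split), seed=config.seed,
        n_train=len(train_idx), n_val=len(val_idx), n_test=len(test_idx),
    )

    opt = Adam(model.params, lr=config.lr)
    bs = config.batch_size
    for _epoch in range(config.epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for i in range(0, len(perm), bs):
            sel = perm[i:i + bs]
            x = imgs[sel][..., None]
            t = masks[sel][..., None]
            logits = model.forward_logits(x, train=True)
            loss, dlogits = _loss(config.loss, logits, t)
            grads = model.backward(dlogits)
            opt.step(grads)
            losses.append(loss)
        report.train_loss.append(float(np.mean(losses)))
        report.val_dice.append(_mean_dice(model, imgs[val_idx], masks[val_idx]))
    if not report.val_dice:  # epochs == 0
        report.val_dice.append(_mean_dice(model, imgs[val_idx], masks[val_idx]))
    report.final_val_dice = report.val_dice[-1]
    return model, report


def _loss(kind: str, logits: np.ndarray, targets: np.ndarray):
    if kind == "sum":
        return dice_bce_loss(logits, targets)
    # single-term variants reuse the combined implementation's pieces
    loss_sum, grad_sum = dice_bce_loss(logits, targets)
    from .nn import _sigmoid  # local import to keep the public surface small

    p = _sigmoid(logits)
    t = targets.astype(np.float64)
    n = p.size
    bce = float(np.mean(np.maximum(logits, 0) - logits * t
                        + np.log1p(np.exp(-np.abs(logits)))))
    grad_bce = ((p - t) / n).astype(np.float32)
    if kind == "cross_entropy":
        return bce, grad_bce
    return loss_sum - bce, grad_sum - grad_bce  # dice term alone


def predict_mask(model: SegNet, projection: Projection2D,
                 threshold: float = 0.5) -> Mask2D:
    """Binary lung mask from the network, sharing the projection's z map."""
    pix = projection.pixels
    if pix.min() < -1e-6 or pix.max() > 1.0 + 1e-6:
        raise ValueError("projection must be normalized to [0, 1] first")
    probs = model.predict_proba(pix.astype(np.float32))
    return Mask2D(probs >= threshold, view=projection.view,
                  z0=projection.z0, dz=projection.dz)


def _dice_arrays(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice(a: Mask2D, b: Mask2D) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("masks must have the same shape")
    return _dice_arrays(a.pixels, b.pixels)


def classical_segment(projection: Projection2D, *,
                      deficit_threshold: float = 0.008,
                      body_threshold: float = 0.05,
                      max_components: int = 2) -> Mask2D:
    """Deterministic lung segmentation by attenuation-deficit analysis.

    The body outline is the largest connected component above a small
    intensity threshold.  Lungs appear as attenuation deficits relative to a
    lung-free background estimate of each craniocaudal intensity profile:
    the thorax outline varies slowly along z, so the per-column maximum over
    rows approximates the profile without the lungs, and pixels whose
    deficit (background minus image) exceeds a noise-adaptive threshold
    inside the body are lung candidates.  Holes are filled and the
    ``max_components`` largest components kept.  Requires a normalized
    projection.  Deliberately tuned for sensitivity near the apex and the
    costophrenic recesses, where the lung is only a few millimetres thick
    along the ray.
    """
    img = projection.pixels.astype(np.float64)
    if img.min() < -1e-6 or img.max() > 1.0 + 1e-6:
        raise ValueError("projection must be normalized to [0, 1] first")

    body = img > body_threshold
    if not body.any():
        raise ValueError("no body found")
    body = ndimage.binary_fill_holes(body)
    lab = label(body)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    body = lab == sizes.argmax()

    background = img.max(axis=0, keepdims=True)
    deficit = np.clip(background - img, 0.0, None)

    noise_sigma = float(img[~body].std()) if (~body).any() else 0.0
    thr = max(deficit_threshold, 6.0 * noise_sigma)
    cand = deficit > thr
    cand &= body
    cand = ndimage.binary_fill_holes(cand)

    lab = label(cand)
    if lab.max() == 0:
        return Mask2D(np.zeros_like(cand), view=projection.view,
                      z0=projection.z0, dz=projection.dz)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = np.argsort(sizes)[::-1][:max_components]
    keep = [k for k in keep if sizes[k] > 0]
    out = np.isin(lab, keep)
    return Mask2D(out, view=projection.view, z0=projection.z0, dz=projection.dz)


def make_dataset(
    n: int,
    seed: int = 0,
    view: str = "AP",
    size: int = 256,
    scout_mode: bool = False,
    config: PhantomConfig | None = None,
):
    """Generate ``n`` (projection, mask) training pairs from random phantoms.

    With ``scout_mode`` the magnification distortion of a scout acquisition
    is applied (with a per-case table-height offset), emulating the domain
    shift between summed projections and real localizer images.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        cfg = config or sample_config(rng, small=False)
        vol, mask3d = generate_phantom(cfg, seed=int(rng.integers(2**31)))
        proj = project_volume(vol, view)
        mask = project_mask(mask3d, view)
        if scout_mode:
            geom = ScoutGeometry(table_height_offset=float(rng.uniform(40.0, 160.0)))
            proj, mask = apply_magnification(proj, mask, geom)
        proj, mask = normalize_resize(proj, mask, size=size)
        pairs.append((proj, mask))
    return pairs


def save_model(model: SegNet, path) -> None:
    """Write a self-describing single-file checkpoint (.npz)."""
    np.savez(path, **model.state())


def load_model(path) -> SegNet:
    with np.load(path) as data:
        return SegNet.from_state(dict(data))
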