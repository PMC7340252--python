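"""The CNN particle / non-particle classifier and micrograph scanner.

A small convolutional network (three 3x3 conv + 2x2 max-pool blocks,
then two dense layers ending in a two-way softmax) is trained on
standardized 64x64 particle crops (label 1) against crops from empty
micrograph areas (label 0).  Picking slides a window over the micrograph
at a fixed stride, scores every window, keeps windows whose particle
probability reaches a cutoff (0.9 by default), and de-duplicates
overlapping detections keeping the higher-probability one.

Training crops and scan windows go through the identical extraction
path (crop -> bin -> resample to 64x64 -> standardize), so a window
centered on a training coordinate is bit-identical to the training crop.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .io_core import CROP_SIZE, CoordinateSet, Micrograph, extract_crop, extract_particles
from .localpicker import enforce_min_distance
from .nn import SmallCNN, cross_entropy

__all__ = [
    "PickModelConfig",
    "TrainHistory",
    "Candidate",
    "build_model",
    "make_training_set",
    "augment_batch",
    "train_model",
    "scan_micrograph",
    "nms",
    "kpick",
    "save_model",
    "load_model",
]


@dataclass
class PickModelConfig:
    """Architecture and training hyper-parameters of the picker CNN.

    The three conv blocks and the two-output softmax head are fixed
    characteristics of the architecture; filter counts, the hidden dense
    width, epochs and seed are tunable.
    """

    conv_filters: tuple[int, int, int] = (32, 64, 128)
    dense_hidden: int = 128
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    augment_max_angle: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3:
            raise ValueError("the architecture uses exactly three conv+pool blocks")


@dataclass
class TrainHistory:
    """Per-epoch accuracy and loss, as monitored during training."""

    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_accuracy)


@dataclass
class Candidate:
    """One scored scan window: center (unbinned px) and particle probability."""

    x: float
    y: float
    prob: float


class KPickModel:
    """A configured CNN with its picking metadata."""

    def __init__(self, config: PickModelConfig):
        self.config = config
        self.net = SmallCNN(
            input_hw=CROP_SIZE,
            conv_filters=config.conv_filters,
            dense_hidden=config.dense_hidden,
            n_out=2,
            seed=config.seed,
        )

    def predict_proba(self, crops: np.ndarray) -> np.ndarray:
        """Probabilities (non-particle, particle) per crop, summing to 1."""
        return self.net.predict_proba(crops)


def build_model(config: PickModelConfig | None = None) -> KPickModel:
    """Build the classifier with deterministically seeded weights."""
    return KPickModel(config or PickModelConfig())


# ---------------------------------------------------------------------------
# training data


def make_training_set(
    micrographs: list[Micrograph],
    positive_coords: list[CoordinateSet],
    particle_size: int,
    box_px: int | None = None,
    bin_factor: int = 4,
    neg_per_pos: int = 1,
    seed: int = 0,
    max_attempts_per_negative: int = 200,
    return_centers: bool = False,
):
    """Assemble labeled crops: class-selected particles vs empty areas.

    Positives are extracted at the given coordinates (label 1).  For each
    positive, ``neg_per_pos`` negatives are drawn from random centers at
    least one particle diameter away from every known particle on the
    same micrograph (label 0).  Deterministic given ``seed``.  With
    ``return_centers`` the (micrograph_id, x, y) of every crop is
    returned as a third element.
    """
    if len(micrographs) != len(positive_coords):
        raise ValueError("one coordinate set per micrograph required")
    box = int(box_px or particle_size)
    rng = np.random.default_rng(seed)
    crops: list[np.ndarray] = []
    labels: list[int] = []
    centers: list[tuple[str, float, float]] = []
    for mic, coords in zip(micrographs, positive_coords):
        stack, _ = extract_particles(mic, coords, box, bin_factor)
        crops.extend(stack.crops)
        labels.extend([1] * len(stack))
        centers.extend(stack.source)
        n_neg = neg_per_pos * len(stack)
        h, w = mic.shape
        half = box // 2
        px = coords.x
        py = coords.y
        placed = 0
        attempts = 0
        max_attempts = max_attempts_per_negative * max(n_neg, 1)
        while placed < n_neg and attempts < max_attempts:
            attempts += 1
            x = rng.uniform(half, w - half - 1)
            y = rng.uniform(half, h - half - 1)
            if len(px) and np.hypot(px - x, py - y).min() < particle_size:
                continue
            crop = extract_crop(mic.image, x, y, box, bin_factor)
            if crop is None:
                continue
            crops.append(crop)
            labels.append(0)
            centers.append((mic.id, float(x), float(y)))
            placed += 1
        if placed < n_neg:
            raise RuntimeError(
                f"could only place {placed}/{n_neg} negatives on micrograph "
                f"{mic.id!r} at >= {particle_size} px from known particles"
            )
    out_crops = np.array(crops, dtype=np.float32)
    out_labels = np.array(labels, dtype=int)
    if return_centers:
        return out_crops, out_labels, centers
    return out_crops, out_labels


def augment_batch(
    crops: np.ndarray,
    seed: int = 0,
    max_angle: float = 20.0,
    flips: bool = True,
) -> np.ndarray:
    """Random small rotations plus horizontal/vertical flips.

    Each crop independently receives a rotation with an angle uniform in
    ``[-max_angle, +max_angle]`` degrees (reflect padding, recropped to
    the original frame), then a horizontal and a vertical flip each with
    probability 0.5 (suppressed with ``flips=False``).  Deterministic
    given ``seed``.
    """
    crops = np.asarray(crops, dtype=np.float32)
    rng = np.random.default_rng(seed)
    out = np.empty_like(crops)
    angles = rng.uniform(-max_angle, max_angle, size=len(crops))
    flips_h = (rng.random(len(crops)) < 0.5) & flips
    flips_v = (rng.random(len(crops)) < 0.5) & flips
    for i, crop in enumerate(crops):
        if angles[i] == 0.0:
            img = crop
        else:
            img = ndimage.rotate(crop, angles[i], reshape=False, order=1, mode="reflect")
        if flips_h[i]:
            img = img[:, ::-1]
        if flips_v[i]:
            img = img[::-1, :]
        out[i] = img
    return out


# ---------------------------------------------------------------------------
# training


def train_model(
    model: KPickModel,
    crops: np.ndarray,
    labels: np.ndarray,
    epochs: int | None = None,
    val_fraction: float | None = None,
    seed: int = 0,
    augment: bool = True,
) -> tuple[KPickModel, TrainHistory]:
    """Train with a stratified validation split and per-epoch augmentation.

    Augmentation is applied to the training portion only; the validation
    crops stay untouched.  Train accuracy/loss are accumulated from the
    training minibatches themselves (i.e. on augmented data), validation
    metrics from a full pass at the end of each epoch.
    """
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    val_fraction = cfg.val_fraction if val_fraction is None else val_fraction
    crops = np.asarray(crops, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training requires both particle and non-particle examples")
    n_pos = int((labels == 1).sum())
    if n_pos < 100:
        warnings.warn(
            f"only {n_pos} positive particles supplied; at least 100 are "
            "recommended for reliable training",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    # stratified split
    train_idx, val_idx = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    train_idx = np.array(sorted(train_idx))
    val_idx = np.array(sorted(val_idx))
    x_val, y_val = crops[val_idx], labels[val_idx]

    history = TrainHistory()
    bs = cfg.batch_size
    for epoch in range(epochs):
        order = rng.permutation(len(train_idx))
        x_tr = crops[train_idx[order]]
        y_tr = labels[train_idx[order]]
        if augment:
            x_tr = augment_batch(x_tr, seed=int(rng.integers(2**31)), max_angle=cfg.augment_max_angle)
        losses, correct, seen = [], 0, 0
        for i in range(0, len(x_tr), bs):
            xb, yb = x_tr[i : i + bs], y_tr[i : i + bs]
            loss = model.net.train_step(xb, yb, lr=cfg.learning_rate)
            losses.append(loss)
            correct += int((model.net.last_probs.argmax(axis=1) == yb).sum())
            seen += len(yb)
        p_val = model.net.predict_proba(x_val)
        history.train_accuracy.append(correct / seen)
        history.train_loss.append(float(np.mean(losses)))
        history.val_accuracy.append(float((p_val.argmax(axis=1) == y_val).mean()))
        history.val_loss.append(cross_entropy(p_val, y_val))
    return model, history


# ---------------------------------------------------------------------------
# picking


def scan_micrograph(
    model: KPickModel,
    micrograph: Micrograph,
    particle_size: int,
    stride: int | None = None,
    p_min: float = 0.9,
    bin_factor: int = 4,
    box_px: int | None = None,
) -> list[Candidate]:
    """Slide a window over the micrograph and score every position.

    Windows of ``box_px`` (default: the particle size) are placed on a
    grid with the given stride (default: particle_size / 4, which keeps
    every true center within half an NMS radius of some window center),
    extracted exactly like training crops, and scored in batches.
    Candidates with particle probability >= ``p_min`` are returned.
    """
    box = int(box_px or particle_size)
    stride = int(stride or max(1, particle_size // 4))
    h, w = micrograph.shape
    if box > h or box > w:
        raise ValueError(f"micrograph {micrograph.shape} smaller than scan box {box}")
    half = box // 2
    xs = np.arange(half, w - half + 1, stride)
    ys = np.arange(half, h - half + 1, stride)
    centers = [(float(x), float(y)) for y in ys for x in xs]
    crops = np.empty((len(centers), CROP_SIZE, CROP_SIZE), dtype=np.float32)
    for i, (x, y) in enumerate(centers):
        crops[i] = extract_crop(micrograph.image, x, y, box, bin_factor)
    probs = model.predict_proba(crops)[:, 1]
    return [
        Candidate(x=cx, y=cy, prob=float(p))
        for (cx, cy), p in zip(centers, probs)
        if p >= p_min
    ]


def nms(candidates: list[Candidate], min_dist: float) -> list[Candidate]:
    """De-duplicate detections: keep the higher-probability pick.

    Greedy by descending probability (ties broken by (x, y) order, so the
    result does not depend on input order); an accepted set always has
    all pairwise distances >= ``min_dist``.
    """
    if not candidates:
        return []
    xy = np.array([(c.x, c.y) for c in candidates])
    probs = np.array([c.prob for c in candidates])
    keep = enforce_min_distance(xy, min_dist, scores=probs, tie_break_xy=True)
    return [candidates[i] for i in keep]


def kpick(
    model: KPickModel,
    micrograph: Micrograph,
    particle_size: int,
    p_min: float = 0.9,
    stride: int | None = None,
    bin_factor: int = 4,
    box_px: int | None = None,
) -> CoordinateSet:
    """Full CNN picking on one micrograph: scan, threshold, de-duplicate."""
    cands = scan_micrograph(
        model, micrograph, particle_size, stride=stride, p_min=p_min,
        bin_factor=bin_factor, box_px=box_px,
    )
    kept = nms(cands, float(particle_size))
    if not kept:
        return CoordinateSet.empty(micrograph.id)
    return CoordinateSet(
        np.array([c.x for c in kept]),
        np.array([c.y for c in kept]),
        np.array([c.prob for c in kept]),
        micrograph.id,
    )


# ---------------------------------------------------------------------------
# persistence


def save_model(model: KPickModel, path) -> None:
    """Save weights (.npz) plus a JSON sidecar with config and seed."""
    path = os.fspath(path)
    np.savez(path if path.endswith(".npz") else path + ".npz", **model.net.state_dict())
    meta = asdict(model.config)
    meta["conv_filters"] = list(meta["conv_filters"])
    with open(os.path.splitext(path)[0] + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(path) -> KPickModel:
    path = os.fspath(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        meta = json.load(fh)
    meta["conv_filters"] = tuple(meta["conv_filters"])
    model = KPickModel(PickModelConfig(**meta))
    with np.load(base + ".npz") as data:
        model.net.load_state_dict(dict(data))
    return model
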