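"""Dual-branch late-fusion biomass regression network and its training protocol.

Two modality-specific convolutional branches (color, jet-encoded depth)
each emit a ``feature_dim``-vector (default 1000, mirroring an ImageNet
classifier layer with its softmax removed).  The branch outputs are
concatenated into a ``2 * feature_dim`` feature vector and passed to a
regression head of one hidden fully connected layer (1000 units) and one
linear output unit; ReLU sits between all layers except the final linear
output.  Training minimizes the mean absolute percentage error (MAPE),
which equalizes learning pressure across a ~300x range of plant masses.

The training protocol is two-stage: each branch is first trained as a
single-modality regressor (branch + one linear unit), then its head is
stripped and the branch weights initialize the fusion network, which is
fine-tuned end to end.

Backbones here are reduced-depth convolutional stacks sized for CPU
training on small renders; the fusion topology — not backbone depth — is
the method.  ImageNet-pretrained backbones would require a GPU deep
learning stack and pretrained weight files, neither of which this package
depends on; ``pretrained=True`` therefore raises.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .preprocess import (
    AugmentConfig,
    ModelInputPair,
    apply_augmentation,
    augment_pair,
    preprocess_pair,
)
from .scene import RGBDSample

# backbone registry: name -> ((channels, stride), ...); each conv is 3x3 with
# BN + ReLU, followed by global average pooling and a linear feature layer.
# The final conv keeps stride 1 so its activation grid (the GradCAM plane)
# stays fine enough to resolve transplant-sized plants.
BACKBONES: dict[str, tuple[tuple[int, int], ...]] = {
    "tiny": ((16, 2), (32, 2), (64, 1)),
    "wide": ((24, 2), (48, 2), (96, 1)),
    "small": ((16, 2), (32, 2), (64, 2), (96, 1)),
}


@dataclass
class BranchConfig:
    """Configuration of one modality branch."""

    modality: str = "rgb"  # {"rgb", "depth"}
    backbone_name: str = "tiny"
    feature_dim: int = 1000
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.modality not in ("rgb", "depth"):
            raise ValueError("modality must be 'rgb' or 'depth'")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")


@dataclass
class TrainConfig:
    """Optimization settings: AdamW, stepped learning-rate schedule, MAPE
    early stopping on validation loss."""

    lr: float = 1e-4
    weight_decay: float = 1e-3
    batch_size: int = 16
    lr_halving_epochs: tuple[int, ...] = (20, 40, 60, 80, 100)
    patience_epochs: int = 60
    max_epochs: int = 300
    seed: int = 0
    augment: bool = True
    augment_config: AugmentConfig = field(default_factory=AugmentConfig)
    # initialize the output unit's bias at the mean training mass so the
    # optimizer starts from the constant-mean predictor instead of 0 g
    init_bias_to_mean: bool = True

    def __post_init__(self) -> None:
        if min(self.lr, self.weight_decay, self.batch_size, self.patience_epochs) <= 0:
            raise ValueError("training parameters must be positive")
        if list(self.lr_halving_epochs) != sorted(self.lr_halving_epochs):
            raise ValueError("lr schedule epochs must be sorted")

    def lr_at(self, epoch: int) -> float:
        """Learning rate during ``epoch`` (1-based): halved at each schedule epoch."""
        n_halvings = sum(1 for e in self.lr_halving_epochs if epoch >= e)
        return self.lr * 0.5**n_halvings


def mape_loss(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute percentage error (fractional): (1/n) sum |A - F| / A."""
    predicted = np.asarray(predicted, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if truth.size == 0:
        raise ValueError("need at least one sample")
    if np.any(truth == 0):
        raise ValueError("MAPE is undefined for zero ground-truth mass")
    return float(np.mean(np.abs(truth - predicted) / np.abs(truth)))


def mape_loss_grad(predicted: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """d MAPE / d predicted: -sign(A - F) / (n |A|)."""
    predicted = np.asarray(predicted, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    n = truth.size
    return (-np.sign(truth - predicted) / (n * np.abs(truth))).astype(np.float32)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_branch(config: BranchConfig, rng: np.random.Generator | None = None) -> nn.Sequential:
    """A feature extractor mapping an S x S x 3 input to a feature_dim vector."""
    if config.pretrained:
        raise ValueError(
            "pretrained backbones are not available in this build; "
            "use pretrained=False (random init) or supply branch weights"
        )
    if config.backbone_name not in BACKBONES:
        raise ValueError(f"unknown backbone {config.backbone_name!r}")
    rng = rng or np.random.default_rng(0)
    plan = BACKBONES[config.backbone_name]
    layers: list[nn.Layer] = []
    cin = 3
    for cout, stride in plan:
        layers.append(nn.Conv2d(cin, cout, kernel_size=3, stride=stride, padding=1, rng=rng))
        layers.append(nn.BatchNorm2d(cout))
        layers.append(nn.ReLU())
        cin = cout
    layers.append(nn.GlobalAvgPool())
    layers.append(nn.Linear(cin, config.feature_dim, rng=rng))
    return nn.Sequential(layers)


class SingleModalityModel:
    """Branch + single linear unit: the ablation model and the branch-
    pretraining vehicle."""

    def __init__(self, branch: nn.Sequential, config: BranchConfig, rng: np.random.Generator):
        self.config = config
        self.branch = branch
        self.head = nn.Sequential([nn.ReLU(), nn.Linear(config.feature_dim, 1, rng=rng)])

    @property
    def modality(self) -> str:
        return self.config.modality

    def _select(self, rgb: np.ndarray, depth_jet: np.ndarray) -> np.ndarray:
        return rgb if self.modality == "rgb" else depth_jet

    def forward(self, rgb: np.ndarray, depth_jet: np.ndarray, train: bool = False) -> np.ndarray:
        feats = self.branch.forward(self._select(rgb, depth_jet), train=train)
        return self.head.forward(feats, train=train)[:, 0]

    def backward(self, grad_out: np.ndarray) -> None:
        g = self.head.backward(grad_out[:, None])
        self.branch.backward(g)

    def params(self) -> list[nn.Param]:
        return self.branch.params() + self.head.params()


class FusionModel:
    """Late-fusion RGB-D regressor: concat(branch features) -> FC head -> grams."""

    def __init__(
        self,
        rgb_branch: nn.Sequential,
        depth_branch: nn.Sequential,
        feature_dim: int,
        head_hidden: int = 1000,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.feature_dim = feature_dim
        self.rgb_branch = rgb_branch
        self.depth_branch = depth_branch
        self.head = nn.Sequential(
            [
                nn.ReLU(),
                nn.Linear(2 * feature_dim, head_hidden, rng=rng),
                nn.ReLU(),
                nn.Linear(head_hidden, 1, rng=rng),
            ]
        )

    def forward(self, rgb: np.ndarray, depth_jet: np.ndarray, train: bool = False) -> np.ndarray:
        f_rgb = self.rgb_branch.forward(rgb, train=train)
        f_depth = self.depth_branch.forward(depth_jet, train=train)
        fused = np.concatenate([f_rgb, f_depth], axis=1)  # (n, 2 * feature_dim)
        self._fused_dim = fused.shape[1]
        return self.head.forward(fused, train=train)[:, 0]

    def backward(self, grad_out: np.ndarray) -> None:
        g = self.head.backward(grad_out[:, None])
        self.rgb_branch.backward(g[:, : self.feature_dim])
        self.depth_branch.backward(g[:, self.feature_dim :])

    def params(self) -> list[nn.Param]:
        return self.rgb_branch.params() + self.depth_branch.params() + self.head.params()


def build_single_modality(
    config: BranchConfig, rng: np.random.Generator | None = None
) -> SingleModalityModel:
    rng = rng or np.random.default_rng(0)
    return SingleModalityModel(build_branch(config, rng), config, rng)


def build_fusion(
    rgb_branch: nn.Sequential,
    depth_branch: nn.Sequential,
    head_hidden: int = 1000,
    rng: np.random.Generator | None = None,
) -> FusionModel:
    """Fuse two branches sharing the same feature dimension."""
    d_rgb = rgb_branch.layers[-1].weight.value.shape[1]
    d_depth = depth_branch.layers[-1].weight.value.shape[1]
    if d_rgb != d_depth:
        raise ValueError(f"branch feature dims differ: {d_rgb} vs {d_depth}")
    return FusionModel(rgb_branch, depth_branch, d_rgb, head_hidden=head_hidden, rng=rng)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class ArrayDataset:
    """Preprocessed pairs as stacked arrays (N, S, S, 3) plus labels (grams)."""

    rgb: np.ndarray
    depth_jet: np.ndarray
    mass_g: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.rgb) == len(self.depth_jet) == len(self.mass_g)):
            raise ValueError("inconsistent dataset lengths")

    def __len__(self) -> int:
        return len(self.mass_g)

    @classmethod
    def from_samples(cls, samples, crop_size: int) -> "ArrayDataset":
        pairs = [preprocess_pair(s, crop_size=crop_size) for s in samples]
        return cls(
            rgb=np.stack([p.rgb_norm for p in pairs]),
            depth_jet=np.stack([p.depth_jet for p in pairs]),
            mass_g=np.array([s.mass_g for s in samples], dtype=np.float64),
        )

    def pair(self, i: int) -> ModelInputPair:
        return ModelInputPair(rgb_norm=self.rgb[i], depth_jet=self.depth_jet[i])


def _to_nchw(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.moveaxis(x, -1, 1).astype(np.float32))


def _forward_in_batches(model, ds: ArrayDataset, batch_size: int = 32) -> np.ndarray:
    preds = []
    for i in range(0, len(ds), batch_size):
        preds.append(
            model.forward(
                _to_nchw(ds.rgb[i : i + batch_size]),
                _to_nchw(ds.depth_jet[i : i + batch_size]),
                train=False,
            )
        )
    return np.concatenate(preds)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    model,
    train_set: ArrayDataset,
    val_set: ArrayDataset,
    config: TrainConfig,
) -> tuple[object, pd.DataFrame]:
    """Minimize MAPE with AdamW, stepped LR, and val-loss early stopping.

    Augmentation (shared rotation; color jitter on RGB only) is applied to
    training batches only; validation MAPE is computed un-augmented.
    Returns the best-validation-loss checkpoint (model with those weights
    restored) and a per-epoch history (epoch, train_loss, val_loss, lr).
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if np.any(val_set.mass_g <= 0) or np.any(train_set.mass_g <= 0):
        raise ValueError("MAPE training requires strictly positive masses")
    rng = np.random.default_rng(config.seed)
    if config.init_bias_to_mean:
        out_bias = model.head.layers[-1].bias
        if np.all(out_bias.value == 0):
            out_bias.value[:] = float(train_set.mass_g.mean())
    opt = nn.AdamW(model.params(), lr=config.lr, weight_decay=config.weight_decay)
    history = []
    best_val = np.inf
    best_params: list[np.ndarray] | None = None
    best_epoch = 0
    n = len(train_set)
    for epoch in range(1, config.max_epochs + 1):
        lr = config.lr_at(epoch)
        opt.lr = lr
        order = rng.permutation(n)
        epoch_losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            rgb_b = []
            depth_b = []
            for j in idx:
                p = train_set.pair(j)
                if config.augment:
                    p = augment_pair(p, rng, config.augment_config)
                rgb_b.append(p.rgb_norm)
                depth_b.append(p.depth_jet)
            rgb_b = _to_nchw(np.stack(rgb_b))
            depth_b = _to_nchw(np.stack(depth_b))
            y = train_set.mass_g[idx]
            opt.zero_grad()
            pred = model.forward(rgb_b, depth_b, train=True)
            loss = mape_loss(pred, y)
            model.backward(mape_loss_grad(pred, y))
            opt.step()
            epoch_losses.append(loss)
        val_pred = _forward_in_batches(model, val_set)
        val_loss = mape_loss(val_pred, val_set.mass_g)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": float(val_loss),
                "lr": lr,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_params = [p.value.copy() for p in model.params()]
            best_bn_stats = [
                (l.running_mean.copy(), l.running_var.copy())
                for l in _bn_layers(model)
            ]
        if epoch - best_epoch >= config.patience_epochs:
            break
    if best_params is not None:
        for p, v in zip(model.params(), best_params):
            p.value = v
        for l, (m, v) in zip(_bn_layers(model), best_bn_stats):
            l.running_mean, l.running_var = m, v
    hist = pd.DataFrame(history)
    hist.attrs["best_val_loss"] = best_val
    hist.attrs["best_epoch"] = best_epoch
    return model, hist


def _bn_layers(model) -> list[nn.BatchNorm2d]:
    seqs = []
    for attr in ("branch", "rgb_branch", "depth_branch", "head"):
        seq = getattr(model, attr, None)
        if seq is not None:
            seqs.append(seq)
    out = []
    for seq in seqs:
        out.extend(l for l in seq.layers if isinstance(l, nn.BatchNorm2d))
    return out


def train_single_modality(
    train_set: ArrayDataset,
    val_set: ArrayDataset,
    train_config: TrainConfig,
    branch_config: BranchConfig,
) -> tuple[SingleModalityModel, pd.DataFrame]:
    """Train one modality-specific regressor (branch + linear unit)."""
    rng = np.random.default_rng(
        train_config.seed + (1 if branch_config.modality == "rgb" else 2)
    )
    m = SingleModalityModel(build_branch(branch_config, rng), branch_config, rng)
    if train_config.max_epochs > 0:
        m, hist = train(m, train_set, val_set, train_config)
    else:
        hist = pd.DataFrame(columns=["epoch", "train_loss", "val_loss", "lr"])
    return m, hist


def pretrain_branches(
    train_set: ArrayDataset,
    val_set: ArrayDataset,
    train_config: TrainConfig,
    branch_config: BranchConfig | None = None,
) -> tuple[nn.Sequential, nn.Sequential, dict[str, pd.DataFrame]]:
    """Stage one of the protocol: train each modality as its own regressor,
    strip the heads, return the trained branches (rgb, depth) + histories."""
    base = branch_config or BranchConfig()
    histories = {}
    branches = {}
    for modality in ("rgb", "depth"):
        cfg = dataclasses.replace(base, modality=modality)
        m, hist = train_single_modality(train_set, val_set, train_config, cfg)
        branches[modality] = m.branch  # head stripped: the branch object itself
        histories[modality] = hist
    return branches["rgb"], branches["depth"], histories


def predict(model, samples, crop_size: int, batch_size: int = 32) -> np.ndarray:
    """Predict grams for raw RGB-D samples (no augmentation)."""
    if isinstance(samples, RGBDSample):
        samples = [samples]
    ds = ArrayDataset.from_samples(samples, crop_size=crop_size)
    return _forward_in_batches(model, ds, batch_size=batch_size)


def mean_baseline_mape(train_masses: np.ndarray, eval_masses: np.ndarray) -> float:
    """MAPE of the constant predictor that always outputs the training mean."""
    const = float(np.mean(train_masses))
    return mape_loss(np.full(len(eval_masses), const), eval_masses)
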