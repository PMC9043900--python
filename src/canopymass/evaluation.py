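"""Accuracy metrics, mass-binned reports, validation sampling, and GradCAM.

Biomass regression error is heteroscedastic across the growth cycle —
small transplants and large occluded plants fail differently — so besides
overall MAPE / RMSE / Pearson r the report breaks both error metrics out
by ground-truth mass bins whose default edges ([0, 2, 5, 10, 15, 25, inf)
grams) track the typical occlusion regimes of a dense tray.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import FusionModel, mape_loss
from .scene import RGBDSample
from .preprocess import preprocess_pair

DEFAULT_BIN_EDGES = (0.0, 2.0, 5.0, 10.0, 15.0, 25.0, np.inf)


def rmse(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean squared error in grams."""
    truth = np.asarray(truth, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if truth.shape != predicted.shape or truth.size == 0:
        raise ValueError("truth and predicted must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((truth - predicted) ** 2)))


def pearson_r(truth: np.ndarray, predicted: np.ndarray) -> float:
    truth = np.asarray(truth, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if truth.size < 2 or truth.std() == 0 or predicted.std() == 0:
        return float("nan")  # correlation undefined for degenerate input
    return float(stats.pearsonr(truth, predicted).statistic)


@dataclass
class BinReport:
    bin_range_g: tuple[float, float]
    n: int
    mape_pct: float | None
    rmse_g: float | None


@dataclass
class EvalReport:
    n: int
    mape_pct: float
    rmse_g: float
    pearson_r: float
    per_bin: list[BinReport] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mape_pct": self.mape_pct,
            "rmse_g": self.rmse_g,
            "pearson_r": self.pearson_r,
            "per_bin": [
                {
                    "bin_range_g": list(b.bin_range_g),
                    "n": b.n,
                    "mape_pct": b.mape_pct,
                    "rmse_g": b.rmse_g,
                }
                for b in self.per_bin
            ],
        }


def binned_report(
    truth: np.ndarray,
    predicted: np.ndarray,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> EvalReport:
    """Overall and per-mass-bin MAPE/RMSE; bins are half-open [lo, hi) on
    ground-truth mass.  Empty bins report n = 0 with null metrics."""
    truth = np.asarray(truth, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    edges = np.asarray(bin_edges, dtype=np.float64)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    if truth.size and truth.min() < edges[0]:
        raise ValueError("ground-truth mass below the first bin edge")
    overall = EvalReport(
        n=truth.size,
        mape_pct=100.0 * mape_loss(predicted, truth),
        rmse_g=rmse(truth, predicted),
        pearson_r=pearson_r(truth, predicted),
    )
    which = np.digitize(truth, edges[1:-1], right=False)  # [lo, hi) assignment
    for b in range(len(edges) - 1):
        sel = which == b
        n_b = int(sel.sum())
        if n_b == 0:
            overall.per_bin.append(BinReport((edges[b], edges[b + 1]), 0, None, None))
        else:
            overall.per_bin.append(
                BinReport(
                    (edges[b], edges[b + 1]),
                    n_b,
                    100.0 * mape_loss(predicted[sel], truth[sel]),
                    rmse(truth[sel], predicted[sel]),
                )
            )
    assert sum(b.n for b in overall.per_bin) == overall.n
    return overall


def weighted_validation_sample(
    masses: np.ndarray,
    n_out: int = 100,
    bin_width_g: float = 1.0,
    n_bins: int = 35,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Inverse-frequency sampling without replacement for a flatter validation set.

    Masses are discretized into ``n_bins`` bins of ``bin_width_g``; each
    individual is weighted by 1 / count(its bin) and ``n_out`` distinct
    indices are drawn, flattening the right-skewed mass distribution.
    """
    masses = np.asarray(masses, dtype=np.float64)
    if masses.size == 0:
        raise ValueError("masses must be non-empty")
    if n_out > masses.size:
        raise ValueError("n_out exceeds population size")
    rng = rng or np.random.default_rng(0)
    bins = np.clip((masses / bin_width_g).astype(int), 0, n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    weights = 1.0 / counts[bins]
    p = weights / weights.sum()
    return rng.choice(masses.size, size=n_out, replace=False, p=p)


# ---------------------------------------------------------------------------
# GradCAM
# ---------------------------------------------------------------------------

def gradcam(
    model: FusionModel,
    sample: RGBDSample,
    branch: str = "rgb",
    layer: int | None = None,
    crop_size: int | None = None,
) -> np.ndarray:
    """Gradient-weighted class activation map for the scalar mass output.

    Channel weights are the spatial means of the output gradient at the
    chosen convolutional layer of one branch (default: the final conv of
    the RGB branch); the map is the ReLU of the weighted activation sum,
    upsampled to the model input size and max-normalized to 1 (an all-zero
    map stays zero).
    """
    from skimage.transform import resize

    if branch not in ("rgb", "depth"):
        raise ValueError("branch must be 'rgb' or 'depth'")
    seq = model.rgb_branch if branch == "rgb" else model.depth_branch
    if layer is None:
        layer = seq.last_conv_index()
    if not (0 <= layer < len(seq.layers)):
        raise ValueError(f"unknown layer index {layer}")
    if crop_size is None:
        crop_size = sample.rgb.shape[0] if sample.rgb.shape[0] == sample.rgb.shape[1] else 480
    pair = preprocess_pair(sample, crop_size=crop_size)
    rgb = np.moveaxis(pair.rgb_norm, -1, 0)[None].astype(np.float32)
    djet = np.moveaxis(pair.depth_jet, -1, 0)[None].astype(np.float32)
    seq.capture_index = layer
    try:
        model.forward(rgb, djet, train=False)
        for p in model.params():
            p.grad = None
        model.backward(np.ones(1, dtype=np.float32))
        acts = seq.captured_activation[0]  # (C, h, w)
        grads = seq.captured_gradient[0]
    finally:
        seq.capture_index = None
        seq.captured_activation = None
        seq.captured_gradient = None
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    cam = resize(cam, (crop_size, crop_size), order=1, mode="constant", anti_aliasing=False)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return cam.astype(np.float32)


def localization_score(cam: np.ndarray, footprint: np.ndarray) -> tuple[float, float]:
    """Mean heatmap value inside vs outside a boolean footprint mask."""
    footprint = footprint.astype(bool)
    if footprint.shape != cam.shape:
        raise ValueError("footprint and cam shapes differ")
    inside = float(cam[footprint].mean()) if footprint.any() else 0.0
    outside = float(cam[~footprint].mean()) if (~footprint).any() else 0.0
    return inside, outside
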