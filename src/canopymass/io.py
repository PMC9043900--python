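"""File conventions: 8-bit RGB PNG + 16-bit depth PNG pairs, CSV manifests,
and the nested run configuration echoed into every output directory."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .scene import MAX_SCENE_DEPTH, RGBDSample

MANIFEST_COLUMNS = ["rgb_path", "depth_path", "mass_g", "plant_id", "timestamp", "treatment", "seed"]

RUN_CONFIG_SECTIONS = ("synth", "preprocess", "model", "train", "eval", "monitor")


@dataclass
class RunConfig:
    """Nested per-stage configuration blocks; unknown sections are rejected
    so typos cannot silently fall back to defaults."""

    synth: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    eval: dict = field(default_factory=dict)
    monitor: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(RUN_CONFIG_SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**{s: dict(d.get(s, {})) for s in RUN_CONFIG_SECTIONS})

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)


def write_rgbd(sample: RGBDSample, rgb_path: str | Path, depth_path: str | Path) -> None:
    """Write the pair: rgb as 8-bit PNG, depth as 16-bit single-channel PNG
    (0.1 mm integer units, 0 = missing)."""
    rgb = np.asarray(sample.rgb)
    depth = np.asarray(sample.depth)
    if rgb.dtype != np.uint8 or rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("rgb must be H x W x 3 uint8")
    if depth.min() < 0 or depth.max() > np.iinfo(np.uint16).max:
        raise ValueError("depth out of uint16 range")
    iio.imwrite(Path(rgb_path), rgb, extension=".png")
    iio.imwrite(Path(depth_path), depth.astype(np.uint16), extension=".png")


def read_rgbd(
    rgb_path: str | Path,
    depth_path: str | Path,
    mass_g: float = 0.0,
    plant_id: str = "",
    timestamp: float | None = None,
    treatment: str | None = None,
) -> RGBDSample:
    """Load and validate an RGB-D pair (8-bit color, 16-bit depth, matching sizes)."""
    rgb_path, depth_path = Path(rgb_path), Path(depth_path)
    for p in (rgb_path, depth_path):
        if not p.exists():
            raise FileNotFoundError(p)
    rgb = iio.imread(rgb_path)
    depth = iio.imread(depth_path)
    if rgb.dtype != np.uint8 or rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"{rgb_path}: expected 8-bit 3-channel PNG, got {rgb.dtype} {rgb.shape}")
    if depth.dtype != np.uint16 or depth.ndim != 2:
        raise ValueError(
            f"{depth_path}: expected 16-bit single-channel PNG, got {depth.dtype} {depth.shape}"
        )
    if rgb.shape[:2] != depth.shape:
        raise ValueError(
            f"size mismatch: rgb {rgb.shape[:2]} vs depth {depth.shape}"
        )
    depth = depth.astype(np.int32)
    if depth.max() > MAX_SCENE_DEPTH:
        raise ValueError(f"{depth_path}: depth exceeds scene maximum {MAX_SCENE_DEPTH}")
    return RGBDSample(
        rgb=rgb,
        depth=depth,
        mass_g=mass_g,
        plant_id=plant_id,
        timestamp=timestamp,
        treatment=treatment,
    )


def load_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Load a dataset manifest CSV and validate its contract."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    bad_mass = df.index[df["mass_g"] <= 0]
    if len(bad_mass):
        raise ValueError(f"{path}: non-positive mass_g at rows {list(bad_mass[:5])}")
    dup = df.duplicated(subset=["plant_id", "timestamp"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (plant_id, timestamp) at rows {list(df.index[dup][:5])}")
    if check_paths:
        base = path.parent
        for col in ("rgb_path", "depth_path"):
            resolved = []
            for i, p in df[col].items():
                cand = Path(p)
                if not cand.is_absolute():
                    cand = base / cand  # manifest-relative convention
                if not cand.exists():
                    raise FileNotFoundError(f"{path} row {i}: {p}")
                resolved.append(str(cand))
            df[col] = resolved
    return df


def load_samples(manifest: pd.DataFrame) -> list[RGBDSample]:
    return [
        read_rgbd(
            r.rgb_path,
            r.depth_path,
            mass_g=float(r.mass_g),
            plant_id=str(r.plant_id),
            timestamp=float(r.timestamp) if str(r.timestamp) != "" else None,
            treatment=str(r.treatment) or None,
        )
        for r in manifest.itertuples()
    ]


def split_manifest(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] | None = None,
    by_cycle: str | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Disjoint, exhaustive train/val/test split.

    ``fractions`` splits rows at random in the given proportions;
    ``by_cycle`` names a column whose values (growth cycles) are assigned
    wholesale to splits, so no cycle straddles two splits — the guard
    against overfitting to within-cycle phenotype variation.
    """
    rng = rng or np.random.default_rng(0)
    if (fractions is None) == (by_cycle is None):
        raise ValueError("specify exactly one of fractions or by_cycle")
    if fractions is not None:
        if not np.isclose(sum(fractions), 1.0):
            raise ValueError("fractions must sum to 1")
        n = len(manifest)
        order = rng.permutation(n)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        idx = {
            "train": order[:n_train],
            "val": order[n_train : n_train + n_val],
            "test": order[n_train + n_val :],
        }
        return {k: manifest.iloc[np.sort(v)].reset_index(drop=True) for k, v in idx.items()}
    cycles = np.array(sorted(manifest[by_cycle].unique()))
    if len(cycles) < 2:
        raise ValueError("need at least two cycles to split by cycle")
    order = rng.permutation(len(cycles))
    n_test = max(1, len(cycles) // 3)
    n_val = max(1, (len(cycles) - n_test) // 3) if len(cycles) - n_test > 1 else 0
    test_c = set(cycles[order[:n_test]])
    val_c = set(cycles[order[n_test : n_test + n_val]])
    out = {
        "train": manifest[~manifest[by_cycle].isin(test_c | val_c)].reset_index(drop=True),
        "val": manifest[manifest[by_cycle].isin(val_c)].reset_index(drop=True),
        "test": manifest[manifest[by_cycle].isin(test_c)].reset_index(drop=True),
    }
    return out


def write_run_record(out_dir: str | Path, config: dict, seed: int | None) -> Path:
    """Machine-readable reproducibility record written by every CLI command."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = {"config": config, "seed": seed, "version": __version__, "numpy": np.__version__}
    path = out / "run_record.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
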