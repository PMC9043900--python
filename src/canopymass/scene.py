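"""Synthetic overhead RGB-D canopy scenes with exact ground-truth biomass.

Emulates a high-density hydroponic lettuce tray imaged from a fixed
overhead RGB-D camera: a regular grid of rosette plants with positional
jitter, neighbor occlusion that grows with plant size, depth dropout
concentrated on tall canopy regions, and exposure variation in the color
channel.  Every plant's fresh mass is known exactly by construction
(a fixed allometric density applied to the plant's own height field), so
the generator supports parameter-recovery testing of biomass-regression
models without any real data.

Geometry and units
------------------
World coordinates are millimetres in the tray plane, heights in mm above
the tray.  The camera looks straight down from ``camera_height`` mm
(default 370).  Depth images are integers in 0.1 mm units: a background
(tray) pixel reads ``10 * camera_height`` = 3700, a surface at height
``h`` mm reads ``10 * (camera_height - h)``, and missing depth is 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

# depth sensor conventions
DEPTH_UNITS_PER_MM = 10
MAX_SCENE_DEPTH = 12000  # 0.1 mm units; the far limit of the scene
DEFAULT_CAMERA_HEIGHT_MM = 370.0
DEFAULT_GRID_SPACING_MM = 76.2  # three inches
DEFAULT_IMAGE_SIZE = (848, 480)  # (width, height)
DEFAULT_MM_PER_PIXEL = 0.9

# allometry: effective fresh-tissue density applied to the rosette height
# field.  A rosette is mostly air between leaves, so the effective value
# is well below the ~1 g/cm^3 of leaf tissue.
LEAF_DENSITY_G_PER_MM3 = 0.18e-3

# integration resolution (samples per axis across the plant bounding box)
# for ground-truth mass; the grid is plant-relative so mass scales exactly
# as the cube of linear size at fixed shape.
_MASS_GRID_N = 256

# depth dropout grows with local canopy height (stereo matching fails more
# on tall, self-shadowing, specular surfaces)
DEPTH_DROPOUT_HEIGHT_COEF = 0.30

_NOMINAL_JITTER_MM = 10.0  # positional tolerance of the camera gantry


@dataclass(frozen=True)
class PlantSpec:
    """Geometry of a single rosette plant.

    The rosette is a union of ``n_leaves`` elliptical-paraboloid lobes
    arranged radially around a central dome, rotated by ``phase``.  All
    linear dimensions scale with ``max_radius``/``max_height``, so mass
    is exactly cubic in linear scale at fixed shape.
    """

    plant_id: str
    grid_row: int = 0
    grid_col: int = 0
    center_offset: tuple[float, float] = (0.0, 0.0)  # mm jitter
    n_leaves: int = 0
    max_radius: float = 0.0  # mm
    max_height: float = 0.0  # mm
    phase: float = 0.0  # radians
    hue_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.max_radius < 0 or self.max_height < 0:
            raise ValueError("max_radius and max_height must be >= 0")
        if self.n_leaves < 0:
            raise ValueError("n_leaves must be >= 0")


@dataclass
class CanopyScene:
    """A procedural tray scene: plants on a jittered grid under a fixed camera."""

    plants: list[PlantSpec]
    grid_spacing: float = DEFAULT_GRID_SPACING_MM
    camera_height: float = DEFAULT_CAMERA_HEIGHT_MM  # mm
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE  # (width, height)
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL
    exposure_factor: float = 1.0
    depth_dropout_base: float = 0.02
    depth_dropout_height: float = DEPTH_DROPOUT_HEIGHT_COEF  # slope vs relative canopy height

    @property
    def background_depth(self) -> int:
        return int(round(self.camera_height * DEPTH_UNITS_PER_MM))

    def plant(self, plant_id: str) -> PlantSpec:
        for p in self.plants:
            if p.plant_id == plant_id:
                return p
        raise KeyError(f"plant {plant_id!r} not in scene")

    def plant_position(self, spec: PlantSpec) -> tuple[float, float]:
        """World position (mm) of a plant: nominal grid node plus jitter."""
        x = spec.grid_col * self.grid_spacing + spec.center_offset[0]
        y = spec.grid_row * self.grid_spacing + spec.center_offset[1]
        return x, y


@dataclass
class RGBDSample:
    """One aligned color+depth pair labeled with the center plant's mass."""

    rgb: np.ndarray  # H x W x 3 uint8
    depth: np.ndarray  # H x W int32, 0.1 mm units, 0 = missing
    mass_g: float
    plant_id: str
    timestamp: float | None = None
    treatment: str | None = None
    center_footprint: np.ndarray | None = None  # H x W bool; visible center-plant pixels

    def __post_init__(self) -> None:
        if self.mass_g < 0:
            raise ValueError("mass_g must be >= 0")
        if self.rgb.shape[:2] != self.depth.shape:
            raise ValueError(
                f"rgb {self.rgb.shape[:2]} and depth {self.depth.shape} disagree"
            )
        if self.depth.min() < 0 or self.depth.max() > MAX_SCENE_DEPTH:
            raise ValueError("depth values must lie in [0, 12000]")


@dataclass(frozen=True)
class StressSchedule:
    """Fertigation schedule: (day, solution) events, solution in {nutrient, water}."""

    treatment_id: str
    events: tuple[tuple[float, str], ...]
    n_plants: int = 27

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("schedule needs at least one event")
        days = [d for d, _ in self.events]
        if days != sorted(days):
            raise ValueError("events must be sorted by day")
        if days[0] != 0:
            raise ValueError("a day-0 event is required")
        for d, sol in self.events:
            if sol not in ("nutrient", "water"):
                raise ValueError(f"unknown solution {sol!r}")
        seen: dict[float, str] = {}
        for d, sol in self.events:
            if d in seen and seen[d] != sol:
                raise ValueError(f"conflicting events on day {d}")
            seen[d] = sol

    def solution_at(self, day: float) -> str:
        current = self.events[0][1]
        for d, sol in self.events:
            if d <= day:
                current = sol
        return current


def table1_schedules(n_plants: int = 27) -> list[StressSchedule]:
    """The four bundled treatment schedules (A: early pulse stress, B/C: mid
    stress with staggered recovery, D: unstressed control)."""
    return [
        StressSchedule("A", ((0, "nutrient"), (6, "water"), (11.7, "nutrient")), n_plants),
        StressSchedule(
            "B", ((0, "nutrient"), (11.7, "water"), (15.7, "water"), (21, "nutrient")), n_plants
        ),
        StressSchedule(
            "C", ((0, "nutrient"), (11.7, "water"), (15.7, "nutrient"), (21, "water")), n_plants
        ),
        StressSchedule("D", ((0, "nutrient"),), n_plants),
    ]


# ---------------------------------------------------------------------------
# rosette height field and ground-truth mass
# ---------------------------------------------------------------------------

def rosette_height(spec: PlantSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Surface height (mm) of a plant at points (x, y) relative to its center."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    h = np.zeros(np.broadcast(x, y).shape, dtype=np.float64)
    if spec.n_leaves == 0 or spec.max_radius <= 0 or spec.max_height <= 0:
        return h
    R, H = spec.max_radius, spec.max_height
    # central dome
    q = (x * x + y * y) / (0.45 * R) ** 2
    np.maximum(h, 0.6 * H * (1.0 - q), out=h)
    n = spec.n_leaves
    a = 0.50 * R  # radial semi-axis of a leaf lobe
    b = max(0.18 * R, 0.9 * np.pi * 0.55 * R / n)  # tangential semi-axis
    for k in range(n):
        phi = spec.phase + 2.0 * np.pi * k / n
        c, s = np.cos(phi), np.sin(phi)
        cx, cy = 0.55 * R * c, 0.55 * R * s
        dx, dy = x - cx, y - cy
        u = dx * c + dy * s
        v = -dx * s + dy * c
        q = (u / a) ** 2 + (v / b) ** 2
        hk = H * (0.75 + 0.25 * np.cos(2.3 * k))  # deterministic leaf-height variation
        np.maximum(h, hk * (1.0 - q), out=h)
    np.clip(h, 0.0, None, out=h)
    return h


def bounding_radius(spec: PlantSpec) -> float:
    """Radius (mm) of a disk guaranteed to contain the plant footprint."""
    return 1.1 * spec.max_radius


def true_mass(spec: PlantSpec, grid_n: int = _MASS_GRID_N) -> float:
    """Ground-truth fresh mass (g): density times un-occluded rosette volume.

    Integrated on a plant-relative grid, so it depends only on the plant's
    own geometry — never on neighbors, rendering, exposure, or dropout —
    and scales exactly as the cube of linear size at fixed shape.
    """
    if spec.n_leaves == 0 or spec.max_radius <= 0:
        return 0.0
    rb = bounding_radius(spec)
    # midpoint rule over the bounding box
    edges = np.linspace(-rb, rb, grid_n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    X, Y = np.meshgrid(centers, centers)
    h = rosette_height(spec, X, Y)
    cell = (2.0 * rb / grid_n) ** 2
    volume_mm3 = float(h.sum() * cell)
    return LEAF_DENSITY_G_PER_MM3 * volume_mm3


def make_plant(
    rng: np.random.Generator,
    target_mass_g: float,
    plant_id: str = "p0",
    grid_row: int = 0,
    grid_col: int = 0,
    jitter_mm: float = _NOMINAL_JITTER_MM,
) -> PlantSpec:
    """Sample a plant shape and scale it so ``true_mass`` hits the target.

    Shape parameters (leaf count, aspect ratio, phase, hue) are drawn from
    the generator; radius and height are then scaled jointly (fixed
    allometry), so the achieved mass matches ``target_mass_g`` exactly up
    to float precision, and 8x mass means exactly 2x linear dimensions.
    """
    if target_mass_g < 0:
        raise ValueError("target_mass_g must be >= 0")
    offset = tuple(rng.uniform(-jitter_mm, jitter_mm, size=2))
    if target_mass_g == 0:
        return PlantSpec(plant_id, grid_row, grid_col, offset, 0, 0.0, 0.0, 0.0, 0.0)
    n_leaves = int(rng.integers(6, 13))
    aspect = rng.uniform(0.35, 0.55)  # height / radius
    phase = rng.uniform(0.0, 2.0 * np.pi)
    hue_shift = float(np.clip(rng.normal(0.0, 0.03), -0.1, 0.1))
    r0 = 50.0
    unit = PlantSpec(plant_id, grid_row, grid_col, offset, n_leaves, r0, aspect * r0, phase, hue_shift)
    m_unit = true_mass(unit)
    scale = (target_mass_g / m_unit) ** (1.0 / 3.0)
    return dataclasses.replace(unit, max_radius=r0 * scale, max_height=aspect * r0 * scale)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _scene_heightmap(
    scene: CanopyScene, center: PlantSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-buffered height field over the image grid centered on ``center``.

    Returns (height mm, owner index, X, Y) where owner is -1 on background.
    The camera (and hence the image) is centered on the center plant's
    *nominal* grid node, not its jittered position.
    """
    W, Himg = scene.image_size
    cx = center.grid_col * scene.grid_spacing
    cy = center.grid_row * scene.grid_spacing
    xs = (np.arange(W) - (W - 1) / 2.0) * scene.mm_per_pixel + cx
    ys = (np.arange(Himg) - (Himg - 1) / 2.0) * scene.mm_per_pixel + cy
    X, Y = np.meshgrid(xs, ys)
    height = np.zeros((Himg, W), dtype=np.float64)
    owner = np.full((Himg, W), -1, dtype=np.int32)
    for idx, p in enumerate(scene.plants):
        px, py = scene.plant_position(p)
        rb = bounding_radius(p)
        if rb <= 0:
            continue
        # cull plants entirely outside the view
        if (
            px + rb < xs[0] or px - rb > xs[-1] or py + rb < ys[0] or py - rb > ys[-1]
        ):
            continue
        hp = rosette_height(p, X - px, Y - py)
        win = hp > height  # nearest surface wins
        height[win] = hp[win]
        owner[win] = idx
    return height, owner, X, Y


def render_scene(
    scene: CanopyScene,
    center_plant_id: str,
    rng: np.random.Generator,
    timestamp: float | None = None,
    treatment: str | None = None,
) -> RGBDSample:
    """Render an aligned RGB-D pair centered on one plant.

    Depth follows the sensor convention (0.1 mm units, tray background at
    ``scene.background_depth``, missing pixels 0); occlusion is genuine
    z-buffering, and per-pixel dropout probability increases with local
    canopy height.  The label is the center plant's occlusion-independent
    ground-truth mass.
    """
    center = scene.plant(center_plant_id)
    center_idx = scene.plants.index(center)
    hmax_allowed = scene.camera_height
    height, owner, _, _ = _scene_heightmap(scene, center)
    if height.max() >= hmax_allowed:
        raise ValueError("plant canopy reaches the camera plane")

    depth = np.rint(
        (scene.camera_height - height) * DEPTH_UNITS_PER_MM
    ).astype(np.int32)

    plant_mask = height > 0
    hscale = height.max() if height.max() > 0 else 1.0
    p_drop = np.clip(
        scene.depth_dropout_base + scene.depth_dropout_height * height / hscale, 0.0, 1.0
    )
    dropped = plant_mask & (rng.random(height.shape) < p_drop)
    depth[dropped] = 0

    # shaded green rosettes over a dark tray
    rgb = np.empty(height.shape + (3,), dtype=np.float64)
    rgb[..., 0] = 45.0
    rgb[..., 1] = 40.0
    rgb[..., 2] = 32.0
    if plant_mask.any():
        shade = 0.35 + 0.65 * (height / hscale)
        hue = np.zeros(height.shape)
        for idx, p in enumerate(scene.plants):
            hue[owner == idx] = p.hue_shift
        base_r = 60.0 * (1.0 + 2.0 * hue)
        base_g = 160.0
        base_b = 55.0 * (1.0 - 2.0 * hue)
        rgb[..., 0][plant_mask] = (shade * base_r)[plant_mask]
        rgb[..., 1][plant_mask] = (shade * base_g)[plant_mask]
        rgb[..., 2][plant_mask] = (shade * base_b)[plant_mask]
    rgb += rng.normal(0.0, 3.0, size=rgb.shape)
    rgb *= scene.exposure_factor
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    return RGBDSample(
        rgb=rgb,
        depth=depth,
        mass_g=true_mass(center),
        plant_id=center_plant_id,
        timestamp=timestamp,
        treatment=treatment,
        center_footprint=owner == center_idx,
    )


def occlusion_fraction(scene: CanopyScene, center_plant_id: str, grid_n: int = 200) -> float:
    """Fraction of the center plant's own footprint hidden by taller neighbors."""
    center = scene.plant(center_plant_id)
    if center.max_radius <= 0:
        return 0.0
    px, py = scene.plant_position(center)
    rb = bounding_radius(center)
    xs = np.linspace(px - rb, px + rb, grid_n)
    ys = np.linspace(py - rb, py + rb, grid_n)
    X, Y = np.meshgrid(xs, ys)
    own = rosette_height(center, X - px, Y - py)
    others = np.zeros_like(own)
    for p in scene.plants:
        if p.plant_id == center_plant_id:
            continue
        qx, qy = scene.plant_position(p)
        np.maximum(others, rosette_height(p, X - qx, Y - qy), out=others)
    fp = own > 0
    if not fp.any():
        return 0.0
    return float((others[fp] > own[fp]).mean())


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def sample_mass(rng: np.random.Generator) -> float:
    """Right-skewed fresh-mass draw over [0.1, 35] g (lognormal, median ~3 g)."""
    return float(np.clip(rng.lognormal(mean=np.log(3.0), sigma=1.0), 0.1, 35.0))


def make_neighborhood_scene(
    rng: np.random.Generator,
    center_mass_g: float,
    neighbor_rel: float = 0.30,
    grid_spacing: float = DEFAULT_GRID_SPACING_MM,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
    exposure_range: tuple[float, float] = (0.7, 1.3),
    depth_dropout_base: float = 0.02,
) -> tuple[CanopyScene, str]:
    """A 3x3 neighborhood: the labeled plant surrounded by eight neighbors
    of similar mass (within ``neighbor_rel``), mimicking the homogeneous
    cultivation of a production tray."""
    plants = []
    center_id = "c"
    for r in (-1, 0, 1):
        for c in (-1, 0, 1):
            if r == 0 and c == 0:
                m = center_mass_g
                pid = center_id
            else:
                m = max(0.1, center_mass_g * (1.0 + rng.uniform(-neighbor_rel, neighbor_rel)))
                pid = f"n{r}{c}"
            plants.append(make_plant(rng, m, plant_id=pid, grid_row=r, grid_col=c))
    scene = CanopyScene(
        plants=plants,
        grid_spacing=grid_spacing,
        image_size=image_size,
        mm_per_pixel=mm_per_pixel,
        exposure_factor=rng.uniform(*exposure_range),
        depth_dropout_base=depth_dropout_base,
    )
    return scene, center_id


def generate_samples(
    n_scenes: int,
    rng: np.random.Generator,
    mass_sampler: Callable[[np.random.Generator], float] = sample_mass,
    **scene_kwargs,
) -> list[RGBDSample]:
    """Generate ``n_scenes`` in-memory labeled RGB-D samples."""
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    samples = []
    for i in range(n_scenes):
        scene, cid = make_neighborhood_scene(rng, mass_sampler(rng), **scene_kwargs)
        s = render_scene(scene, cid, rng)
        s = dataclasses.replace(s, plant_id=f"plant_{i:05d}")
        samples.append(s)
    return samples


def generate_dataset(
    n_scenes: int,
    out_dir: str | Path,
    rng: np.random.Generator,
    seed: int | None = None,
    mass_sampler: Callable[[np.random.Generator], float] = sample_mass,
    **scene_kwargs,
) -> pd.DataFrame:
    """Write ``n_scenes`` RGB-D pairs as PNGs plus a CSV manifest; returns the manifest."""
    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    samples = generate_samples(n_scenes, rng, mass_sampler=mass_sampler, **scene_kwargs)
    for i, s in enumerate(samples):
        rgb_path = out / f"scene_{i:05d}_rgb.png"
        depth_path = out / f"scene_{i:05d}_depth.png"
        cio.write_rgbd(s, rgb_path, depth_path)
        rows.append(
            {
                "rgb_path": rgb_path.name,  # manifest-relative: dataset stays relocatable
                "depth_path": depth_path.name,
                "mass_g": s.mass_g,
                "plant_id": s.plant_id,
                "timestamp": 0.0,
                "treatment": "",
                "seed": seed if seed is not None else -1,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# growth experiments under stress schedules
# ---------------------------------------------------------------------------

def simulate_growth(
    schedules: Sequence[StressSchedule],
    n_timepoints: int,
    dt_hours: float = 8.0,
    rng: np.random.Generator | None = None,
    r_per_day: float = 0.20,
    carrying_capacity_g: float = 40.0,
    cv_r: float = 0.08,
    cv_k: float = 0.15,
    m0_g: float = 0.4,
    cv_m0: float = 0.25,
    lag_days: float = 1.0,
    suppression: float = 1.0,
) -> pd.DataFrame:
    """Per-plant logistic growth trajectories under fertigation schedules.

    m_{t+1} = m_t + r_t m_t (1 - m_t/K) dt.  During water (nutrient-
    deprivation) events the rate multiplier relaxes toward
    ``1 - suppression`` with first-order lag ``lag_days``; nutrient events
    relax it back to 1.  Plant-level lognormal-ish variation on r, K, m0.
    Returns a long DataFrame: plant_id, treatment, timepoint, time_days,
    mass_g.
    """
    if not schedules:
        raise ValueError("at least one schedule required")
    if rng is None:
        rng = np.random.default_rng(0)
    dt_days = dt_hours / 24.0
    rows = []
    for sched in schedules:
        for j in range(sched.n_plants):
            r_i = r_per_day * max(0.05, 1.0 + cv_r * rng.standard_normal())
            k_i = carrying_capacity_g * max(0.2, 1.0 + cv_k * rng.standard_normal())
            m = m0_g * max(0.2, 1.0 + cv_m0 * rng.standard_normal())
            target0 = 1.0 - suppression if sched.solution_at(0.0) == "water" else 1.0
            s = target0
            for t in range(n_timepoints):
                day = t * dt_days
                rows.append(
                    {
                        "plant_id": f"{sched.treatment_id}_{j:03d}",
                        "treatment": sched.treatment_id,
                        "timepoint": t,
                        "time_days": day,
                        "mass_g": m,
                    }
                )
                target = 1.0 - suppression if sched.solution_at(day) == "water" else 1.0
                if lag_days <= 0:
                    s = target
                else:
                    s += (target - s) * min(1.0, dt_days / lag_days)
                m = m + r_i * s * m * (1.0 - m / k_i) * dt_days
    return pd.DataFrame(rows)


def generate_growth_experiment(
    schedules: Sequence[StressSchedule],
    n_timepoints: int,
    dt_hours: float = 8.0,
    rng: np.random.Generator | None = None,
    render: bool = False,
    out_dir: str | Path | None = None,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
    grid_spacing: float = DEFAULT_GRID_SPACING_MM,
    **growth_kwargs,
) -> pd.DataFrame:
    """A multi-timepoint stress experiment: trajectories plus optional scenes.

    Plants from all treatments are randomized onto one rectangular grid
    (as in a drip-fertigated tray with per-site solution control).  With
    ``render=True`` every plant is imaged at every timepoint, each plant
    keeping a fixed shape over time and rescaling with its current mass;
    PNGs and a manifest are written to ``out_dir``.  Ground-truth
    trajectories are always returned.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    traj = simulate_growth(
        schedules, n_timepoints, dt_hours=dt_hours, rng=rng, **growth_kwargs
    )
    if not render:
        return traj

    from . import io as cio

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    plant_ids = sorted(traj["plant_id"].unique())
    n_plants = len(plant_ids)
    ncols = int(np.ceil(np.sqrt(n_plants)))
    order = rng.permutation(n_plants)  # completely randomized spatial layout
    shape_specs: dict[str, PlantSpec] = {}
    positions: dict[str, tuple[int, int]] = {}
    for slot, idx in enumerate(order):
        pid = plant_ids[idx]
        positions[pid] = (slot // ncols, slot % ncols)
        r, c = positions[pid]
        shape_specs[pid] = make_plant(rng, 1.0, plant_id=pid, grid_row=r, grid_col=c)

    unit_masses = {pid: true_mass(sp) for pid, sp in shape_specs.items()}
    rows = []
    treatments = dict(zip(traj["plant_id"], traj["treatment"]))
    for t, group in traj.groupby("timepoint"):
        masses = dict(zip(group["plant_id"], group["mass_g"]))
        plants = []
        for pid in plant_ids:
            sp = shape_specs[pid]
            scale = (masses[pid] / unit_masses[pid]) ** (1.0 / 3.0)
            plants.append(
                dataclasses.replace(
                    sp, max_radius=sp.max_radius * scale, max_height=sp.max_height * scale
                )
            )
        scene = CanopyScene(
            plants=plants,
            grid_spacing=grid_spacing,
            image_size=image_size,
            mm_per_pixel=mm_per_pixel,
        )
        day = float(group["time_days"].iloc[0])
        for pid in plant_ids:
            sample = render_scene(scene, pid, rng, timestamp=day, treatment=treatments[pid])
            if out is not None:
                rgb_path = out / f"t{t:03d}_{pid}_rgb.png"
                depth_path = out / f"t{t:03d}_{pid}_depth.png"
                cio.write_rgbd(sample, rgb_path, depth_path)
                rows.append(
                    {
                        "rgb_path": rgb_path.name,
                        "depth_path": depth_path.name,
                        "mass_g": sample.mass_g,
                        "plant_id": pid,
                        "timestamp": day,
                        "treatment": treatments[pid],
                        "seed": -1,
                    }
                )
    if out is not None:
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
        traj.to_csv(out / "trajectories.csv", index=False)
    return traj
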