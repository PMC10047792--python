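"""Random circular-anomaly phantoms, labelled point clouds and datasets.

A phantom is 1-4 circular inclusions on a constant background conductivity
of 1 inside the unit disk.  Each inclusion has a random radius, a random
centre (uniform over the positions where it fits with a small margin) and a
random conductivity contrast, drawn log-uniformly over [0.2, 5] with a dead
zone around the background value so every inclusion has nonzero contrast.

Point labels are defined on the continuous domain: a point is anomalous iff
it lies strictly inside at least one inclusion circle, independent of any
mesh.  Training point clouds are stratified: equal numbers of uniform
samples from the background region and from the anomalous region, so small
inclusions are not underrepresented.

Measurement noise of level ``delta`` percent adds i.i.d. Gaussian noise with
standard deviation ``max(|m|) * delta / 100``, the maximum magnitude over
the entries of the clean measurement vector.  (The magnitude is used
because the overall sign of the adjacent-pair differences is a pure
convention — flipping the drive orientation flips every entry — and a noise
scale must be sign-invariant.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .forward import ConductivityField, ForwardSolver, MeasurementVector
from .mesh import TriMesh, triangle_centroids

__all__ = [
    "Circle",
    "Phantom",
    "PointCloud",
    "NoiseSpec",
    "NormalizationStats",
    "DatasetRecord",
    "Dataset",
    "DatasetConfig",
    "sample_phantom",
    "rasterize",
    "label_point",
    "label_points",
    "sample_point_cloud",
    "add_noise",
    "fit_normalization",
    "apply_normalization",
    "normalize_points",
    "build_dataset",
]

BACKGROUND_CONDUCTIVITY = 1.0
RADIUS_RANGE = (0.1, 0.35)
CONDUCTIVITY_RANGE = (0.2, 5.0)
CONDUCTIVITY_DEAD_ZONE = (0.8, 1.25)
PLACEMENT_MARGIN = 0.05


@dataclass(frozen=True)
class Circle:
    center: tuple[float, float]
    radius: float
    conductivity: float


@dataclass
class Phantom:
    """Ground-truth conductivity: circles over constant background 1."""

    circles: list[Circle] = field(default_factory=list)
    background_conductivity: float = BACKGROUND_CONDUCTIVITY

    def __post_init__(self) -> None:
        if not 0 <= len(self.circles) <= 4:
            raise ValueError("phantom supports 0-4 circular anomalies")
        for c in self.circles:
            if np.hypot(*c.center) + c.radius > 1.0 - PLACEMENT_MARGIN + 1e-12:
                raise ValueError(f"circle {c} not inside the disk with margin")
            if c.radius <= 0 or c.conductivity <= 0:
                raise ValueError(f"invalid circle {c}")

    @property
    def n_anomalies(self) -> int:
        return len(self.circles)

    def anomaly_area(self) -> float:
        """Area of the union of inclusion circles (Monte-Carlo-free for
        disjoint circles; overlapping circles are rare and slightly
        overcounted — used only for diagnostics)."""
        return float(sum(np.pi * c.radius**2 for c in self.circles))

    def to_dict(self) -> dict:
        return {
            "background": self.background_conductivity,
            "circles": [
                {"center": list(c.center), "radius": c.radius, "conductivity": c.conductivity}
                for c in self.circles
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Phantom":
        return cls(
            circles=[
                Circle(tuple(c["center"]), c["radius"], c["conductivity"])
                for c in d["circles"]
            ],
            background_conductivity=d.get("background", BACKGROUND_CONDUCTIVITY),
        )


@dataclass
class PointCloud:
    """Continuous-domain points with binary labels (0 background, 1 anomaly)."""

    points: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.points) != len(self.labels):
            raise ValueError("points/labels length mismatch")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise level ``delta`` in percent."""

    delta: float

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("noise level must be nonnegative")


@dataclass
class NormalizationStats:
    """0-1 normalisation constants fitted on the training split only.

    Measurements use either a single scalar min/max over all training
    entries (default) or per-channel min/max vectors; points map the disk
    coordinates from [-1, 1] to [0, 1] per coordinate.
    """

    m_min: float | np.ndarray
    m_max: float | np.ndarray
    point_lo: float = -1.0
    point_hi: float = 1.0

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.m_max) > np.asarray(self.m_min)):
            raise ValueError("degenerate measurement range: max must exceed min")
        if not self.point_hi > self.point_lo:
            raise ValueError("degenerate point range")

    @property
    def per_channel(self) -> bool:
        return np.ndim(self.m_min) > 0

    def to_dict(self) -> dict:
        return {
            "m_min": np.asarray(self.m_min).tolist(),
            "m_max": np.asarray(self.m_max).tolist(),
            "point_lo": self.point_lo,
            "point_hi": self.point_hi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        m_min, m_max = d["m_min"], d["m_max"]
        if isinstance(m_min, list):
            m_min, m_max = np.array(m_min), np.array(m_max)
        return cls(m_min=m_min, m_max=m_max,
                   point_lo=d.get("point_lo", -1.0), point_hi=d.get("point_hi", 1.0))


@dataclass
class DatasetRecord:
    """One simulated experiment: phantom, clean measurements, seed, split."""

    phantom: Phantom
    measurements: MeasurementVector
    seed: int
    split: str = "train"


@dataclass
class Dataset:
    records: list[DatasetRecord]
    mesh: TriMesh
    master_seed: int

    def __len__(self) -> int:
        return len(self.records)

    def measurement_matrix(self) -> np.ndarray:
        return np.stack([r.measurements.values for r in self.records])


# -- sampling -------------------------------------------------------------


def _sample_contrast(rng: np.random.Generator) -> float:
    """Log-uniform over [0.2, 5] excluding the dead zone (0.8, 1.25)."""
    lo, hi = np.log(CONDUCTIVITY_RANGE[0]), np.log(CONDUCTIVITY_RANGE[1])
    while True:
        c = float(np.exp(rng.uniform(lo, hi)))
        if not (CONDUCTIVITY_DEAD_ZONE[0] < c < CONDUCTIVITY_DEAD_ZONE[1]):
            return c


def sample_phantom(rng: np.random.Generator, n_anomalies: int) -> Phantom:
    """Draw a random phantom with ``n_anomalies`` circles (0 allowed for
    homogeneous fixtures)."""
    if not 0 <= n_anomalies <= 4:
        raise ValueError("n_anomalies must be in 0..4")
    circles = []
    for _ in range(n_anomalies):
        r = float(rng.uniform(*RADIUS_RANGE))
        rmax = 1.0 - PLACEMENT_MARGIN - r
        # uniform over the disk of radius rmax
        rho = rmax * np.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * np.pi)
        circles.append(
            Circle(
                center=(float(rho * np.cos(ang)), float(rho * np.sin(ang))),
                radius=r,
                conductivity=_sample_contrast(rng),
            )
        )
    return Phantom(circles=circles)


def rasterize(phantom: Phantom, mesh: TriMesh) -> ConductivityField:
    """Per-triangle conductivity: a triangle takes a circle's value iff its
    centroid lies inside the circle; later circles override earlier ones."""
    cent = triangle_centroids(mesh)
    sigma = np.full(mesh.n_triangles, phantom.background_conductivity)
    for c in phantom.circles:
        inside = np.hypot(cent[:, 0] - c.center[0], cent[:, 1] - c.center[1]) < c.radius
        sigma[inside] = c.conductivity
    return ConductivityField(mesh, sigma)


def label_points(phantom: Phantom, points: np.ndarray) -> np.ndarray:
    """Vectorised continuous-domain labels: 1 iff strictly inside any circle."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[None, :]
    if np.any(np.hypot(pts[:, 0], pts[:, 1]) > 1.0 + 1e-9):
        raise ValueError("point outside the closed unit disk")
    lab = np.zeros(len(pts), dtype=np.int64)
    for c in phantom.circles:
        d = np.hypot(pts[:, 0] - c.center[0], pts[:, 1] - c.center[1])
        lab[d < c.radius] = 1
    return lab


def label_point(phantom: Phantom, p: Sequence[float]) -> int:
    """Label of a single point: 1 iff strictly inside any inclusion circle."""
    return int(label_points(phantom, np.asarray(p))[0])


def _uniform_disk(rng: np.random.Generator, n: int) -> np.ndarray:
    rho = np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([rho * np.cos(ang), rho * np.sin(ang)])


def _sample_region(
    phantom: Phantom, n: int, anomalous: bool, rng: np.random.Generator
) -> np.ndarray:
    """Uniform samples from the background or anomalous region.

    Background: rejection from the uniform disk.  Anomalous region: propose
    from an area-weighted mixture of the circles and accept with probability
    1/(number of covering circles), which is exactly uniform on the union.
    """
    out = np.empty((0, 2))
    if anomalous:
        areas = np.array([c.radius**2 for c in phantom.circles], dtype=float)
        probs = areas / areas.sum()
        centers = np.array([c.center for c in phantom.circles])
        radii = np.array([c.radius for c in phantom.circles])
    while len(out) < n:
        batch = max(4 * (n - len(out)), 64)
        if anomalous:
            which = rng.choice(len(probs), size=batch, p=probs)
            local = _uniform_disk(rng, batch) * radii[which, None]
            pts = centers[which] + local
            cover = np.zeros(batch)
            for c in phantom.circles:
                cover += (
                    np.hypot(pts[:, 0] - c.center[0], pts[:, 1] - c.center[1]) < c.radius
                )
            keep = rng.uniform(size=batch) * cover < 1.0
            pts = pts[keep & (cover > 0)]
        else:
            pts = _uniform_disk(rng, batch)
            pts = pts[label_points(phantom, pts) == 0]
        out = np.vstack([out, pts])
    return out[:n]


def sample_point_cloud(
    phantom: Phantom, n_per_stratum: int, rng: np.random.Generator
) -> PointCloud:
    """Balanced stratified cloud: ``n_per_stratum`` uniform points from the
    background region and the same number from the anomalous region,
    shuffled together."""
    if n_per_stratum > 0 and phantom.n_anomalies == 0:
        raise ValueError("phantom has no anomalous region to sample from")
    bg = _sample_region(phantom, n_per_stratum, anomalous=False, rng=rng)
    an = _sample_region(phantom, n_per_stratum, anomalous=True, rng=rng)
    pts = np.vstack([bg, an])
    labels = np.concatenate(
        [np.zeros(n_per_stratum, np.int64), np.ones(n_per_stratum, np.int64)]
    )
    perm = rng.permutation(len(pts))
    return PointCloud(points=pts[perm], labels=labels[perm])


def add_noise(
    m: MeasurementVector, spec: NoiseSpec, rng: np.random.Generator
) -> MeasurementVector:
    """Additive Gaussian noise with std ``max(|m|) * delta / 100``."""
    if spec.delta == 0:
        return MeasurementVector(m.values.copy(), m.n_electrodes)
    std = float(np.max(np.abs(m.values))) * spec.delta / 100.0
    noisy = m.values + rng.normal(0.0, std, size=len(m.values))
    return MeasurementVector(noisy, m.n_electrodes)


# -- normalisation --------------------------------------------------------


def fit_normalization(
    train_measurements: np.ndarray | Iterable, per_channel: bool = False
) -> NormalizationStats:
    """Min/max 0-1 statistics over the training measurement matrix.

    Scalar (one min/max over all entries) by default; ``per_channel=True``
    fits one min/max per measurement channel, which expands the small
    between-experiment variation of each channel to the full input range.
    """
    if isinstance(train_measurements, np.ndarray):
        M = train_measurements
    else:
        M = np.stack([np.asarray(getattr(r, "values", r)) for r in train_measurements])
    if M.size == 0:
        raise ValueError("empty training set")
    if per_channel:
        return NormalizationStats(m_min=M.min(axis=0), m_max=M.max(axis=0))
    return NormalizationStats(m_min=float(M.min()), m_max=float(M.max()))


def apply_normalization(x: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Affine 0-1 map fitted on training data; values outside the training
    range map outside [0, 1] (no clipping)."""
    return (np.asarray(x, dtype=np.float64) - stats.m_min) / (stats.m_max - stats.m_min)


def normalize_points(points: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Map point coordinates from [-1, 1] to [0, 1] per coordinate."""
    lo, hi = stats.point_lo, stats.point_hi
    return (np.asarray(points, dtype=np.float64) - lo) / (hi - lo)


# -- dataset construction -------------------------------------------------


@dataclass(frozen=True)
class DatasetConfig:
    """Composition of a simulated dataset.

    The full-size study uses 4,096 training phantoms per anomaly count 1-4
    (16,384 total) and 1,024 validation phantoms; the "small" preset scales
    this to 2,000 / 200 for single-workstation runs.
    """

    n_train_per_class: int = 4096
    n_val: int = 1024
    master_seed: int = 0

    @classmethod
    def small(cls, master_seed: int = 0) -> "DatasetConfig":
        return cls(n_train_per_class=500, n_val=200, master_seed=master_seed)


def _simulate_records(
    mesh: TriMesh,
    n_per_class: Sequence[int],
    seeds: np.ndarray,
    split: str,
) -> list[DatasetRecord]:
    records = []
    i = 0
    for n_anom, count in zip((1, 2, 3, 4), n_per_class):
        for _ in range(count):
            seed = int(seeds[i])
            rng = np.random.default_rng(seed)
            phantom = sample_phantom(rng, n_anom)
            m = ForwardSolver(rasterize(phantom, mesh)).measure()
            records.append(
                DatasetRecord(phantom=phantom, measurements=m, seed=seed, split=split)
            )
            i += 1
    return records


def build_dataset(
    config: DatasetConfig, mesh: TriMesh, split: str = "train"
) -> Dataset:
    """Simulate a dataset of (phantom, clean measurement) records.

    Fully reproducible: per-record seeds are spawned from the master seed
    with a counter-based scheme, and each record is regenerable bit-exactly
    from (phantom seed, mesh).  Noise is never stored; it is drawn fresh at
    use time.
    """
    if split == "train":
        total = 4 * config.n_train_per_class
        per_class = [config.n_train_per_class] * 4
        stream = 0
    elif split in ("val", "validation"):
        total = config.n_val
        base = config.n_val // 4
        per_class = [base] * 4
        per_class[-1] += config.n_val - 4 * base
        stream = 1
    else:
        raise ValueError(f"unknown split {split!r}")
    ss = np.random.SeedSequence(entropy=config.master_seed, spawn_key=(stream,))
    seeds = ss.generate_state(total, dtype=np.uint32) % (2**31)
    records = _simulate_records(mesh, per_class, seeds, split)
    return Dataset(records=records, mesh=mesh, master_seed=config.master_seed)
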