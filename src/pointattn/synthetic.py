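"""Synthetic labeled point clouds for end-to-end testing without downloads.

Two regimes are emulated. Shape mode mimics CAD-derived single-object
clouds: uniform surface samples of parametric solids, unit-normalized, with
Gaussian jitter. Volume mode mimics clouds sampled from 3-D density maps
(as in cryo-ET subtomogram analysis): a fixed number of points drawn with
probability proportional to a mixture-of-Gaussians voxel density.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PointCloud

__all__ = [
    "FAMILIES", "PART_CATEGORIES", "ShapeSpec", "VolumeSpec",
    "make_shape", "make_part_labeled_shape", "sample_volume",
    "make_dataset", "category_part_sets", "nearest_centroid_baseline",
]

FAMILIES = ("sphere", "cube", "torus", "cylinder", "cone")

# families that decompose into parts, with global part ids
# (ShapeNet-style: one contiguous label space across categories)
PART_CATEGORIES = ("cylinder", "cone")
_PART_IDS = {"cylinder": (0, 1, 2),      # side, top cap, bottom cap
             "cone": (3, 4)}             # side, base


def category_part_sets() -> dict[int, list[int]]:
    """Admissible global part ids per category index."""
    return {i: list(_PART_IDS[f]) for i, f in enumerate(PART_CATEGORIES)}


@dataclass
class ShapeSpec:
    family: str
    n: int = 1024
    jitter: float = 0.01              # Gaussian sigma in normalized units
    seed: int = 0
    size: dict = field(default_factory=dict)


@dataclass
class VolumeSpec:
    grid: tuple[int, int, int] = (32, 32, 32)
    centers: np.ndarray = None        # (M, 3) blob centers in [0,1]^3
    widths: np.ndarray = None         # (M,) Gaussian sigmas
    weights: np.ndarray = None        # (M,) non-negative mixture weights
    n: int = 1024
    seed: int = 0
    normalize: bool = True


# ---------------------------------------------------------------------------
# surface samplers (canonical orientation: symmetry axis along z)

def _sample_sphere(rng, n, size):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * size.get("radius", 1.0), None


def _sample_cube(rng, n, size):
    h = size.get("half_side", 1.0)
    face = rng.integers(0, 6, size=n)
    uv = rng.uniform(-h, h, size=(n, 2))
    pts = np.empty((n, 3))
    axis = face // 2
    sign = np.where(face % 2 == 0, h, -h)
    for a in range(3):
        sel = axis == a
        pts[sel, a] = sign[sel]
        others = [i for i in range(3) if i != a]
        pts[np.ix_(sel, others)] = uv[sel]
    return pts, None


def _sample_torus(rng, n, size):
    R = size.get("major", 1.0)
    r = size.get("minor", 0.4)
    # area element is proportional to R + r*cos(u): rejection sample u
    u = np.empty(0)
    while len(u) < n:
        cand = rng.uniform(0, 2 * np.pi, size=2 * n)
        accept = rng.uniform(0, R + r, size=2 * n) < R + r * np.cos(cand)
        u = np.concatenate([u, cand[accept]])
    u = u[:n]
    v = rng.uniform(0, 2 * np.pi, size=n)
    x = (R + r * np.cos(u)) * np.cos(v)
    y = (R + r * np.cos(u)) * np.sin(v)
    z = r * np.sin(u)
    return np.column_stack([x, y, z]), None


def _sample_cylinder(rng, n, size):
    r = size.get("radius", 0.4)
    h = size.get("height", 1.6)
    a_side = 2 * np.pi * r * h
    a_cap = np.pi * r ** 2
    p = np.array([a_side, a_cap, a_cap])
    which = rng.choice(3, size=n, p=p / p.sum())
    pts = np.empty((n, 3))
    labels = np.empty(n, dtype=np.int64)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    side = which == 0
    pts[side] = np.column_stack([r * np.cos(theta[side]),
                                 r * np.sin(theta[side]),
                                 rng.uniform(-h / 2, h / 2, size=side.sum())])
    labels[side] = _PART_IDS["cylinder"][0]
    for j, zcap in ((1, h / 2), (2, -h / 2)):
        cap = which == j
        rad = r * np.sqrt(rng.uniform(0, 1, size=cap.sum()))
        pts[cap] = np.column_stack([rad * np.cos(theta[cap]),
                                    rad * np.sin(theta[cap]),
                                    np.full(cap.sum(), zcap)])
        labels[cap] = _PART_IDS["cylinder"][j]
    return pts, labels


def _sample_cone(rng, n, size):
    r = size.get("radius", 0.6)
    h = size.get("height", 1.2)
    slant = np.sqrt(r ** 2 + h ** 2)
    a_side = np.pi * r * slant
    a_base = np.pi * r ** 2
    which = rng.choice(2, size=n, p=np.array([a_side, a_base]) / (a_side + a_base))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    pts = np.empty((n, 3))
    labels = np.empty(n, dtype=np.int64)
    side = which == 0
    # uniform on lateral surface: radial coordinate ~ sqrt(U)
    t = np.sqrt(rng.uniform(0, 1, size=side.sum()))
    pts[side] = np.column_stack([r * t * np.cos(theta[side]),
                                 r * t * np.sin(theta[side]),
                                 h / 2 - h * t])
    labels[side] = _PART_IDS["cone"][0]
    base = ~side
    rad = r * np.sqrt(rng.uniform(0, 1, size=base.sum()))
    pts[base] = np.column_stack([rad * np.cos(theta[base]),
                                 rad * np.sin(theta[base]),
                                 np.full(base.sum(), -h / 2)])
    labels[base] = _PART_IDS["cone"][1]
    return pts, labels


_SAMPLERS = {
    "sphere": _sample_sphere,
    "cube": _sample_cube,
    "torus": _sample_torus,
    "cylinder": _sample_cylinder,
    "cone": _sample_cone,
}


def _finalize(pts: np.ndarray, labels, spec: ShapeSpec,
              rng: np.random.Generator, family_label: int) -> PointCloud:
    # scale about the analytic center (origin) so surface identities
    # such as |max coordinate| = half-side survive normalization exactly
    pts = pts / np.linalg.norm(pts, axis=1).max()
    if spec.jitter > 0:
        pts = pts + rng.normal(scale=spec.jitter, size=pts.shape)
    return PointCloud(pts, point_labels=labels, cloud_label=family_label)


def make_shape(spec: ShapeSpec) -> PointCloud:
    """Uniform surface sample of one family, unit-normalized then jittered."""
    if spec.family not in _SAMPLERS:
        raise ValueError(f"unknown family '{spec.family}'")
    if spec.n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(spec.seed)
    pts, labels = _SAMPLERS[spec.family](rng, spec.n, spec.size)
    cloud = _finalize(pts, None, spec, rng, FAMILIES.index(spec.family))
    return cloud


def make_part_labeled_shape(spec: ShapeSpec) -> PointCloud:
    """As make_shape, keeping the analytic per-point part labels."""
    if spec.family not in PART_CATEGORIES:
        raise ValueError(f"family '{spec.family}' has no part decomposition")
    rng = np.random.default_rng(spec.seed)
    pts, labels = _SAMPLERS[spec.family](rng, spec.n, spec.size)
    cloud = _finalize(pts, labels, spec, rng,
                      PART_CATEGORIES.index(spec.family))
    return cloud


# ---------------------------------------------------------------------------
# density-volume sampling

def _density_grid(spec: VolumeSpec) -> np.ndarray:
    d = np.zeros(spec.grid)
    axes = [np.linspace(0, 1, g, endpoint=False) + 0.5 / g for g in spec.grid]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.atleast_2d(np.asarray(spec.centers, dtype=float))
    widths = np.broadcast_to(np.asarray(spec.widths, dtype=float), len(centers))
    weights = (np.ones(len(centers)) if spec.weights is None
               else np.broadcast_to(np.asarray(spec.weights, dtype=float),
                                    len(centers)))
    for c, w, a in zip(centers, widths, weights):
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        d += a * np.exp(-r2 / (2 * w ** 2))
    return d


def sample_volume(spec: VolumeSpec) -> PointCloud:
    """Draw exactly n points with probability proportional to voxel
    density (with-replacement categorical draw + intra-voxel uniform
    jitter), emulating fixed-size clouds sampled from a 3-D image."""
    density = _density_grid(spec)
    if density.sum() <= 0:
        raise ValueError("density has zero total mass")
    rng = np.random.default_rng(spec.seed)
    p = density.ravel() / density.sum()
    flat = rng.choice(len(p), size=spec.n, replace=True, p=p)
    ijk = np.column_stack(np.unravel_index(flat, spec.grid)).astype(float)
    ijk += rng.uniform(0, 1, size=ijk.shape)
    pts = ijk / np.asarray(spec.grid, dtype=float)   # back to [0,1]^3
    if spec.normalize:
        pts = pts - pts.mean(axis=0)
        pts = pts / np.linalg.norm(pts, axis=1).max()
    return PointCloud(pts)


# ---------------------------------------------------------------------------
# dataset assembly

def _volume_layout(class_rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = int(class_rng.integers(2, 6))
    centers = class_rng.uniform(0.25, 0.75, size=(m, 3))
    widths = class_rng.uniform(0.04, 0.12, size=m)
    weights = class_rng.uniform(0.5, 1.5, size=m)
    return centers, widths, weights


def make_dataset(n_classes: int, per_class: int, split: float = 0.8,
                 seed: int = 0, mode: str = "shapes", n_points: int = 1024,
                 jitter: float = 0.01) -> tuple[list[PointCloud], list[PointCloud]]:
    """Stratified, disjoint, reproducible (train, test) collections.

    mode='shapes' uses the first n_classes parametric families;
    mode='volumes' builds n_classes random-but-fixed blob layouts (at the
    scale of typical subtomogram studies that is 7 classes of 400 clouds
    each).
    """
    if per_class < 2:
        raise ValueError("per_class must be at least 2")
    if not 0 < split < 1:
        raise ValueError("split must lie in (0,1)")
    if mode == "shapes" and n_classes > len(FAMILIES):
        raise ValueError(f"at most {len(FAMILIES)} shape families available")
    n_train = int(round(per_class * split))
    if n_train < 1 or n_train >= per_class:
        raise ValueError("split leaves an empty train or test side")
    train: list[PointCloud] = []
    test: list[PointCloud] = []
    for cls in range(n_classes):
        if mode == "volumes":
            layout = _volume_layout(
                np.random.default_rng(np.random.SeedSequence((seed, cls))))
        for idx in range(per_class):
            item_seed = np.random.SeedSequence((seed, cls, idx))
            if mode == "shapes":
                cloud = make_shape(ShapeSpec(FAMILIES[cls], n=n_points,
                                             jitter=jitter, seed=item_seed))
            elif mode == "volumes":
                centers, widths, weights = layout
                cloud = sample_volume(VolumeSpec(
                    centers=centers, widths=widths, weights=weights,
                    n=n_points, seed=item_seed))
                cloud.cloud_label = cls
            else:
                raise ValueError(f"unknown mode '{mode}'")
            (train if idx < n_train else test).append(cloud)
    return train, test


def make_part_dataset(per_class: int, split: float = 0.8, seed: int = 0,
                      n_points: int = 1024, jitter: float = 0.01
                      ) -> tuple[list[PointCloud], list[PointCloud]]:
    """Stratified part-labeled (train, test) over the part-bearing
    families; cloud_label is the category index used for one-hot tiling."""
    if per_class < 2:
        raise ValueError("per_class must be at least 2")
    n_train = int(round(per_class * split))
    train: list[PointCloud] = []
    test: list[PointCloud] = []
    for ci, family in enumerate(PART_CATEGORIES):
        for idx in range(per_class):
            spec = ShapeSpec(family, n=n_points, jitter=jitter,
                             seed=np.random.SeedSequence((seed, ci, idx)))
            cloud = make_part_labeled_shape(spec)
            (train if idx < n_train else test).append(cloud)
    return train, test


# ---------------------------------------------------------------------------
# separability baseline

def _radial_descriptor(cloud: PointCloud, bins: int = 16) -> np.ndarray:
    r = np.linalg.norm(cloud.coords - cloud.coords.mean(axis=0), axis=1)
    hist, _ = np.histogram(r, bins=bins, range=(0, 1.5), density=True)
    return hist


def nearest_centroid_baseline(train: list[PointCloud],
                              test: list[PointCloud]) -> float:
    """Accuracy (%) of a nearest-centroid rule on radial histograms; a
    cheap lower bound certifying that the class geometry is separable."""
    X = np.stack([_radial_descriptor(c) for c in train])
    y = np.array([c.cloud_label for c in train])
    centroids = {cls: X[y == cls].mean(axis=0) for cls in np.unique(y)}
    classes = np.array(sorted(centroids))
    C = np.stack([centroids[c] for c in classes])
    Xt = np.stack([_radial_descriptor(c) for c in test])
    yt = np.array([c.cloud_label for c in test])
    pred = classes[np.argmin(((Xt[:, None, :] - C[None]) ** 2).sum(-1), axis=1)]
    return 100.0 * float((pred == yt).mean())
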