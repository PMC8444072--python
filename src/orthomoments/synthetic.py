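"""Synthetic image generators with the statistical structure the pipeline assumes.

Two designs are emulated:

* multi-class binary *wing* images — a fixed venation skeleton of 19
  control points (returned as paired landmarks) whose positions are
  displaced per class by an effect size ``delta`` and jittered per
  sample, rasterized as thick polylines inside a half-elliptic outline;
* two-class grayscale *mass* regions of interest — benign masses are
  smooth ellipses with a sharp sigmoidal margin, malignant masses are
  spiculated radial stars ``r(theta) = r0 (1 + a |sin(k theta / 2)|^g)``
  with a blurred margin, both embedded in correlated background noise,
  each paired with five categorical expert features drawn from
  class-conditional tables.

Every generator is a pure function of (spec, seed): per-image random
substreams are derived from the seed by counter, so a sample does not
depend on batch order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, morphology

__all__ = [
    "WingSpec",
    "MassSpec",
    "gen_wings",
    "gen_masses",
    "landmark_features",
    "table_mutual_information",
    "DEFAULT_EXPERT_TABLES",
]

# 19 venation control points in unit coordinates (u = along width,
# v = along height); arbitrary but fixed layout
_BASE_LANDMARKS_UV = np.array(
    [
        (0.03, 0.50), (0.15, 0.35), (0.15, 0.65), (0.30, 0.25), (0.30, 0.50),
        (0.30, 0.75), (0.45, 0.18), (0.45, 0.42), (0.45, 0.60), (0.45, 0.82),
        (0.60, 0.30), (0.60, 0.52), (0.60, 0.72), (0.75, 0.22), (0.75, 0.45),
        (0.75, 0.65), (0.88, 0.35), (0.88, 0.55), (0.95, 0.48),
    ]
)

# six veins as polylines through the control points above
_VEINS = (
    (0, 1, 3, 6, 13, 16, 18),
    (0, 4, 7, 10, 14, 17, 18),
    (0, 2, 5, 8, 11, 15, 18),
    (2, 5, 9, 12, 15),
    (3, 4, 5),
    (13, 14, 15),
)


@dataclass(frozen=True)
class WingSpec:
    """Generator settings for multi-class wing-like binary images.

    ``delta`` displaces each class's vein control points by a fixed
    magnitude in a class-specific random direction (between-class
    effect); ``jitter`` is the within-class Gaussian sd of control
    points in pixels.  ``class_sizes`` overrides ``n_per_class`` when
    given (e.g. 14 classes of 5 plus one of 4 gives the 74-sample
    design).
    """

    n_classes: int = 15
    n_per_class: int = 5
    height: int = 254
    width: int = 724
    delta: float = 3.0
    jitter: float = 1.0
    thickness: int = 3
    speckle_rate: float = 0.0005
    seed: int = 0
    class_sizes: tuple[int, ...] | None = None
    #: shift of the per-sample substream counter; batches generated from
    #: the same seed but different offsets share the class geometry and
    #: differ only in within-class jitter (fresh samples from the same
    #: population, e.g. an independent held-out batch)
    sample_offset: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.delta < 0 or self.jitter <= 0:
            raise ValueError("delta must be >= 0 and jitter > 0")
        if self.height < 40 or self.width < 60:
            raise ValueError("image dimensions too small to contain the vein skeleton")
        if self.class_sizes is not None and len(self.class_sizes) != self.n_classes:
            raise ValueError("class_sizes length must equal n_classes")

    @property
    def sizes(self) -> tuple[int, ...]:
        if self.class_sizes is not None:
            return self.class_sizes
        return tuple([self.n_per_class] * self.n_classes)


def paper_wing_spec(**overrides) -> WingSpec:
    """The 74-sample design: 14 classes of five samples plus one of four."""
    sizes = tuple([5] * 14 + [4])
    defaults = dict(n_classes=15, class_sizes=sizes)
    defaults.update(overrides)
    return WingSpec(**defaults)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _wing_outline(height: int, width: int) -> np.ndarray:
    mask = np.zeros((height, width), dtype=bool)
    rr, cc = draw.ellipse(
        (height - 1) / 2, (width - 1) / 2, 0.44 * height, 0.48 * width, shape=mask.shape
    )
    mask[rr, cc] = True
    return mask


def _rasterize_wing(points: np.ndarray, spec: WingSpec, rng: np.random.Generator) -> np.ndarray:
    H, W = spec.height, spec.width
    img = np.zeros((H, W), dtype=bool)
    pts = np.clip(np.round(points).astype(int), [0, 0], [H - 1, W - 1])
    for vein in _VEINS:
        for a, b in zip(vein, vein[1:]):
            rr, cc = draw.line(*pts[a], *pts[b])
            img[rr, cc] = True
    interior = _wing_outline(H, W)
    boundary = interior & ~ndimage.binary_erosion(interior)
    img |= boundary
    radius = max(spec.thickness // 2, 1)
    img = morphology.dilation(img, morphology.disk(radius))
    img &= ndimage.binary_dilation(interior, iterations=radius)
    if spec.speckle_rate > 0:
        img |= rng.random((H, W)) < spec.speckle_rate
    return img.astype(float)


def gen_wings(spec: WingSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate wing images, class labels, and 19 x 2 landmarks per image.

    Returns ``(images, labels, landmarks)`` with images of shape
    ``(n, height, width)`` in {0, 1}, integer labels, and landmark
    (row, col) coordinates of the jittered control points.
    """
    H, W = spec.height, spec.width
    base = np.column_stack(
        [_BASE_LANDMARKS_UV[:, 1] * (H - 1), _BASE_LANDMARKS_UV[:, 0] * (W - 1)]
    )
    images, labels, landmarks = [], [], []
    for c, n_c in enumerate(spec.sizes):
        rng_c = _rng(spec.seed, 1, c)
        angles = rng_c.uniform(0, 2 * np.pi, size=len(base))
        offset = spec.delta * np.column_stack([np.sin(angles), np.cos(angles)])
        for i in range(n_c):
            rng_i = _rng(spec.seed, 2, c, i + spec.sample_offset)
            pts = base + offset + rng_i.normal(0.0, spec.jitter, size=base.shape)
            images.append(_rasterize_wing(pts, spec, rng_i))
            labels.append(c)
            landmarks.append(pts)
    return np.stack(images), np.asarray(labels), np.stack(landmarks)


# class-conditional categorical tables for the five expert features;
# chosen so the BI-RADS assessment is the most class-informative
# feature and breast density the least (exact mutual-information
# ordering is a tested property)
DEFAULT_EXPERT_TABLES: dict[str, dict[str, dict]] = {
    "assessment": {
        "categories": [0, 1, 2, 3, 4, 5],
        "benign": [0.02, 0.08, 0.35, 0.35, 0.18, 0.02],
        "malignant": [0.01, 0.01, 0.04, 0.09, 0.50, 0.35],
    },
    "margin": {
        "categories": ["circumscribed", "obscured", "ill_defined", "spiculated"],
        "benign": [0.55, 0.25, 0.15, 0.05],
        "malignant": [0.05, 0.15, 0.40, 0.40],
    },
    "shape": {
        "categories": ["oval", "round", "lobulated", "irregular"],
        "benign": [0.40, 0.25, 0.25, 0.10],
        "malignant": [0.10, 0.10, 0.25, 0.55],
    },
    "subtlety": {
        "categories": [1, 2, 3, 4, 5],
        "benign": [0.10, 0.20, 0.30, 0.25, 0.15],
        "malignant": [0.06, 0.14, 0.25, 0.30, 0.25],
    },
    "density": {
        "categories": [1, 2, 3, 4],
        "benign": [0.12, 0.38, 0.38, 0.12],
        "malignant": [0.10, 0.36, 0.40, 0.14],
    },
}


@dataclass(frozen=True)
class MassSpec:
    """Generator settings for two-class mass-like grayscale images.

    Class prevalence defaults to the 48/52 benign/malignant split of
    the mammographic cohort the generator emulates.  Setting
    ``spiculation`` to 0 and ``margin_blur_malignant`` equal to
    ``margin_blur_benign`` makes the two class generators coincide
    (null case).
    """

    n_benign: int = 48
    n_malignant: int = 52
    size: int = 300
    radius_fraction: float = 0.30
    spiculation: float = 0.35
    spike_count: int = 12
    spike_sharpness: float = 1.5
    margin_blur_benign: float = 0.06
    margin_blur_malignant: float = 0.35
    noise_corr_length: float = 8.0
    expert_tables: dict = field(default_factory=lambda: DEFAULT_EXPERT_TABLES)
    seed: int = 0

    def __post_init__(self):
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("both classes need at least one sample")
        if self.size < 32:
            raise ValueError("mass images must be at least 32 px")
        for name, tab in self.expert_tables.items():
            for cls in ("benign", "malignant"):
                probs = np.asarray(tab[cls], dtype=float)
                if len(probs) != len(tab["categories"]) or np.any(probs < 0):
                    raise ValueError(f"invalid conditional table for {name!r}/{cls}")
                if not np.isclose(probs.sum(), 1.0):
                    raise ValueError(f"probabilities for {name!r}/{cls} must sum to 1")


def _mass_image(label: str, spec: MassSpec, rng: np.random.Generator) -> np.ndarray:
    S = spec.size
    rows = np.arange(S)[:, None] - (S - 1) / 2 - rng.uniform(-0.04, 0.04) * S
    cols = np.arange(S)[None, :] - (S - 1) / 2 - rng.uniform(-0.04, 0.04) * S
    r = np.hypot(rows, cols)
    theta = np.arctan2(rows, cols)
    r0 = spec.radius_fraction * (S / 2) * (1.0 + rng.uniform(-0.1, 0.1))
    phi = rng.uniform(0, 2 * np.pi)
    ecc = rng.uniform(0.05, 0.25)
    # both classes share an elliptical core so that zero spiculation and
    # equal margin blur make the generators coincide (null case)
    boundary = r0 * (1.0 + ecc * np.cos(2.0 * (theta - phi)))
    if label == "malignant":
        boundary = boundary * (
            1.0
            + spec.spiculation
            * np.abs(np.sin(spec.spike_count * theta / 2.0 + phi)) ** spec.spike_sharpness
        )
        width = spec.margin_blur_malignant * r0
    else:
        width = spec.margin_blur_benign * r0
    mass = 1.0 / (1.0 + np.exp(-(boundary - r) / max(width, 1e-6)))
    noise = rng.normal(size=(S, S))
    noise = ndimage.gaussian_filter(noise, spec.noise_corr_length)
    sd = noise.std()
    if sd > 0:
        noise = noise / sd * 0.08
    img = 0.25 + noise + 0.55 * mass * (1.0 + rng.uniform(-0.08, 0.08))
    return np.clip(img, 0.0, 1.0)


def gen_masses(spec: MassSpec) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate mass images, labels, and the expert-feature table.

    Expert features are drawn from the class-conditional tables and are
    therefore conditionally independent of the image given the class.
    """
    images, labels, rows = [], [], []
    plan = [("benign", i) for i in range(spec.n_benign)] + [
        ("malignant", i) for i in range(spec.n_malignant)
    ]
    for cls, i in plan:
        key = 0 if cls == "benign" else 1
        rng = _rng(spec.seed, 3, key, i)
        images.append(_mass_image(cls, spec, rng))
        labels.append(cls)
        feat = {}
        for name, tab in spec.expert_tables.items():
            cats = tab["categories"]
            feat[name] = cats[rng.choice(len(cats), p=np.asarray(tab[cls], dtype=float))]
        rows.append(feat)
    return np.stack(images), np.asarray(labels), pd.DataFrame(rows)


def table_mutual_information(tables: dict, p_malignant: float = 0.52) -> dict[str, float]:
    """Exact mutual information (nats) between class and each expert feature."""
    out = {}
    pc = {"benign": 1.0 - p_malignant, "malignant": p_malignant}
    for name, tab in tables.items():
        pb = np.asarray(tab["benign"], dtype=float)
        pm = np.asarray(tab["malignant"], dtype=float)
        marg = pc["benign"] * pb + pc["malignant"] * pm
        mi = 0.0
        for cls, probs in (("benign", pb), ("malignant", pm)):
            mask = probs > 0
            mi += pc[cls] * np.sum(probs[mask] * np.log(probs[mask] / marg[mask]))
        out[name] = float(mi)
    return out


def landmark_features(landmarks: np.ndarray) -> np.ndarray:
    """Alignment-standardized landmark coordinates as flat features.

    Each configuration is centered, scaled to unit centroid size, and
    rotated onto the first configuration by least-squares (a light
    Procrustes analogue without iterative mean-shape refinement);
    features are the flattened aligned coordinates (2L per sample).
    """
    landmarks = np.asarray(landmarks, dtype=float)
    if landmarks.ndim != 3 or landmarks.shape[2] != 2:
        raise ValueError("expected an (n, L, 2) landmark array")
    normed = []
    for conf in landmarks:
        centered = conf - conf.mean(axis=0)
        size = np.sqrt(np.sum(centered**2))
        if size <= 0:
            raise ValueError("degenerate landmark configuration (all points coincide)")
        normed.append(centered / size)
    ref = normed[0]
    feats = []
    for conf in normed:
        # least-squares proper rotation of conf onto ref
        U, _, Vt = np.linalg.svd(conf.T @ ref)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            U[:, -1] *= -1
            R = U @ Vt
        feats.append((conf @ R).ravel())
    return np.stack(feats)
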