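"""Seeded synthetic feature tables and toy images.

The generator emulates the shape of a deep-feature classification problem:
an ``n x D`` table over ``c`` classes in which only ``k`` columns carry class
signal.  Informative columns are class-conditional Gaussians whose means sit
at the vertices of a regular simplex scaled so every pair of class means is
``separation * noise_sd`` apart — one interpretable knob controls problem
difficulty.  The remaining ``D - k`` columns are label-independent Gaussian
noise.  Ground truth (which columns are informative) is returned alongside,
so feature-selection recovery can be scored exactly.

``generate_toy_images`` draws small raster images of clustered ellipses with
class-specific hue and geometry, giving the descriptor extractor a fully
self-contained, seeded image source.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .data import FeatureMask, FeatureTable

__all__ = [
    "TABLE2_CLASS_COUNTS",
    "DATE_CLASSES",
    "SyntheticConfig",
    "GroundTruth",
    "generate_feature_table",
    "generate_toy_images",
    "save_images",
]

# Real date-fruit dataset class sizes (Barhi, Khalas, Meneifi, Naboot Saif,
# Sullaj); used when class_proportions="table2".
DATE_CLASSES = ("Barhi", "Khalas", "Meneifi", "Naboot Saif", "Sullaj")
TABLE2_CLASS_COUNTS = (1811, 1385, 1295, 1424, 2157)

# Default separation: chosen so that on the default desk-scale problem
# (n=400, D=64, k=8, 5 classes) a K=5 nearest-neighbour classifier using ALL
# features scores in the 0.80-0.95 holdout band — hard enough that pruning
# noise columns helps, easy enough that the signal is recoverable.
DEFAULT_SEPARATION = 5.0


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic feature-table generator.

    separation is the pairwise distance between class means on the
    informative axes, in units of noise_sd.
    """

    n_samples: int = 400
    n_features: int = 64
    n_informative: int = 8
    n_classes: int = 5
    separation: float = DEFAULT_SEPARATION
    noise_sd: float = 1.0
    class_proportions: object = None  # None = uniform, "table2", or a simplex vector
    class_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_informative <= self.n_features:
            raise ValueError("need 1 <= n_informative <= n_features")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_informative < self.n_classes - 1:
            raise ValueError(
                "equidistant class means need n_informative >= n_classes - 1"
            )

    def proportions(self) -> np.ndarray:
        if self.class_proportions is None:
            p = np.full(self.n_classes, 1.0 / self.n_classes)
        elif isinstance(self.class_proportions, str):
            if self.class_proportions != "table2":
                raise ValueError(f"unknown proportions preset {self.class_proportions!r}")
            if self.n_classes != len(TABLE2_CLASS_COUNTS):
                raise ValueError("'table2' proportions define exactly 5 classes")
            counts = np.asarray(TABLE2_CLASS_COUNTS, dtype=float)
            p = counts / counts.sum()
        else:
            p = np.asarray(self.class_proportions, dtype=float)
            if len(p) != self.n_classes or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError("class_proportions must be a simplex vector of length n_classes")
        return p

    def labels_list(self) -> list[str]:
        if self.class_names is not None:
            if len(self.class_names) != self.n_classes:
                raise ValueError("class_names length must equal n_classes")
            return list(self.class_names)
        if self.class_proportions == "table2":
            return list(DATE_CLASSES)
        return [f"class{i}" for i in range(self.n_classes)]


@dataclass
class GroundTruth:
    """What the generator knows: the informative columns and class means."""

    true_mask: FeatureMask
    class_means: np.ndarray  # (c, k) means on the informative axes
    class_names: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_mask": "".join(str(int(b)) for b in self.true_mask.bits),
                "informative_indices": [int(i) for i in self.true_mask.indices()],
                "class_means": self.class_means.tolist(),
                "class_names": self.class_names,
            },
            indent=2,
        )


def _largest_remainder_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Apportion n samples to classes by largest remainder; exact for exact fractions."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _simplex_vertices(c: int, k: int) -> np.ndarray:
    """c points in R^k, unit pairwise distance, centred at the origin (k >= c-1)."""
    g = np.eye(c) - np.full((c, c), 1.0 / c)
    # rows of g span a (c-1)-dim subspace with pairwise distance sqrt(2)
    u, s, _ = np.linalg.svd(g)
    coords = (u * s)[:, : c - 1] / np.sqrt(2.0)
    out = np.zeros((c, k))
    out[:, : c - 1] = coords
    return out


def generate_feature_table(config: SyntheticConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw a seeded feature table with a known informative subset.

    Returns the table plus a :class:`GroundTruth` holding the true mask and
    the class means actually used.
    """
    rng = np.random.default_rng(config.seed)
    n, d, k, c = (
        config.n_samples,
        config.n_features,
        config.n_informative,
        config.n_classes,
    )
    counts = _largest_remainder_counts(n, config.proportions())
    if (counts == 0).any():
        bad = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(
            f"class {bad} receives 0 samples at n={n}; raise n_samples or adjust proportions"
        )
    names = config.labels_list()
    labels = np.repeat(np.array(names, dtype=object), counts)

    means = _simplex_vertices(c, k) * (config.separation * config.noise_sd)
    informative = np.sort(rng.choice(d, size=k, replace=False))
    bits = np.zeros(d, dtype=np.uint8)
    bits[informative] = 1

    values = rng.normal(0.0, config.noise_sd, size=(n, d))
    row = 0
    for ci, cnt in enumerate(counts):
        values[row : row + cnt][:, informative] += means[ci]
        row += cnt
    # shuffle rows so class blocks are not contiguous
    perm = rng.permutation(n)
    values, labels = values[perm], labels[perm]

    feature_names = np.array([f"f{j:04d}" for j in range(d)], dtype=object)
    table = FeatureTable(values=values, labels=labels, feature_names=feature_names)
    truth = GroundTruth(
        true_mask=FeatureMask(bits=bits), class_means=means, class_names=names
    )
    return table, truth


# ---------------------------------------------------------------------------
# Toy images
# ---------------------------------------------------------------------------

# Visual archetypes: hue (degrees), mean ellipse count, mean ellipse radius
# (pixels at the 64x64 working size).  Hues are spread around the wheel so
# colour histograms separate the classes.
_ARCHETYPES = (
    {"hue": 10.0, "n_blobs": 3, "radius": 9.0},
    {"hue": 70.0, "n_blobs": 5, "radius": 7.0},
    {"hue": 140.0, "n_blobs": 7, "radius": 5.0},
    {"hue": 210.0, "n_blobs": 4, "radius": 11.0},
    {"hue": 300.0, "n_blobs": 9, "radius": 4.0},
    {"hue": 40.0, "n_blobs": 12, "radius": 3.0},
)

IMAGE_SIZE = 64


def _hsv_rgb(h_deg: float, s: float, v: float) -> tuple[int, int, int]:
    r, g, b = colorsys.hsv_to_rgb((h_deg % 360.0) / 360.0, s, v)
    return int(r * 255), int(g * 255), int(b * 255)


def generate_toy_images(
    n_per_class: int,
    n_classes: int = 5,
    seed: int = 0,
    size: int = IMAGE_SIZE,
    class_names: tuple[str, ...] | None = None,
) -> tuple[list[np.ndarray], list[str]]:
    """Draw a labelled set of cluster-of-ellipses raster images.

    Each class has a distinct hue and blob-count/size distribution.  Returns
    (images, labels) with images as uint8 HxWx3 arrays; fully seeded.
    """
    if n_classes > len(_ARCHETYPES):
        raise ValueError(
            f"n_classes={n_classes} exceeds the {len(_ARCHETYPES)} built-in archetypes"
        )
    if class_names is None:
        class_names = (
            DATE_CLASSES if n_classes == len(DATE_CLASSES) else
            tuple(f"class{i}" for i in range(n_classes))
        )
    rng = np.random.default_rng(seed)
    images: list[np.ndarray] = []
    labels: list[str] = []
    for ci in range(n_classes):
        arch = _ARCHETYPES[ci]
        for _ in range(n_per_class):
            img = Image.new("RGB", (size, size), color=(18, 18, 22))
            draw = ImageDraw.Draw(img)
            cx = rng.uniform(0.3, 0.7) * size
            cy = rng.uniform(0.3, 0.7) * size
            n_blobs = max(1, int(round(rng.normal(arch["n_blobs"], 0.8))))
            for _b in range(n_blobs):
                r = max(1.5, rng.normal(arch["radius"], arch["radius"] * 0.15))
                x = cx + rng.normal(0, size * 0.12)
                y = cy + rng.normal(0, size * 0.12)
                hue = arch["hue"] + rng.normal(0, 6.0)
                col = _hsv_rgb(hue, rng.uniform(0.75, 0.95), rng.uniform(0.75, 0.95))
                draw.ellipse([x - r, y - r * 0.8, x + r, y + r * 0.8], fill=col)
            images.append(np.asarray(img, dtype=np.uint8))
            labels.append(class_names[ci])
    return images, labels


def save_images(images: list[np.ndarray], labels: list[str], out_dir: str | Path) -> list[Path]:
    """Write images as PNG files named ``<label>_<index>.png``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    counter: dict[str, int] = {}
    for img, lab in zip(images, labels):
        i = counter.get(lab, 0)
        counter[lab] = i + 1
        p = out_dir / f"{lab.replace(' ', '_')}_{i:04d}.png"
        Image.fromarray(img).save(p)
        paths.append(p)
    return paths
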