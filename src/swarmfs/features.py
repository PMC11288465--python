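"""Image-to-feature-table extraction.

Two routes produce the ``FeatureTable`` the selection and training stages
consume.  The built-in *toy descriptor* is deterministic and dependency-light:
per-channel colour histograms, normalized grayscale central moments and
foreground-blob statistics, concatenated per image.  It exists so the whole
pipeline can be exercised end to end on generated images.  Deep convolutional
extractors (e.g. a 2048-feature residual-network backbone) plug in through the
*external adapter* contract: an adapter registers a callable plus the feature
width it promises, and the framework treats its output as opaque numbers —
downstream stages never care where a table came from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from PIL import Image
from skimage import measure
from skimage.filters import threshold_otsu

from .data import FeatureTable

__all__ = [
    "DescriptorSpec",
    "ExtractorUnavailableError",
    "DimensionalityMismatchError",
    "extract_descriptor_features",
    "register_adapter",
    "unregister_adapter",
    "run_external_adapter",
    "WORKING_SIZE",
]

# Images are resized to this square working size before descriptor
# computation, so the feature layout is independent of input resolution.
WORKING_SIZE = 64


class ExtractorUnavailableError(RuntimeError):
    """No adapter is registered under the requested name."""


class DimensionalityMismatchError(ValueError):
    """An adapter returned a different feature width than it declared."""


@dataclass
class DescriptorSpec:
    """Parameters of the toy descriptor.

    Feature layout (and count) for fixed params:

    - ``hist_bins`` bins x 3 channels of normalized colour histograms,
    - normalized grayscale central moments of total order 2..``moment_order``
      (7 values for order 3: mu20, mu11, mu02, mu30, mu21, mu12, mu03),
    - 4 foreground-blob statistics (count, mean area, area SD, foreground
      fraction; areas as fractions of the image area so all descriptor
      blocks share the unit scale) from an Otsu threshold on grayscale.

    Defaults give D = 8*3 + 7 + 4 = 35.
    """

    hist_bins: int = 8
    moment_order: int = 3

    def __post_init__(self) -> None:
        if self.hist_bins < 2:
            raise ValueError("hist_bins must be >= 2")
        if self.moment_order < 2:
            raise ValueError("moment_order must be >= 2")

    @property
    def n_moment_features(self) -> int:
        # central moments of total order 2..moment_order (mu00/mu10/mu01 carry
        # no shape information after centring)
        return sum(o + 1 for o in range(2, self.moment_order + 1))

    @property
    def n_features(self) -> int:
        return 3 * self.hist_bins + self.n_moment_features + 4

    def feature_names(self) -> list[str]:
        names = [
            f"hist_{ch}_{b}" for ch in ("r", "g", "b") for b in range(self.hist_bins)
        ]
        for order in range(2, self.moment_order + 1):
            for i in range(order + 1):
                names.append(f"mom_{order - i}_{i}")
        names.extend(["blob_count", "blob_mean_area", "blob_area_sd", "blob_fg_frac"])
        return names


def _to_working_array(image: np.ndarray | Image.Image) -> np.ndarray:
    if isinstance(image, Image.Image):
        img = image.convert("RGB")
    else:
        arr = np.asarray(image)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected an HxWx3 image, got shape {arr.shape}")
        img = Image.fromarray(arr.astype(np.uint8), "RGB")
    if img.size[0] == 0 or img.size[1] == 0:
        raise ValueError("zero-area image")
    img = img.resize((WORKING_SIZE, WORKING_SIZE), Image.BILINEAR)
    return np.asarray(img, dtype=np.uint8)


def _descriptor_row(arr: np.ndarray, spec: DescriptorSpec) -> np.ndarray:
    feats: list[float] = []
    # (a) per-channel colour histograms, each normalized to sum 1
    for ch in range(3):
        hist, _ = np.histogram(arr[:, :, ch], bins=spec.hist_bins, range=(0, 256))
        feats.extend(hist / hist.sum())
    # (b) normalized grayscale central moments
    gray = arr.astype(float).mean(axis=2)
    mu = measure.moments_central(gray, order=spec.moment_order)
    eta = measure.moments_normalized(mu, order=spec.moment_order)
    for order in range(2, spec.moment_order + 1):
        for i in range(order + 1):
            feats.append(float(eta[order - i, i]))
    # (c) foreground-blob statistics via Otsu threshold; areas are fractions
    # of the image so every block lives on a comparable 0-1ish scale
    n_pixels = gray.size
    if np.ptp(gray) < 1e-9:
        count, mean_area, sd_area, fg_frac = 0.0, 0.0, 0.0, 0.0
    else:
        fg = gray > threshold_otsu(gray)
        labelled = measure.label(fg)
        areas = np.bincount(labelled.ravel())[1:]
        areas = areas[areas > 0] / n_pixels
        count = float(len(areas)) / 10.0
        mean_area = float(areas.mean()) if len(areas) else 0.0
        sd_area = float(areas.std()) if len(areas) else 0.0
        fg_frac = float(fg.mean())
    feats.extend([count, mean_area, sd_area, fg_frac])
    row = np.asarray(feats, dtype=float)
    return np.nan_to_num(row, nan=0.0, posinf=0.0, neginf=0.0)


def extract_descriptor_features(
    images: Sequence[np.ndarray | Image.Image],
    labels: Sequence[str],
    spec: DescriptorSpec | None = None,
) -> FeatureTable:
    """Compute toy-descriptor rows for a labelled image set.

    Deterministic: the same image always yields the same row.
    """
    spec = spec or DescriptorSpec()
    if len(images) != len(labels):
        raise ValueError("images and labels must have equal length")
    if len(images) == 0:
        raise ValueError("empty image set")
    rows = np.stack([_descriptor_row(_to_working_array(im), spec) for im in images])
    return FeatureTable(
        values=rows,
        labels=np.asarray(labels, dtype=object),
        feature_names=np.asarray(spec.feature_names(), dtype=object),
    )


# ---------------------------------------------------------------------------
# External adapter contract
# ---------------------------------------------------------------------------

_ADAPTERS: dict[str, tuple[Callable[..., np.ndarray], int]] = {}


def register_adapter(name: str, fn: Callable[..., np.ndarray], n_features: int) -> None:
    """Register an external extractor under ``name``.

    ``fn(images) -> (n, n_features) array``; ``n_features`` is the width the
    adapter promises to produce (e.g. 2048 for a residual-network backbone).
    """
    if n_features < 1:
        raise ValueError("declared n_features must be >= 1")
    _ADAPTERS[name] = (fn, n_features)


def unregister_adapter(name: str) -> None:
    _ADAPTERS.pop(name, None)


def run_external_adapter(
    images: Sequence[np.ndarray | Image.Image],
    labels: Sequence[str],
    adapter: str,
) -> FeatureTable:
    """Run a registered adapter and wrap its output in a validated table."""
    if adapter not in _ADAPTERS:
        raise ExtractorUnavailableError(
            f"extractor unavailable: no adapter registered under {adapter!r} "
            f"(registered: {sorted(_ADAPTERS)}); the built-in toy descriptor "
            "does not require an adapter"
        )
    fn, declared = _ADAPTERS[adapter]
    values = np.asarray(fn(images), dtype=float)
    if values.ndim != 2 or values.shape != (len(images), declared):
        raise DimensionalityMismatchError(
            f"adapter {adapter!r} declared {declared} features but returned "
            f"shape {values.shape} for {len(images)} images"
        )
    names = np.asarray([f"{adapter}_{j:04d}" for j in range(declared)], dtype=object)
    return FeatureTable(values=values, labels=np.asarray(labels, dtype=object), feature_names=names)
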