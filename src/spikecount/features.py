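"""Chromatic color coordinates, vegetation color indices, and histogram-based
feature selection.

The recognition method separates wheat spikes from soil and leaves using three
indices computed from chromatic (intensity-normalized) channel coordinates:

* excess green        ``Eg  = 2g - r - b``  (equivalently ``3g - 1``)
* normalized green-red ``Dgr = (g - r) / (g + r)``
* normalized green-blue ``Dgb = (g - b) / (g + b)``

where ``r = R/(R+G+B)`` etc.  At the grain-filling stage spikes have turned
yellowish-green while leaves remain green, so ``Dgr`` separates spikes from
leaves, and ``Eg`` separates vegetation from brown soil.  Feature usefulness is
quantified here by the overlap coefficient between per-class histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChromaticImage",
    "FeatureMaps",
    "ClassHistogram",
    "normalize_chromatic",
    "compute_indices",
    "class_histograms",
    "histogram_overlap",
    "select_features",
]

#: class codes used throughout the package for label rasters
SOIL, LEAF, SPIKE = 0, 1, 2
CLASS_NAMES = {SOIL: "soil", LEAF: "leaf", SPIKE: "spike"}


@dataclass(frozen=True)
class ChromaticImage:
    """Per-pixel chromatic coordinates, each an H x W float plane.

    Invariant: ``r + g + b == 1`` at every pixel (zero-sum raw pixels carry
    the neutral value 1/3 in each coordinate).
    """

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape


@dataclass(frozen=True)
class FeatureMaps:
    """The three color-index planes, same shape as the source image.

    Ranges under chromatic normalization: ``Eg`` in [-1, 2], ``Dgr`` and
    ``Dgb`` in [-1, 1].
    """

    Eg: np.ndarray
    Dgr: np.ndarray
    Dgb: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.Eg.shape

    def plane(self, name: str) -> np.ndarray:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown feature plane {name!r}") from None

    def names(self) -> tuple[str, ...]:
        return ("Eg", "Dgr", "Dgb")


@dataclass(frozen=True)
class ClassHistogram:
    """Normalized histogram of one feature restricted to one class."""

    class_name: str
    bin_edges: np.ndarray
    density: np.ndarray  # sums to 1

    def __post_init__(self):
        if len(self.bin_edges) != len(self.density) + 1:
            raise ValueError("bin_edges must have len(density) + 1 entries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending")


def normalize_chromatic(image: np.ndarray) -> ChromaticImage:
    """Convert an 8-bit RGB image to chromatic coordinates r, g, b.

    Each coordinate is the channel's fraction of the pixel's total intensity,
    which removes the first-order effect of illumination differences across
    the canopy.  Pixels with ``R + G + B == 0`` (pure black, e.g. deep shadow)
    carry the neutral value (1/3, 1/3, 1/3).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
    planes = image.astype(np.float64)
    total = planes.sum(axis=2)
    zero = total == 0
    total[zero] = 1.0
    r = planes[..., 0] / total
    g = planes[..., 1] / total
    b = planes[..., 2] / total
    r[zero] = g[zero] = b[zero] = 1.0 / 3.0
    return ChromaticImage(r=r, g=g, b=b)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num/den with 0 where den == 0 (zero is the neutral 'no evidence' value)."""
    out = np.zeros_like(num, dtype=np.float64)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def compute_indices(chrom: ChromaticImage) -> FeatureMaps:
    """Compute the Eg, Dgr and Dgb planes from chromatic coordinates."""
    r, g, b = chrom.r, chrom.g, chrom.b
    Eg = 2.0 * g - r - b
    Dgr = _safe_ratio(g - r, g + r)
    Dgb = _safe_ratio(g - b, g + b)
    return FeatureMaps(Eg=Eg, Dgr=Dgr, Dgb=Dgb)


def image_features(image: np.ndarray) -> FeatureMaps:
    """Convenience: chromatic normalization followed by index computation."""
    return compute_indices(normalize_chromatic(image))


def class_histograms(
    feature_plane: np.ndarray,
    class_map: np.ndarray,
    n_bins: int = 64,
) -> dict[str, ClassHistogram]:
    """Per-class normalized histograms of one feature plane on shared bins.

    The bins span the pooled min/max over all pixels so that densities of
    different classes are directly comparable bin by bin.

    Raises ``ValueError`` if any of the three classes has no pixels.
    """
    feature_plane = np.asarray(feature_plane, dtype=np.float64)
    class_map = np.asarray(class_map)
    if feature_plane.shape != class_map.shape:
        raise ValueError("feature plane and class map shapes differ")
    lo = float(feature_plane.min())
    hi = float(feature_plane.max())
    if hi <= lo:  # constant plane: a single degenerate-width pair of edges
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    out: dict[str, ClassHistogram] = {}
    for code, name in CLASS_NAMES.items():
        values = feature_plane[class_map == code]
        if values.size == 0:
            raise ValueError(f"class {name!r} has no pixels in the class map")
        counts, _ = np.histogram(values, bins=edges)
        out[name] = ClassHistogram(
            class_name=name, bin_edges=edges, density=counts / counts.sum()
        )
    return out


def histogram_overlap(h1: ClassHistogram, h2: ClassHistogram) -> float:
    """Overlap coefficient of two histograms on identical bins.

    ``sum_i min(d1_i, d2_i)``: 0 for disjoint supports, 1 for identical
    densities.  Symmetric in its arguments.
    """
    if h1.bin_edges.shape != h2.bin_edges.shape or not np.allclose(
        h1.bin_edges, h2.bin_edges
    ):
        raise ValueError("histograms must share identical bin edges")
    return float(np.minimum(h1.density, h2.density).sum())


@dataclass(frozen=True)
class FeatureScore:
    """Class-separation summary for one color index."""

    feature: str
    spike_vs_soil: float  # histogram overlap coefficient
    spike_vs_leaf: float

    @property
    def best_overlap(self) -> float:
        return min(self.spike_vs_soil, self.spike_vs_leaf)


@dataclass(frozen=True)
class FeatureSelection:
    scores: tuple[FeatureScore, ...] = field(default_factory=tuple)
    selected: tuple[str, ...] = field(default_factory=tuple)


def select_features(
    features: FeatureMaps,
    class_map: np.ndarray,
    n_bins: int = 64,
    overlap_threshold: float = 0.3,
) -> FeatureSelection:
    """Rank the three indices by class separation and pick the useful ones.

    A feature is selected when it separates spikes from at least one
    confounder class, i.e. when the smaller of its spike-vs-soil and
    spike-vs-leaf histogram overlaps falls below ``overlap_threshold``.
    On canopy scenes with the expected color structure this selects Eg
    (anti-soil) and Dgr (anti-leaf) and rejects Dgb, whose class
    distributions nearly coincide.
    """
    scores = []
    for name in features.names():
        hists = class_histograms(features.plane(name), class_map, n_bins=n_bins)
        scores.append(
            FeatureScore(
                feature=name,
                spike_vs_soil=histogram_overlap(hists["spike"], hists["soil"]),
                spike_vs_leaf=histogram_overlap(hists["spike"], hists["leaf"]),
            )
        )
    scores.sort(key=lambda s: s.best_overlap)
    selected = tuple(s.feature for s in scores if s.best_overlap < overlap_threshold)
    return FeatureSelection(scores=tuple(scores), selected=selected)


def save_feature_tiff(features: FeatureMaps, path) -> None:
    """Save the three index planes as a 32-bit float multi-channel TIFF."""
    import tifffile

    stack = np.stack([features.Eg, features.Dgr, features.Dgb]).astype(np.float32)
    tifffile.imwrite(path, stack)


def histograms_to_table(
    histograms: dict[str, dict[str, ClassHistogram]]
) -> "pd.DataFrame":
    """Flatten {feature: {class: histogram}} to a long-form table for CSV export."""
    import pandas as pd

    rows = []
    for feature, per_class in histograms.items():
        for name, h in per_class.items():
            for lo, hi, d in zip(h.bin_edges[:-1], h.bin_edges[1:], h.density):
                rows.append((feature, name, lo, hi, d))
    return pd.DataFrame(
        rows, columns=["feature", "class", "bin_lo", "bin_hi", "density"]
    )
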