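"""Seeded synthetic canopy scenes with per-instance ground truth.

The generator emulates a downward-looking photograph of a wheat canopy at the
grain-filling stage: brownish textured soil, green curved leaves, and
yellow-green elongated spikes with awns.  Four named color regimes (``N1`` ..
``N4``) mimic a nitrogen-fertilization gradient: under generous fertilization
(N3/N4) leaves stay deep green while spikes yellow, so the normalized
green-red index Dgr separates the two classes cleanly; with no fertilization
(N1) leaves, stalks and spikes are all yellowish green and the class colors
nearly coincide.  Soil is always separable from vegetation by the excess-green
index Eg, and the normalized green-blue index Dgb is uninformative in every
regime — the structure the downstream feature selection is expected to
discover.

Every scene is bit-for-bit reproducible from its ``(config, seed)`` pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .features import LEAF, SOIL, SPIKE

__all__ = [
    "ColorModel",
    "SceneConfig",
    "SceneTruth",
    "PlacementError",
    "default_color_models",
    "generate_scene",
    "generate_dataset",
]

TREATMENTS = ("N1", "N2", "N3", "N4")


class PlacementError(RuntimeError):
    """Raised when an instance cannot be placed in a too-crowded scene."""

    def __init__(self, kind: str, index: int):
        self.kind = kind
        self.index = index
        super().__init__(
            f"could not place {kind} instance {index}: scene too crowded "
            f"(retry budget exhausted)"
        )


@dataclass(frozen=True)
class ColorModel:
    """Gaussian color model for one scene class in 8-bit RGB units.

    ``texture_amplitude`` scales a low-frequency multiplicative brightness
    field shared by the three channels; because it rescales R, G and B
    jointly it leaves chromatic coordinates (and hence all color indices)
    unchanged, modelling illumination texture rather than hue variation.
    """

    class_name: str
    mean_rgb: tuple[float, float, float]
    sd_rgb: tuple[float, float, float]
    texture_amplitude: float = 0.0
    #: organ-to-organ channel variation: each rendered instance carries a
    #: constant offset drawn from this SD.  Unlike per-pixel noise it does
    #: not average out inside a superpixel, so it is what limits
    #: superpixel-level class separability (plant heterogeneity under
    #: nitrogen starvation lives here)
    instance_sd_rgb: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not all(0 <= c <= 255 for c in self.mean_rgb):
            raise ValueError(f"mean_rgb out of [0, 255]: {self.mean_rgb}")
        if not all(s >= 0 for s in self.sd_rgb):
            raise ValueError(f"sd_rgb must be non-negative: {self.sd_rgb}")
        if not all(s >= 0 for s in self.instance_sd_rgb):
            raise ValueError(f"instance_sd_rgb must be non-negative: {self.instance_sd_rgb}")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be >= 0")


# Class means are designed in chromatic coordinates (see features module) and
# converted to 8-bit RGB at a class-typical brightness.  Along N4 -> N1 the
# leaf and spike Dgr means converge and the channel variation grows,
# reproducing the loss of color contrast in unfertilized plots.  The
# variation is split into a per-pixel SD and a per-organ SD whose quadrature
# sum gives the pooled pixel-population SD; the per-organ share grows toward
# N1 (starved stands are heterogeneous plant to plant).  Soil keeps r > g
# (negative Eg) everywhere; all three classes share a Dgb mean near 0.41 so
# that Dgb carries no class information.
_SOIL = {  # (mean, per-pixel sd)
    "N1": ((191, 99, 40), (9, 9, 9)),
    "N2": ((191, 99, 40), (9, 9, 9)),
    "N3": ((191, 99, 40), (8, 8, 8)),
    "N4": ((191, 99, 40), (8, 8, 8)),
}
_SPIKE = {  # (mean, per-pixel sd, per-organ sd)
    "N1": ((124, 139, 60), (7, 7, 7), (10, 10, 10)),
    "N2": ((125, 147, 63), (7, 7, 7), (6, 6, 6)),
    "N3": ((135, 155, 66), (5, 5, 5), (4, 4, 4)),
    "N4": ((144, 159, 67), (5, 5, 5), (3, 3, 3)),
}
_LEAF = {
    "N1": ((113, 138, 59), (7, 7, 7), (10, 10, 10)),
    "N2": ((101, 146, 63), (7, 7, 7), (6, 6, 6)),
    "N3": ((95, 149, 60), (5, 5, 5), (4, 4, 4)),
    "N4": ((90, 150, 60), (5, 5, 5), (3, 3, 3)),
}


def default_color_models(nitrogen_like: str) -> dict[str, ColorModel]:
    """Class color models for one nitrogen-like regime.

    Returns a dict with keys ``soil``, ``leaf``, ``spike``.  The models
    satisfy, in expectation over sampled pixels: soil Eg < 0 < spike Eg;
    leaf and spike Dgr distributions separated by >= 2 pooled SD for N3/N4,
    >= 1 SD for N2 and < 1 SD for N1; and mutually overlapping Dgb
    distributions for all three classes.
    """
    if nitrogen_like not in TREATMENTS:
        raise ValueError(
            f"unknown treatment code {nitrogen_like!r}; expected one of {TREATMENTS}"
        )
    soil_mean, soil_sd = _SOIL[nitrogen_like]
    spike_mean, spike_sd, spike_org = _SPIKE[nitrogen_like]
    leaf_mean, leaf_sd, leaf_org = _LEAF[nitrogen_like]
    return {
        "soil": ColorModel("soil", soil_mean, soil_sd, texture_amplitude=0.12),
        "spike": ColorModel(
            "spike", spike_mean, spike_sd, texture_amplitude=0.08,
            instance_sd_rgb=spike_org,
        ),
        "leaf": ColorModel(
            "leaf", leaf_mean, leaf_sd, texture_amplitude=0.10,
            instance_sd_rgb=leaf_org,
        ),
    }


def sample_pixels(model: ColorModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n independent RGB pixels from a color model (no spatial texture).

    Each pixel is treated as coming from its own organ, so the draw combines
    the per-pixel and per-organ variances — the pooled population a
    histogram over many organs would show.
    """
    mean = np.asarray(model.mean_rgb, dtype=np.float64)
    sd = np.asarray(model.sd_rgb, dtype=np.float64)
    inst = np.asarray(model.instance_sd_rgb, dtype=np.float64)
    raw = rng.normal(mean, np.sqrt(sd**2 + inst**2), size=(n, 3))
    return np.clip(np.round(raw), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and color configuration of one synthetic canopy scene.

    The default frame is a quarter (by area) of the 2592 x 1944 reference
    photograph size; lengths below are in pixels at that scale.
    """

    image_height: int = 972
    image_width: int = 1296
    n_spikes: int = 30
    n_leaves: int = 40
    spike_length_range: tuple[float, float] = (120.0, 200.0)
    spike_width_range: tuple[float, float] = (24.0, 38.0)
    leaf_length_range: tuple[float, float] = (180.0, 380.0)
    leaf_width_range: tuple[float, float] = (10.0, 20.0)
    overlap_probability: float = 0.15
    nitrogen_like: str = "N4"
    awn_density: int = 10
    seed: int = 0
    max_retries: int = 400
    min_gap: int = 8  # dilation radius keeping non-overlapping spikes apart
    max_chain: int = 3  # largest allowed group of mutually touching spikes

    def __post_init__(self):
        for name in (
            "spike_length_range",
            "spike_width_range",
            "leaf_length_range",
            "leaf_width_range",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < min <= max, got {(lo, hi)}")
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_spikes < 0 or self.n_leaves < 0:
            raise ValueError("instance counts must be >= 0")
        if not 0.0 <= self.overlap_probability <= 1.0:
            raise ValueError("overlap_probability must be in [0, 1]")
        if self.nitrogen_like not in TREATMENTS:
            raise ValueError(f"unknown treatment code {self.nitrogen_like!r}")
        if self.awn_density < 0:
            raise ValueError("awn_density must be >= 0")


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one generated scene."""

    instance_masks: list[np.ndarray]  # one boolean raster per spike
    class_map: np.ndarray  # H x W uint8 with values {SOIL, LEAF, SPIKE}
    true_count: int
    overlap_groups: list[frozenset[int]]  # groups of >= 2 touching spikes


# ---------------------------------------------------------------------------
# shape rasterizers


def _capsule_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    angle: float,
    length: float,
    width: float,
) -> np.ndarray:
    """Boolean raster of a capsule (segment dilated by width/2)."""
    h, w = shape
    half = max(length / 2.0 - width / 2.0, 0.5)
    dy, dx = np.sin(angle), np.cos(angle)
    p0 = np.array([center[0] - half * dy, center[1] - half * dx])
    p1 = np.array([center[0] + half * dy, center[1] + half * dx])
    r = width / 2.0
    pad = int(np.ceil(r)) + 2
    r0 = max(int(min(p0[0], p1[0])) - pad, 0)
    r1 = min(int(max(p0[0], p1[0])) + pad + 1, h)
    c0 = max(int(min(p0[1], p1[1])) - pad, 0)
    c1 = min(int(max(p0[1], p1[1])) + pad + 1, w)
    mask = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return mask
    yy, xx = np.mgrid[r0:r1, c0:c1]
    pts = np.stack([yy, xx], axis=-1).astype(np.float64)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    rel = pts - p0
    if seg_len2 == 0:
        dist2 = (rel**2).sum(axis=-1)
    else:
        t = np.clip((rel @ seg) / seg_len2, 0.0, 1.0)
        proj = p0 + t[..., None] * seg
        dist2 = ((pts - proj) ** 2).sum(axis=-1)
    mask[r0:r1, c0:c1] = dist2 <= r * r
    return mask


def _line_pixels(
    shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    n = int(np.ceil(np.hypot(*(p1 - p0)))) + 1
    t = np.linspace(0.0, 1.0, n)
    rows = np.round(p0[0] + t * (p1[0] - p0[0])).astype(int)
    cols = np.round(p0[1] + t * (p1[1] - p0[1])).astype(int)
    ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    return rows[ok], cols[ok]


def _spike_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    angle: float,
    length: float,
    width: float,
    awn_density: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Capsule body plus thin awn strokes fanning from the tip."""
    mask = _capsule_mask(shape, center, angle, length, width)
    if awn_density > 0:
        dy, dx = np.sin(angle), np.cos(angle)
        tip = np.array([center[0] + (length / 2) * dy, center[1] + (length / 2) * dx])
        for _ in range(awn_density):
            spread = rng.uniform(-0.5, 0.5)
            a = angle + spread
            alen = rng.uniform(0.08, 0.18) * length
            base = tip - np.array([dy, dx]) * rng.uniform(0.0, 0.6) * length
            end = base + np.array([np.sin(a), np.cos(a)]) * alen
            rows, cols = _line_pixels(shape, base, end)
            mask[rows, cols] = True
    return mask


def _leaf_mask(
    shape: tuple[int, int],
    start: tuple[float, float],
    angle: float,
    length: float,
    width: float,
    curvature: float,
) -> np.ndarray:
    """Curved strip: quadratic Bezier spine dilated by width/2."""
    h, w = shape
    p0 = np.array(start, dtype=np.float64)
    d = np.array([np.sin(angle), np.cos(angle)])
    n = np.array([-d[1], d[0]])
    p2 = p0 + d * length
    p1 = p0 + d * (length / 2) + n * curvature * length
    t = np.linspace(0.0, 1.0, max(int(length), 8))[:, None]
    spine = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    mask = np.zeros(shape, dtype=bool)
    rows = np.round(spine[:, 0]).astype(int)
    cols = np.round(spine[:, 1]).astype(int)
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    mask[rows[ok], cols[ok]] = True
    radius = max(int(round(width / 2)), 1)
    return _dilate_local(mask, radius)


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy**2 + xx**2 <= radius**2


def _dilate_local(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation restricted to the mask's bounding box (speed)."""
    if not mask.any():
        return mask
    rows, cols = np.nonzero(mask)
    h, w = mask.shape
    r0 = max(rows.min() - radius - 1, 0)
    r1 = min(rows.max() + radius + 2, h)
    c0 = max(cols.min() - radius - 1, 0)
    c1 = min(cols.max() + radius + 2, w)
    out = np.zeros_like(mask)
    out[r0:r1, c0:c1] = ndimage.binary_dilation(mask[r0:r1, c0:c1], _disk(radius))
    return out


# ---------------------------------------------------------------------------
# texture + rendering


def _texture_field(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Low-frequency multiplicative brightness field around 1."""
    if amplitude == 0:
        return np.ones(shape)
    coarse = rng.standard_normal((max(shape[0] // 48, 2), max(shape[1] // 48, 2)))
    zoom = (shape[0] / coarse.shape[0], shape[1] / coarse.shape[1])
    smooth = ndimage.zoom(coarse, zoom, order=1)[: shape[0], : shape[1]]
    smooth = smooth / max(np.abs(smooth).max(), 1e-9)
    return 1.0 + amplitude * smooth


def _render(
    class_map: np.ndarray,
    leaf_masks: list[np.ndarray],
    spike_masks: list[np.ndarray],
    models: dict[str, ColorModel],
    rng: np.random.Generator,
) -> np.ndarray:
    """Paint soil, then each leaf, then each spike.

    Every organ instance carries its own constant channel offset (drawn from
    the model's ``instance_sd_rgb``) on top of the class texture field and
    per-pixel noise, so organ-to-organ color variation survives superpixel
    averaging the way real plant heterogeneity does.
    """
    shape = class_map.shape
    image = np.zeros(shape + (3,), dtype=np.float64)
    # soil base layer over the whole frame
    soil = models["soil"]
    texture = _texture_field(shape, soil.texture_amplitude, rng)
    noise = rng.normal(0.0, 1.0, size=shape + (3,)) * np.asarray(soil.sd_rgb)
    image[:] = np.asarray(soil.mean_rgb) * texture[..., None] + noise
    for name, masks in (("leaf", leaf_masks), ("spike", spike_masks)):
        model = models[name]
        texture = _texture_field(shape, model.texture_amplitude, rng)
        noise = rng.normal(0.0, 1.0, size=shape + (3,)) * np.asarray(model.sd_rgb)
        colors = np.asarray(model.mean_rgb) * texture[..., None] + noise
        for mask in masks:
            offset = rng.normal(0.0, np.asarray(model.instance_sd_rgb))
            image[mask] = colors[mask] + offset
    return np.clip(np.round(image), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# placement


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri

    def group(self, i: int, n: int) -> set[int]:
        root = self.find(i)
        return {j for j in range(n) if self.find(j) == root}


def _sample_spike(
    config: SceneConfig, rng: np.random.Generator
) -> tuple[tuple[float, float], float, float, float]:
    length = rng.uniform(*config.spike_length_range)
    width = rng.uniform(*config.spike_width_range)
    margin = length / 2 + 4
    h, w = config.image_height, config.image_width
    if 2 * margin >= h or 2 * margin >= w:
        raise ValueError("spike length does not fit in the image")
    center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
    angle = rng.uniform(0, np.pi)
    return center, angle, length, width


def generate_truth(config: SceneConfig) -> SceneTruth:
    """Build the geometry/ground truth of a scene without rendering it.

    Useful for mask-level experiments (e.g. counting on perfect masks)
    where the rendered image is never consumed.  The truth is identical to
    the one :func:`generate_scene` would return for the same config.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    truth, _ = _build_truth(config, rng)
    return truth


def generate_scene(config: SceneConfig) -> tuple[np.ndarray, SceneTruth]:
    """Render one canopy scene and its ground truth.

    Spikes are placed with a guard gap (``min_gap``) unless a Bernoulli draw
    with ``overlap_probability`` selects overlapped placement, in which case
    the new spike is positioned so its mask intersects an existing spike over
    at least 5% of the smaller mask.  Touching groups never exceed
    ``max_chain`` members.  Raises :class:`PlacementError` when the retry
    budget runs out.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    truth, leaf_masks = _build_truth(config, rng)
    models = default_color_models(config.nitrogen_like)
    image = _render(truth.class_map, leaf_masks, truth.instance_masks, models, rng)
    return image, truth


def _build_truth(
    config: SceneConfig, rng: np.random.Generator
) -> tuple[SceneTruth, list[np.ndarray]]:
    shape = (config.image_height, config.image_width)

    # spikes first: they own their pixels; leaves fill around them
    instance_masks: list[np.ndarray] = []
    geometry: list[tuple[tuple[float, float], float, float, float]] = []
    occupancy = np.zeros(shape, dtype=bool)
    uf = _UnionFind(config.n_spikes)
    for i in range(config.n_spikes):
        want_overlap = len(instance_masks) > 0 and rng.random() < config.overlap_probability
        placed = False
        for _ in range(config.max_retries):
            if want_overlap:
                # anchor on a spike whose touching group still has room;
                # lean the new spike against one of the anchor's ends so the
                # fused region forms an elbow, the way leaning spikes do
                candidates = [
                    j
                    for j in range(len(instance_masks))
                    if len(uf.group(j, i)) < config.max_chain
                ]
                if not candidates:
                    want_overlap = False
                    continue
                j = int(rng.choice(candidates))
                anchor = instance_masks[j]
                a_center, a_angle, a_length, a_width = geometry[j]
                end_sign = 1.0 if rng.random() < 0.5 else -1.0
                a_dir = np.array([np.sin(a_angle), np.cos(a_angle)])
                contact = np.asarray(a_center) + end_sign * (a_length / 2) * a_dir
                delta = np.deg2rad(rng.uniform(55.0, 80.0)) * (
                    1.0 if rng.random() < 0.5 else -1.0
                )
                angle = a_angle + delta
                length = rng.uniform(*config.spike_length_range)
                width = rng.uniform(*config.spike_width_range)
                # new spike's near end sits just inside the anchor's end
                new_dir = np.array([np.sin(angle), np.cos(angle)])
                inset = rng.uniform(0.3, 0.8) * width
                center = contact + end_sign * new_dir * (length / 2 - inset)
                center += rng.uniform(-2, 2, size=2)
                mask = _spike_mask(
                    shape,
                    (float(center[0]), float(center[1])),
                    angle,
                    length,
                    width,
                    config.awn_density,
                    rng,
                )
                if not mask.any():
                    continue
                inter = int((mask & anchor).sum())
                smaller = min(int(mask.sum()), int(anchor.sum()))
                if inter < 0.05 * smaller or inter > 0.5 * smaller:
                    continue
                # may not touch spikes outside the anchor's group
                touching = [
                    t
                    for t in range(len(instance_masks))
                    if (mask & instance_masks[t]).any()
                ]
                group = set()
                for t in touching:
                    group |= uf.group(t, i)
                if len(group) + 1 > config.max_chain:
                    continue
                instance_masks.append(mask)
                geometry.append(((float(center[0]), float(center[1])), angle, length, width))
                for t in touching:
                    uf.union(i, t)
                placed = True
                break
            else:
                center, angle, length, width = _sample_spike(config, rng)
                mask = _spike_mask(
                    shape, center, angle, length, width, config.awn_density, rng
                )
                if not mask.any():
                    continue
                grown = _dilate_local(mask, config.min_gap)
                if (grown & occupancy).any():
                    continue
                instance_masks.append(mask)
                geometry.append((center, angle, length, width))
                placed = True
                break
        if not placed:
            raise PlacementError("spike", i)
        occupancy |= instance_masks[-1]

    # leaves: unconstrained placement under the spikes
    leaf_masks: list[np.ndarray] = []
    h, w = shape
    for _ in range(config.n_leaves):
        start = (rng.uniform(0, h), rng.uniform(0, w))
        angle = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(*config.leaf_length_range)
        width = rng.uniform(*config.leaf_width_range)
        curvature = rng.uniform(-0.25, 0.25)
        leaf_masks.append(_leaf_mask(shape, start, angle, length, width, curvature))

    # spikes painted over leaves in the class map, so the union of the
    # instance masks equals the spike region exactly
    class_map = np.full(shape, SOIL, dtype=np.uint8)
    for mask in leaf_masks:
        class_map[mask] = LEAF
    for mask in instance_masks:
        class_map[mask] = SPIKE

    groups = []
    seen: set[frozenset[int]] = set()
    for i in range(config.n_spikes):
        g = frozenset(uf.group(i, config.n_spikes))
        if len(g) >= 2 and g not in seen:
            seen.add(g)
            groups.append(g)

    truth = SceneTruth(
        instance_masks=instance_masks,
        class_map=class_map,
        true_count=len(instance_masks),
        overlap_groups=sorted(groups, key=min),
    )
    return truth, leaf_masks


def generate_dataset(
    n_scenes: int, config: SceneConfig, base_seed: int
) -> list[tuple[np.ndarray, SceneTruth]]:
    """Generate ``n_scenes`` scenes, scene i seeded with ``base_seed + i``."""
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    out = []
    for i in range(n_scenes):
        try:
            out.append(generate_scene(replace(config, seed=base_seed + i)))
        except PlacementError as err:
            raise PlacementError(err.kind, err.index) from RuntimeError(
                f"scene {i} (seed {base_seed + i}) failed"
            )
    return out
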