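"""Synthetic SEM-image generator emulating crossed-acicular shell microstructure.

The generator produces backscatter-like grayscale images together with exact
per-pixel ground truth, so that segmentation, morphometry and calibration can
be tested end-to-end without any real micrographs.  It encodes the statistical
structure the downstream analysis assumes:

* biomineral units (BMUs) are needle-shaped bright plateaus with darker soft
  rims, their long axes drawn from two dip modes at ±``dip_angle_mean``
  degrees off the growth front;
* BMU sizes follow a mixture of a temperature-invariant small-size lognormal
  bulk and a sparse "large" component whose scale grows linearly with
  culturing temperature — only the upper tail carries the temperature signal;
* pores are dark blobs elongated parallel to the growth front whose large-size
  component scales exponentially with temperature;
* topography is emulated as intensity (plateau/rim/background gray levels),
  plus Gaussian imaging noise and occasional dirt/scratch artifacts.

The growth front is the image vertical axis; growth direction is horizontal.
Orientations are degrees of the major axis measured from the vertical, in
``(-90, 90]``.  All generators are pure functions of ``(config, seed)``:
identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .io import MnCaSeries, SEMImage

__all__ = [
    "SyntheticConfig",
    "EntitySpec",
    "GroundTruth",
    "sample_bmu_population",
    "sample_pore_population",
    "generate_microstructure_image",
    "generate_mnca_profile",
    "sparse_labels_from_truth",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic microstructure model.

    Sizes are μm², angles degrees, intensities in ``[0, 1]``.  The defaults
    represent the six-level culturing design (1–15 °C): a temperature-invariant
    small-BMU bulk around the few-pixel detection limit, a sparse large-BMU
    component whose median scales linearly in temperature (≈2.75 μm² at 1 °C to
    ≈10.45 μm² at 15 °C), and a large-pore component scaling exponentially at
    ≈0.19 /°C from a ≈0.56 μm² base (≈0.68 μm² at 1 °C, ≈10 μm² at 15 °C).
    """

    canvas_size: tuple[int, int] = (1280, 1280)  # (H, W) pixels
    pixel_area: float = 0.0003  # μm² per pixel
    temperature: float = 9.0  # °C
    # biomineral units
    n_bmu: int = 800
    bulk_size_log_mean: float = math.log(0.003)  # ln μm²
    bulk_size_log_sd: float = 1.0
    # tail_fraction is sized so that a temperature group (3 specimens) carries
    # well over 15 large entities in expectation: the 15 largest per group must
    # all come from the temperature-scaled component, as in the culturing data
    tail_fraction: float = 0.012  # fraction drawn from the "large" component
    bmu_tail_base: float = 2.2  # μm², large-BMU median at 0 °C
    bmu_tail_scale_slope: float = 0.55  # μm²/°C
    tail_size_log_sd: float = 0.25  # lognormal spread of the large components
    bmu_elongation_log_mean: float = math.log(2.5)
    bmu_elongation_log_sd: float = 0.25
    dip_angle_mean: float = 35.0  # degrees off the growth front
    dip_angle_sd: float = 8.0
    # pores
    pore_density: float = 1.5  # pores / μm²
    pore_bulk_log_mean: float = math.log(0.01)  # ln μm²
    pore_bulk_log_sd: float = 0.8
    pore_base_size: float = 0.56  # μm², large-pore median scale at 0 °C
    pore_growth_rate: float = 0.193  # 1/°C, exponential scaling of large pores
    pore_elongation_log_mean: float = math.log(2.0)
    pore_elongation_log_sd: float = 0.25
    pore_orientation_sd: float = 6.0  # degrees around the growth front axis
    # rendering
    gray_levels: tuple[float, float, float] = (0.85, 0.45, 0.15)  # plateau/rim/bg
    pore_gray: float = 0.04
    rim_width_px: int = 2
    noise_sd: float = 0.03
    artifact_rate: float = 2.0  # expected artifacts per image
    seed: int = 0

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ValueError(f"non-finite config parameter: {f.name}={v}")
        if not (0.0 <= self.tail_fraction <= 1.0):
            raise ValueError("tail_fraction must lie in [0, 1]")
        positive = ("pixel_area", "bulk_size_log_sd", "bmu_tail_base", "pore_base_size")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if min(self.n_bmu, self.pore_density, self.noise_sd, self.artifact_rate) < 0:
            raise ValueError("counts, densities, noise_sd and artifact_rate must be non-negative")
        if len(self.canvas_size) != 2 or min(self.canvas_size) < 16:
            raise ValueError("canvas_size must be (H, W) with H, W >= 16")

    def with_(self, **kwargs) -> "SyntheticConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def canvas_area_um2(self) -> float:
        return self.canvas_size[0] * self.canvas_size[1] * self.pixel_area

    @property
    def n_pore(self) -> int:
        return int(round(self.pore_density * self.canvas_area_um2))


@dataclass
class EntitySpec:
    """Intended geometry of one entity before rasterization."""

    kind: str  # "BMU" | "pore"
    size_um2: float
    orientation_deg: float  # major axis, degrees from the vertical (growth front)
    elongation: float  # major/minor axis ratio, >= 1
    center: tuple[float, float]  # (row, col)


@dataclass
class GroundTruth:
    """Per-pixel truth matching a generated image.

    ``bmu_mask``/``pore_mask`` hold per-entity integer ids (0 = background);
    ``truth_table`` has one row per rendered entity with its intended area.
    Entities that could not be placed without overlap are absent from both.
    """

    bmu_mask: np.ndarray
    pore_mask: np.ndarray
    artifact_mask: np.ndarray
    truth_table: pd.DataFrame  # entity_id, kind, area_um2, orientation_deg, elongation

    def validate(self) -> None:
        for kind, mask in (("BMU", self.bmu_mask), ("pore", self.pore_mask)):
            ids_mask = set(np.unique(mask)) - {0}
            rows = self.truth_table[self.truth_table["kind"] == kind]
            ids_table = set(rows["entity_id"].astype(int))
            if ids_mask != ids_table:
                raise ValueError(f"{kind} mask ids and truth_table rows disagree")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


def _wrap_orientation(deg: np.ndarray) -> np.ndarray:
    """Wrap angles into (-90, 90] (axial data)."""
    out = (np.asarray(deg, dtype=float) + 90.0) % 180.0 - 90.0
    out[out == -90.0] = 90.0
    return out


def _sample_population(config: SyntheticConfig, kind: str) -> list[EntitySpec]:
    config.validate()
    h, w = config.canvas_size
    if kind == "BMU":
        rng = _rng(config.seed, 1)
        n = config.n_bmu
        tail_scale = config.bmu_tail_base + config.bmu_tail_scale_slope * config.temperature
        bulk = rng.lognormal(config.bulk_size_log_mean, config.bulk_size_log_sd, size=n)
        is_tail = rng.random(n) < config.tail_fraction
        tail = tail_scale * rng.lognormal(0.0, config.tail_size_log_sd, size=n)
        sizes = np.where(is_tail, tail, bulk)
        mode = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        orient = _wrap_orientation(
            mode * config.dip_angle_mean + rng.normal(0.0, config.dip_angle_sd, size=n)
        )
        elong = np.maximum(
            1.05,
            rng.lognormal(config.bmu_elongation_log_mean, config.bmu_elongation_log_sd, size=n),
        )
    elif kind == "pore":
        rng = _rng(config.seed, 2)
        n = config.n_pore
        tail_scale = config.pore_base_size * math.exp(
            config.pore_growth_rate * config.temperature
        )
        bulk = rng.lognormal(config.pore_bulk_log_mean, config.pore_bulk_log_sd, size=n)
        is_tail = rng.random(n) < config.tail_fraction
        tail = tail_scale * rng.lognormal(0.0, config.tail_size_log_sd, size=n)
        sizes = np.where(is_tail, tail, bulk)
        orient = _wrap_orientation(rng.normal(0.0, config.pore_orientation_sd, size=n))
        elong = np.maximum(
            1.05,
            rng.lognormal(config.pore_elongation_log_mean, config.pore_elongation_log_sd, size=n),
        )
    else:  # pragma: no cover - internal
        raise ValueError(kind)
    centers = np.column_stack([rng.uniform(0, h, size=n), rng.uniform(0, w, size=n)])
    return [
        EntitySpec(kind, float(s), float(o), float(e), (float(r), float(c)))
        for s, o, e, (r, c) in zip(sizes, orient, elong, centers)
    ]


def sample_bmu_population(config: SyntheticConfig) -> list[EntitySpec]:
    """Draw the BMU population for one image.

    Sizes come from the bulk-plus-scaled-tail lognormal mixture; orientations
    from the two dip modes at ±``dip_angle_mean``.  Deterministic in
    ``(config, config.seed)``.
    """
    return _sample_population(config, "BMU")


def sample_pore_population(config: SyntheticConfig) -> list[EntitySpec]:
    """Draw the pore population for one image (growth-front-aligned blobs)."""
    return _sample_population(config, "pore")


def _expected_entity_pixels(config: SyntheticConfig) -> float:
    lnmean = lambda mu, sd: math.exp(mu + sd * sd / 2.0)  # noqa: E731
    bmu_tail_mean = (
        config.bmu_tail_base + config.bmu_tail_scale_slope * config.temperature
    ) * math.exp(config.tail_size_log_sd**2 / 2.0)
    bmu_um2 = config.n_bmu * (
        (1 - config.tail_fraction) * lnmean(config.bulk_size_log_mean, config.bulk_size_log_sd)
        + config.tail_fraction * bmu_tail_mean
    )
    pore_tail_mean = config.pore_base_size * math.exp(
        config.pore_growth_rate * config.temperature
    ) * math.exp(config.tail_size_log_sd**2 / 2.0)
    pore_um2 = config.n_pore * (
        (1 - config.tail_fraction) * lnmean(config.pore_bulk_log_mean, config.pore_bulk_log_sd)
        + config.tail_fraction * pore_tail_mean
    )
    return (bmu_um2 + pore_um2) / config.pixel_area


def _ellipse_pixels(
    spec: EntitySpec,
    center: tuple[float, float],
    shape: tuple[int, int],
    pixel_area: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize an entity as a rotated ellipse of the intended pixel area.

    One corrective rescale keeps the rendered pixel count close to the
    intended ``size_um2 / pixel_area`` (rasterization bias matters for small
    entities).  Returns at least one pixel.
    """
    target_px = spec.size_um2 / pixel_area
    fallback_r = min(max(int(round(center[0])), 0), shape[0] - 1)
    fallback_c = min(max(int(round(center[1])), 0), shape[1] - 1)
    if target_px < 1.5:
        return np.array([fallback_r]), np.array([fallback_c])
    a = math.sqrt(target_px * spec.elongation / math.pi)  # semi-major, px
    b = math.sqrt(target_px / (math.pi * spec.elongation))
    # draw_ellipse's r_radius runs along rows (the growth front) at rotation 0
    rot = math.radians(spec.orientation_deg)
    scale = 1.0
    best: tuple[np.ndarray, np.ndarray] | None = None
    best_err = math.inf
    for _ in range(5):  # iterate the size correction: rasterization biases small ellipses
        rr, cc = draw_ellipse(center[0], center[1], a * scale, b * scale, shape=shape, rotation=rot)
        if len(rr) == 0:
            break
        err = abs(len(rr) - target_px) / target_px
        if err < best_err:
            best, best_err = (rr, cc), err
        if err <= 0.02:
            break
        scale *= math.sqrt(target_px / len(rr))
    if best is None:
        return np.array([fallback_r]), np.array([fallback_c])
    return best


def _place_entities(
    specs: list[EntitySpec],
    shape: tuple[int, int],
    pixel_area: float,
    occupied: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 40,
) -> list[tuple[EntitySpec, np.ndarray, np.ndarray]]:
    """Place entities without overlap or adjacency (1-px margin), largest first.

    The first attempt uses the sampled center; failed attempts resample
    uniformly.  Entities that cannot be placed are dropped.
    """
    placed: list[tuple[EntitySpec, np.ndarray, np.ndarray]] = []
    h, w = shape
    order = sorted(range(len(specs)), key=lambda i: -specs[i].size_um2)
    struct = np.ones((3, 3), dtype=bool)
    for i in order:
        spec = specs[i]
        target_px = spec.size_um2 / pixel_area
        for attempt in range(max_tries):
            center = spec.center if attempt == 0 else (rng.uniform(0, h), rng.uniform(0, w))
            rr, cc = _ellipse_pixels(spec, center, shape, pixel_area)
            if target_px >= 10 and abs(len(rr) - target_px) / target_px > 0.12:
                continue  # badly rasterized or clipped at the border: try elsewhere
            r0, r1 = rr.min(), rr.max() + 1
            c0, c1 = cc.min(), cc.max() + 1
            patch = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
            patch[rr - r0 + 1, cc - c0 + 1] = True
            grown = ndimage.binary_dilation(patch, structure=struct)
            pr0, pc0 = max(r0 - 1, 0), max(c0 - 1, 0)
            pr1, pc1 = min(r1 + 1, h), min(c1 + 1, w)
            window = grown[pr0 - (r0 - 1) : pr1 - (r0 - 1), pc0 - (c0 - 1) : pc1 - (c0 - 1)]
            if not (occupied[pr0:pr1, pc0:pc1] & window).any():
                occupied[rr, cc] = True
                placed.append((replace(spec, center=center), rr, cc))
                break
    return placed


def generate_microstructure_image(config: SyntheticConfig) -> tuple[SEMImage, GroundTruth]:
    """Render one synthetic backscatter image plus exact ground truth.

    BMUs are bright anisotropic plateaus with darker soft rims, pores dark
    blobs elongated along the growth front; Gaussian noise and dirt/scratch
    artifacts are added on top, then intensities are quantized to the 16-bit
    grid so that a write/read TIFF roundtrip is lossless.
    """
    config.validate()
    h, w = config.canvas_size
    expected = _expected_entity_pixels(config)
    if expected > 0.6 * h * w:
        raise ValueError(
            f"overcrowded config: expected entity pixels {expected:.0f} exceed 60% of the "
            f"{h}x{w} canvas (n_bmu={config.n_bmu}, pore_density={config.pore_density}/μm², "
            f"temperature={config.temperature}°C); enlarge the canvas or reduce densities"
        )
    bmu_specs = sample_bmu_population(config)
    pore_specs = sample_pore_population(config)
    rng_place = _rng(config.seed, 3)
    occupied = np.zeros((h, w), dtype=bool)
    # one size-sorted pass over both kinds, so the largest entities claim space first
    placed_all = _place_entities(
        bmu_specs + pore_specs, (h, w), config.pixel_area, occupied, rng_place
    )
    placed_bmu = [t for t in placed_all if t[0].kind == "BMU"]
    placed_pore = [t for t in placed_all if t[0].kind == "pore"]
    if occupied.mean() > 0.9:
        raise ValueError(
            f"rendered occupancy {100 * occupied.mean():.1f}% exceeds 90% "
            f"(n_bmu={config.n_bmu}, pore_density={config.pore_density}/μm²)"
        )

    plateau, rim, background = config.gray_levels
    image = np.full((h, w), background, dtype=float)
    bmu_mask = np.zeros((h, w), dtype=np.int32)
    pore_mask = np.zeros((h, w), dtype=np.int32)
    rows = []

    for idx, (spec, rr, cc) in enumerate(placed_bmu, start=1):
        bmu_mask[rr, cc] = idx
        r0, c0 = rr.min(), cc.min()
        patch = np.zeros((rr.max() - r0 + 1, cc.max() - c0 + 1), dtype=bool)
        patch[rr - r0, cc - c0] = True
        core = ndimage.binary_erosion(patch, iterations=config.rim_width_px)
        image[rr, cc] = rim
        kr, kc = np.nonzero(core)
        image[kr + r0, kc + c0] = plateau
        rows.append((idx, "BMU", spec.size_um2, spec.orientation_deg, spec.elongation))
    for idx, (spec, rr, cc) in enumerate(placed_pore, start=1):
        pore_mask[rr, cc] = idx
        image[rr, cc] = config.pore_gray
        rows.append((idx, "pore", spec.size_um2, spec.orientation_deg, spec.elongation))

    artifact_mask = np.zeros((h, w), dtype=bool)
    rng_art = _rng(config.seed, 5)
    for _ in range(rng_art.poisson(config.artifact_rate)):
        if rng_art.random() < 0.5:  # bright scratch
            r0, c0 = rng_art.integers(0, h), rng_art.integers(0, w)
            ang = rng_art.uniform(0, math.pi)
            length = rng_art.integers(60, 250)
            r1 = int(np.clip(r0 + length * math.sin(ang), 0, h - 1))
            c1 = int(np.clip(c0 + length * math.cos(ang), 0, w - 1))
            rr, cc = draw_line(int(r0), int(c0), r1, c1)
            artifact_mask[rr, cc] = True
            image[rr, cc] = 0.95
        else:  # dark dirt blob
            r0, c0 = rng_art.integers(0, h), rng_art.integers(0, w)
            rr, cc = draw_disk((int(r0), int(c0)), int(rng_art.integers(3, 9)), shape=(h, w))
            artifact_mask[rr, cc] = True
            image[rr, cc] = 0.10

    if config.noise_sd > 0:
        rng_noise = _rng(config.seed, 4)
        image = image + rng_noise.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    image = np.round(image * 65535.0) / 65535.0  # 16-bit grid: lossless TIFF roundtrip

    truth = GroundTruth(
        bmu_mask=bmu_mask,
        pore_mask=pore_mask,
        artifact_mask=artifact_mask,
        truth_table=pd.DataFrame(
            rows, columns=["entity_id", "kind", "area_um2", "orientation_deg", "elongation"]
        ),
    )
    sem = SEMImage(
        pixels=image,
        pixel_area=config.pixel_area,
        specimen_id=f"synthetic-s{config.seed}",
        temperature=config.temperature,
        kind_hint="etched",
    )
    return sem, truth


def generate_mnca_profile(
    pre_level: float,
    post_level: float,
    n_pre: int,
    n_post: int,
    noise_cv: float,
    seed: int,
    *,
    specimen_id: str = "synthetic",
    spacing: float = 1.0,
) -> MnCaSeries:
    """Simulate a two-level Mn/Ca transect with an abrupt changepoint.

    The field-grown zone sits at ``pre_level``, the laboratory zone at
    ``post_level`` (μmol/mol); multiplicative lognormal noise with coefficient
    of variation ``noise_cv`` preserves the level medians.  The true
    changepoint (first laboratory spot) is recorded on the series.
    """
    if pre_level <= 0 or post_level <= 0:
        raise ValueError("Mn/Ca levels must be positive")
    if n_pre < 3 or n_post < 3:
        raise ValueError("need at least 3 spots per zone")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    levels = np.concatenate([np.full(n_pre, pre_level), np.full(n_post, post_level)])
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        rng = np.random.default_rng(seed)
        levels = levels * np.exp(rng.normal(0.0, sigma, size=levels.size))
    return MnCaSeries(
        specimen_id=specimen_id,
        positions=np.arange(n_pre + n_post, dtype=float) * spacing,
        mnca=levels,
        true_changepoint=n_pre,
    )


def sparse_labels_from_truth(
    truth: GroundTruth,
    kind: str = "BMU",
    n_regions: int = 12,
    radius: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Emulate user-drawn training labels from ground truth.

    Returns an integer raster: 0 unlabeled, 1 entity, 2 background; each class
    gets ``n_regions`` small disk-shaped label regions (the workflow requires
    at least 10 per class).  Background labels avoid entities and artifacts.
    """
    entity = (truth.bmu_mask if kind == "BMU" else truth.pore_mask) > 0
    other = (truth.pore_mask if kind == "BMU" else truth.bmu_mask) > 0
    background = ~(entity | other | truth.artifact_mask)
    rng = np.random.default_rng(seed)
    labels = np.zeros(entity.shape, dtype=np.uint8)
    min_dist = 2 * (radius + 1) + 1
    for cls, mask in ((1, entity), (2, background)):
        coords = np.argwhere(mask)
        if len(coords) == 0:
            raise ValueError(f"no pixels available to label for class {cls}")
        chosen: list[np.ndarray] = []
        tries = 0
        while len(chosen) < n_regions and tries < 200 * n_regions:
            tries += 1
            cand = coords[rng.integers(0, len(coords))]
            if any(abs(cand - p).max() < min_dist for p in chosen):
                continue
            rr, cc = draw_disk(tuple(cand), radius, shape=mask.shape)
            keep = mask[rr, cc]
            labels[rr[keep], cc[keep]] = cls
            chosen.append(cand)
        if len(chosen) < n_regions:
            raise ValueError(f"could not place {n_regions} label regions for class {cls}")
    return labels
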