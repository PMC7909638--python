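"""End-to-end synthetic experiment: generate → segment → measure → calibrate.

Reproduces the study design in silico: several specimens per culturing
temperature (six levels, 1–15 °C), one pixel classifier per target (biomineral
units, pores) trained on a single labeled image, morphometry of the predicted
masks with artifact exclusion, and the downstream proxy statistics (top-N
Spearman correlation, linear/exponential calibration, mean-threshold
coverage).  Ground truth is kept alongside to score segmentation quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import morphometry, proxystats, segmentation, synthetic
from .io import SEMImage
from .synthetic import GroundTruth, SyntheticConfig

logger = logging.getLogger("shellproxy.pipeline")

DEFAULT_TEMPERATURES = (1.0, 3.0, 6.0, 9.0, 12.0, 15.0)


@dataclass
class ExperimentResult:
    """Everything the synthetic end-to-end run measures."""

    temperatures: list[float]
    specimen_seeds: list[int]
    iou_bmu: list[float]  # per image, classifier mask vs truth
    iou_pore: list[float]
    coverage: list[float]  # percent, batch mean-gray threshold
    coverage_spearman_r: float
    coverage_spearman_p: float
    bmu_model: proxystats.CalibrationModel  # linear fit to pooled top-N BMU sizes
    pore_model: proxystats.CalibrationModel  # exponential fit to pooled top-N pore sizes
    bmu_groups: list[proxystats.TemperatureGroup]
    pore_groups: list[proxystats.TemperatureGroup]
    classifier_oob: dict


def _iou(pred: np.ndarray, truth: np.ndarray, ignore: np.ndarray) -> float:
    """Intersection-over-union outside the (manually excluded) artifact pixels."""
    keep = ~ignore
    p, t = pred & keep, truth & keep
    union = (p | t).sum()
    return float((p & t).sum() / union) if union else 1.0


def generate_ladder(
    base_config: SyntheticConfig,
    temperatures=DEFAULT_TEMPERATURES,
    n_specimens: int = 3,
    seed: int = 0,
) -> list[tuple[SEMImage, GroundTruth, SyntheticConfig]]:
    """Generate the specimen × temperature image ladder with per-image seeds."""
    out = []
    for ti, temp in enumerate(temperatures):
        for s in range(n_specimens):
            cfg = replace(base_config, temperature=float(temp), seed=int(seed) + 1000 * ti + s)
            img, truth = synthetic.generate_microstructure_image(cfg)
            img.specimen_id = f"T{temp:g}-s{s}"
            out.append((img, truth, cfg))
    return out


def run_synthetic_experiment(
    base_config: SyntheticConfig | None = None,
    temperatures=DEFAULT_TEMPERATURES,
    n_specimens: int = 3,
    seed: int = 0,
    top_n: int = 15,
    min_pixels: int = 3,
) -> ExperimentResult:
    """Run the full pipeline on a synthetic temperature ladder.

    One BMU and one pore classifier are trained on the first specimen of the
    middle temperature level (sparse labels emulating user annotation), then
    applied to every image.  Artifact pixels from the ground truth stand in
    for the manual exclusion step.
    """
    if base_config is None:
        base_config = SyntheticConfig()
    ladder = generate_ladder(base_config, temperatures, n_specimens, seed)

    train_idx = (len(temperatures) // 2) * n_specimens  # first specimen, middle level
    train_img, train_truth, train_cfg = ladder[train_idx]
    classifiers = {}
    for kind in ("BMU", "pore"):
        labels = synthetic.sparse_labels_from_truth(
            train_truth, kind=kind, n_regions=12, seed=train_cfg.seed
        )
        classifiers[kind] = segmentation.train_pixel_classifier(
            [train_img], [labels], seed=int(seed)
        )
        logger.info("%s classifier OOB accuracy: %.4f", kind, classifiers[kind].oob_accuracy)

    iou_bmu, iou_pore = [], []
    group_records: dict[float, dict[str, list]] = {
        float(t): {"BMU": [], "pore": []} for t in temperatures
    }
    images = []
    for img, truth, cfg in ladder:
        images.append(img)
        exclusion = truth.artifact_mask
        for kind, iou_list, truth_mask in (
            ("BMU", iou_bmu, truth.bmu_mask > 0),
            ("pore", iou_pore, truth.pore_mask > 0),
        ):
            mask = segmentation.predict_mask(classifiers[kind], img)
            iou_list.append(_iou(mask.mask, truth_mask, exclusion))
            labeled, _ = morphometry.label_components(mask)
            records = morphometry.measure_particles(
                labeled,
                cfg.pixel_area,
                min_pixels=min_pixels,
                exclusion=exclusion,
                kind=kind,
                specimen_id=img.specimen_id,
                temperature=cfg.temperature,
            )
            group_records[cfg.temperature][kind].extend(records)

    masks, _threshold = segmentation.binarize_mean_threshold(images)
    coverages = [segmentation.coverage(m) for m in masks]
    temps_per_image = [cfg.temperature for _, _, cfg in ladder]
    cov_r, cov_p = proxystats.spearman(coverages, temps_per_image)

    bmu_groups = [
        proxystats.TemperatureGroup(t, group_records[float(t)]["BMU"]) for t in temperatures
    ]
    pore_groups = [
        proxystats.TemperatureGroup(t, group_records[float(t)]["pore"]) for t in temperatures
    ]
    bmu_areas, bmu_temps = proxystats.top_n_pairs(bmu_groups, n=top_n, kind="BMU")
    pore_areas, pore_temps = proxystats.top_n_pairs(pore_groups, n=top_n, kind="pore")
    bmu_model = proxystats.fit_linear(bmu_temps, bmu_areas)
    pore_model = proxystats.fit_exponential(pore_temps, pore_areas)

    return ExperimentResult(
        temperatures=[float(t) for t in temperatures],
        specimen_seeds=[cfg.seed for _, _, cfg in ladder],
        iou_bmu=iou_bmu,
        iou_pore=iou_pore,
        coverage=coverages,
        coverage_spearman_r=cov_r,
        coverage_spearman_p=cov_p,
        bmu_model=bmu_model,
        pore_model=pore_model,
        bmu_groups=bmu_groups,
        pore_groups=pore_groups,
        classifier_oob={k: c.oob_accuracy for k, c in classifiers.items()},
    )


def truth_calibration_replicate(
    base_config: SyntheticConfig | None = None,
    temperatures=DEFAULT_TEMPERATURES,
    n_specimens: int = 3,
    seed: int = 0,
    top_n: int = 15,
) -> dict:
    """Sampling-level parameter-recovery replicate (no imaging).

    Draws the entity populations only, pools the intended areas into
    temperature groups, and refits the calibration models — isolating the
    statistical recovery of the configured effect sizes from segmentation.
    Returns the fitted pore exponential rate ``b``, the configured rate, and
    the top-N BMU Spearman r.
    """
    if base_config is None:
        base_config = SyntheticConfig()
    bmu_pairs, pore_pairs = [], []
    for ti, temp in enumerate(temperatures):
        bmu_areas, pore_areas = [], []
        for s in range(n_specimens):
            cfg = replace(base_config, temperature=float(temp), seed=int(seed) + 1000 * ti + s)
            bmu_areas.extend(sp.size_um2 for sp in synthetic.sample_bmu_population(cfg))
            pore_areas.extend(sp.size_um2 for sp in synthetic.sample_pore_population(cfg))
        for a in sorted(bmu_areas, reverse=True)[:top_n]:
            bmu_pairs.append((a, float(temp)))
        for a in sorted(pore_areas, reverse=True)[:top_n]:
            pore_pairs.append((a, float(temp)))
    pore_model = proxystats.fit_exponential(
        [t for _, t in pore_pairs], [a for a, _ in pore_pairs]
    )
    r, p = proxystats.spearman([a for a, _ in bmu_pairs], [t for _, t in bmu_pairs])
    return {
        "pore_rate_b": pore_model.params["b"],
        "pore_rate_configured": base_config.pore_growth_rate,
        "bmu_top_n_spearman_r": r,
    }
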