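"""Readers and writers for SEM images, label masks, particle tables and Mn/Ca transects.

All pixel coordinates are 0-based, row-major ``(row, col)``.  Areas are always
carried both in pixels and in μm² (``area_um2 = area_px * pixel_area``) to avoid
unit ambiguity between pipeline stages.  Images are exchanged as 8- or 16-bit
grayscale TIFF/PNG and rescaled to intensities in ``[0, 1]`` on read; pipeline
outputs are written as 16-bit TIFF and plain CSV so that reruns diff cleanly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("shellproxy.io")

#: CSV column order for particle tables.
PARTICLE_COLUMNS = (
    "entity_id",
    "kind",
    "area_um2",
    "area_px",
    "elongation",
    "centroid_row",
    "centroid_col",
    "specimen_id",
    "temperature_c",
    "flags",
)


@dataclass
class SEMImage:
    """Calibrated 2-D grayscale SEM backscatter raster.

    Gray value is read as a proxy for surface topography: biomineral plateaus
    appear bright, inter-crystalline depressions and pores dark.

    Parameters
    ----------
    pixels : ndarray
        2-D float array with intensities in ``[0, 1]``.
    pixel_area : float
        Area of one pixel in μm².
    specimen_id : str
        Free-text specimen identifier.
    temperature : float or None
        Culturing temperature in °C, if known.
    kind_hint : str
        ``"etched"`` for biomineral-unit imaging (H2O2-treated surface),
        ``"polished"`` for pore imaging, or ``""``.
    """

    pixels: np.ndarray
    pixel_area: float
    specimen_id: str = ""
    temperature: float | None = None
    kind_hint: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("SEMImage requires a 2-D grayscale array")
        if not np.isfinite(self.pixels).all():
            raise ValueError("image intensities must be finite")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensities must lie in [0, 1], got [{lo}, {hi}]")
        if not (np.isfinite(self.pixel_area) and self.pixel_area > 0):
            raise ValueError("pixel_area must be a positive finite number (μm²/pixel)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area_um2(self) -> float:
        """Total imaged area in μm²."""
        return float(self.pixels.size * self.pixel_area)


@dataclass
class ParticleRecord:
    """One connected microstructural entity (biomineral unit or pore)."""

    entity_id: int
    kind: str  # "BMU" | "pore"
    area_px: int
    area: float  # μm²
    elongation: float
    centroid: tuple[float, float]  # (row, col), 0-based
    specimen_id: str = ""
    temperature: float | None = None
    flags: tuple[str, ...] = ()
    extras: dict = field(default_factory=dict)


@dataclass
class MnCaSeries:
    """Ordered Mn/Ca transect of laser-ablation spots along the growth axis."""

    specimen_id: str
    positions: np.ndarray  # strictly increasing spot positions (index or μm)
    mnca: np.ndarray  # μmol/mol, > 0
    true_changepoint: int | None = None  # known only for synthetic series

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.mnca = np.asarray(self.mnca, dtype=float)
        if self.positions.shape != self.mnca.shape or self.positions.ndim != 1:
            raise ValueError("positions and mnca must be matching 1-D arrays")
        if len(self.positions) and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.mnca <= 0):
            raise ValueError("Mn/Ca values must be positive")

    def __len__(self) -> int:
        return len(self.mnca)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def read_image(
    path: str | Path,
    pixel_area: float,
    *,
    specimen_id: str = "",
    temperature: float | None = None,
    kind_hint: str = "",
) -> SEMImage:
    """Read an 8/16-bit grayscale TIFF or PNG and rescale to ``[0, 1]``.

    Integer intensities are divided by the bit-depth maximum (255 or 65535).
    RGB input is rejected: convert to single-channel grayscale first.
    """
    path = Path(path)
    if pixel_area is None:
        raise ValueError("pixel_area (μm²/pixel) is required to calibrate the image")
    if path.suffix.lower() in {".tif", ".tiff"}:
        raw = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)
    if raw.ndim != 2:
        raise ValueError(
            f"{path.name}: expected single-channel grayscale, got shape {raw.shape}; "
            "convert RGB input to grayscale before reading"
        )
    if raw.dtype == np.uint8:
        pixels = raw.astype(float) / 255.0
    elif raw.dtype == np.uint16:
        pixels = raw.astype(float) / 65535.0
    elif np.issubdtype(raw.dtype, np.floating):
        pixels = raw.astype(float)
    else:
        raise ValueError(f"{path.name}: unsupported dtype {raw.dtype}")
    return SEMImage(
        pixels=pixels,
        pixel_area=pixel_area,
        specimen_id=specimen_id,
        temperature=temperature,
        kind_hint=kind_hint,
    )


def write_image(image: SEMImage, path: str | Path) -> None:
    """Write intensities as 16-bit grayscale TIFF (value = round(I * 65535))."""
    data = np.round(image.pixels * 65535.0).astype(np.uint16)
    tifffile.imwrite(Path(path), data)


def write_label_mask(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label raster as 16-bit TIFF (0 = background)."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


# ---------------------------------------------------------------------------
# particle tables
# ---------------------------------------------------------------------------


def _records_to_frame(records: list[ParticleRecord]) -> pd.DataFrame:
    rows = []
    extra_cols: list[str] = []
    for r in records:
        row = {
            "entity_id": r.entity_id,
            "kind": r.kind,
            "area_um2": r.area,
            "area_px": r.area_px,
            "elongation": r.elongation,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "specimen_id": r.specimen_id,
            "temperature_c": "" if r.temperature is None else r.temperature,
            "flags": ";".join(r.flags),
        }
        for k, v in r.extras.items():
            row[k] = v
            if k not in extra_cols:
                extra_cols.append(k)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(PARTICLE_COLUMNS) + extra_cols)


def write_particle_table(records: list[ParticleRecord], path: str | Path) -> None:
    """Write per-entity records as CSV (stable column order, diffable floats)."""
    frame = _records_to_frame(records)
    frame.to_csv(Path(path), index=False, float_format="%.10g")


def read_particle_table(
    path: str | Path,
    *,
    min_pixels: int = 3,
    column_map: dict[str, str] | None = None,
) -> list[ParticleRecord]:
    """Read a particle table from CSV or XLSX (one row per entity).

    Rows violating invariants (area below the ``min_pixels`` analysis
    threshold, elongation < 1) are flagged on the returned records, never
    silently dropped.  ``column_map`` renames file columns to the expected
    names, for externally produced tables whose layout differs.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=column_map)
    if "area_um2" not in frame.columns:
        raise ValueError(
            f"{path.name}: missing required column 'area_um2' "
            f"(found: {list(frame.columns)}); pass column_map to rename"
        )
    if frame.empty:
        warnings.warn(f"{path.name}: empty particle table", stacklevel=2)
        return []
    records: list[ParticleRecord] = []
    known = set(PARTICLE_COLUMNS)
    for i, row in frame.iterrows():
        flags: list[str] = []
        raw_flags = row.get("flags", "")
        if isinstance(raw_flags, str) and raw_flags:
            flags.extend(raw_flags.split(";"))
        raw_px = row.get("area_px", 0)
        area_px = 0 if pd.isna(raw_px) else int(raw_px)
        if area_px and area_px < min_pixels:
            if "below_min_pixels" not in flags:
                flags.append("below_min_pixels")
        elong = float(row.get("elongation", 1.0) or 1.0)
        if elong < 1.0:
            flags.append("invalid_elongation")
        temp = row.get("temperature_c", None)
        temp = None if temp is None or (isinstance(temp, float) and np.isnan(temp)) or temp == "" else float(temp)
        extras = {k: row[k] for k in frame.columns if k not in known}
        records.append(
            ParticleRecord(
                entity_id=int(row.get("entity_id", i)),
                kind=str(row.get("kind", "BMU")),
                area_px=area_px,
                area=float(row["area_um2"]),
                elongation=elong,
                centroid=(
                    float(row.get("centroid_row", np.nan)),
                    float(row.get("centroid_col", np.nan)),
                ),
                specimen_id=str(row.get("specimen_id", "")),
                temperature=temp,
                flags=tuple(flags),
                extras=extras,
            )
        )
    n_flagged = sum(1 for r in records if "below_min_pixels" in r.flags)
    if n_flagged:
        logger.info(
            "%s: %d of %d rows below the %d-pixel analysis threshold (flagged)",
            path.name,
            n_flagged,
            len(records),
            min_pixels,
        )
    return records


# ---------------------------------------------------------------------------
# Mn/Ca transects
# ---------------------------------------------------------------------------


def read_mnca_table(
    path: str | Path,
    *,
    column_map: dict[str, str] | None = None,
) -> dict[str, MnCaSeries]:
    """Read an Mn/Ca spot table (CSV/XLSX) into one ordered series per specimen.

    Expects columns ``specimen_id``, ``position``, ``mnca_umol_mol``; one row
    per laser spot.  Non-positive Mn/Ca rows are physically impossible and are
    rejected with a warning; duplicate positions within a specimen are an error.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=column_map)
    required = {"specimen_id", "position", "mnca_umol_mol"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    bad = frame["mnca_umol_mol"] <= 0
    if bad.any():
        warnings.warn(
            f"{path.name}: rejected {int(bad.sum())} row(s) with non-positive Mn/Ca",
            stacklevel=2,
        )
        frame = frame[~bad]
    out: dict[str, MnCaSeries] = {}
    for sid, sub in frame.groupby("specimen_id", sort=True):
        sub = sub.sort_values("position", kind="stable")
        pos = sub["position"].to_numpy(dtype=float)
        if len(pos) > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError(f"{path.name}: duplicate spot positions for specimen {sid}")
        out[str(sid)] = MnCaSeries(
            specimen_id=str(sid), positions=pos, mnca=sub["mnca_umol_mol"].to_numpy(dtype=float)
        )
    return out


def write_mnca_table(series_set: list[MnCaSeries], path: str | Path) -> None:
    rows = [
        {"specimen_id": s.specimen_id, "position": p, "mnca_umol_mol": v}
        for s in series_set
        for p, v in zip(s.positions, s.mnca)
    ]
    pd.DataFrame(rows, columns=["specimen_id", "position", "mnca_umol_mol"]).to_csv(
        Path(path), index=False, float_format="%.10g"
    )
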