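"""ROI placement and the lesion-to-liver contrast (LLC) statistic.

LLC is defined as ``|SI_liver - SI_lesion| / SI_liver`` from mean signal
intensities of two circular ROIs: one inside the lesion avoiding necrotic
portions, one of identical radius in the adjacent parenchyma avoiding
vessels.  Manual "as large as possible" placement is operationalized as
the largest inscribed pixel-center disc after a one-pixel erosion margin,
with deterministic tie-breaks, so placements are auditable and identical
across all acquisition conditions of a series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .errors import (
    CompletenessError,
    LesionTooSmallError,
    PlacementError,
    UndefinedContrastError,
)
from .phantom import LABELS, ImageSeries

__all__ = [
    "ROISample",
    "place_rois",
    "measure_si",
    "llc",
    "build_cohort_table",
    "condition_label",
]


@dataclass(frozen=True)
class ROISample:
    """A circular pixel ROI within one compartment."""

    roi_id: str
    compartment: str  # "lesion" | "parenchyma"
    center: tuple[int, int]
    radius_px: int
    rows: np.ndarray
    cols: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


def _disc_pixels(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return np.nonzero(inside)


def _largest_inscribed_disc(eligible: np.ndarray) -> tuple[tuple[int, int], int]:
    """Center and integer radius of the largest disc that fits in
    ``eligible`` with a one-pixel erosion margin.

    A disc of radius r centered at c fits iff the distance from c to the
    nearest ineligible pixel exceeds r; the margin subtracts one more
    pixel.  Ties go to the smallest (row, col) center (row-major argmax).
    """
    edt = distance_transform_edt(eligible)
    radius = np.ceil(edt).astype(int) - 2
    flat = int(np.argmax(radius))
    center = np.unravel_index(flat, eligible.shape)
    return (int(center[0]), int(center[1])), int(radius[center])


def place_rois(
    label_map: np.ndarray, lesion_id: str = "", min_area: int = 5
) -> tuple[ROISample, ROISample]:
    """Place the lesion ROI and the size-matched parenchyma ROI.

    The lesion ROI is the largest inscribed disc in the lesion label
    excluding necrosis; the parenchyma ROI has the same radius, centered
    at the parenchyma location nearest to the lesion boundary whose disc
    contains parenchyma pixels only.
    """
    label_map = np.asarray(label_map)
    eligible = label_map == LABELS["lesion"]
    if int(eligible.sum()) < min_area:
        raise LesionTooSmallError(
            f"lesion {lesion_id or '?'}: {int(eligible.sum())} eligible pixels "
            f"< min_area {min_area}"
        )
    center, radius = _largest_inscribed_disc(eligible)
    if radius < 0:
        raise LesionTooSmallError(
            f"lesion {lesion_id or '?'}: no disc fits after the erosion margin"
        )
    rows, cols = _disc_pixels(label_map.shape, center, radius)
    lesion_roi = ROISample(
        roi_id=f"{lesion_id}:lesion", compartment="lesion",
        center=center, radius_px=radius, rows=rows, cols=cols,
    )

    parenchyma = label_map == LABELS["parenchyma"]
    edt_par = distance_transform_edt(parenchyma)
    valid = edt_par > radius + 1  # same erosion margin as the lesion ROI
    if not valid.any():
        raise PlacementError(
            f"lesion {lesion_id or '?'}: no parenchyma placement for radius {radius}"
        )
    dist_to_lesion = distance_transform_edt(label_map != LABELS["lesion"])
    cost = np.where(valid, dist_to_lesion, np.inf)
    flat = int(np.argmin(cost))  # ties -> smallest (row, col), row-major
    p_center = np.unravel_index(flat, label_map.shape)
    p_center = (int(p_center[0]), int(p_center[1]))
    prows, pcols = _disc_pixels(label_map.shape, p_center, radius)
    par_roi = ROISample(
        roi_id=f"{lesion_id}:parenchyma", compartment="parenchyma",
        center=p_center, radius_px=radius, rows=prows, cols=pcols,
    )
    return lesion_roi, par_roi


def measure_si(image: np.ndarray, roi: ROISample) -> float:
    """Arithmetic mean signal intensity over the ROI pixels."""
    image = np.asarray(image)
    if (
        roi.rows.min() < 0
        or roi.cols.min() < 0
        or roi.rows.max() >= image.shape[0]
        or roi.cols.max() >= image.shape[1]
    ):
        raise ValueError(f"ROI {roi.roi_id} out of image bounds {image.shape}")
    return float(image[roi.rows, roi.cols].mean())


def llc(si_liver: float, si_lesion: float) -> float:
    """Lesion-to-liver contrast ``|SI_liver - SI_lesion| / SI_liver``.

    Dimensionless and invariant under common positive scaling of both
    inputs.  Undefined when the liver signal is exactly zero (possible
    only in noise-free simulations at the parenchyma null point).
    """
    if si_liver < 0 or si_lesion < 0:
        raise ValueError("signal intensities must be non-negative")
    if si_liver == 0:
        raise UndefinedContrastError("SI_liver is zero; LLC undefined at the null point")
    return abs(si_liver - si_lesion) / si_liver


def condition_label(condition) -> str:
    """Canonical condition name: ``TI<ms>`` for inversion times, ``VIBE``."""
    if isinstance(condition, str):
        return condition
    ti = float(condition)
    return f"TI{int(ti)}" if ti == int(ti) else f"TI{ti:g}"


def build_cohort_table(
    lesion_series: Mapping[str, tuple[ImageSeries, np.ndarray]],
    covariates: pd.DataFrame | None = None,
    conditions: Sequence | None = None,
    min_area: int = 5,
) -> pd.DataFrame:
    """One LLC record per lesion and acquisition condition (long format).

    ``lesion_series`` maps lesion_id to (series, label_map).  ROIs are
    placed once per lesion on the label map and frozen across all
    conditions.  Records whose liver signal is exactly zero are emitted
    with ``llc = NaN`` and a ``missing_reason`` instead of being dropped.
    A missing condition raises :class:`CompletenessError`.
    """
    records = []
    expected = None
    for lesion_id, (series, label_map) in lesion_series.items():
        names = [condition_label(t) for t in series.ti_list_ms]
        images = list(series.data)
        if series.vibe is not None:
            names.append("VIBE")
            images.append(series.vibe)
        if conditions is not None:
            want = [condition_label(c) for c in conditions]
            missing = [c for c in want if c not in names]
            if missing:
                raise CompletenessError(
                    f"lesion {lesion_id} missing condition(s): {missing}"
                )
            keep = [names.index(c) for c in want]
            names = [names[i] for i in keep]
            images = [images[i] for i in keep]
        if expected is None:
            expected = names
        elif names != expected:
            raise CompletenessError(
                f"lesion {lesion_id} conditions {names} != {expected}"
            )
        lesion_roi, par_roi = place_rois(label_map, lesion_id, min_area=min_area)
        for name, image in zip(names, images):
            si_les = measure_si(image, lesion_roi)
            si_liv = measure_si(image, par_roi)
            try:
                value, reason = llc(si_liv, si_les), ""
            except UndefinedContrastError:
                value, reason = np.nan, "si_liver_zero"
            records.append(
                {
                    "lesion_id": lesion_id,
                    "condition": name,
                    "si_liver": si_liv,
                    "si_lesion": si_les,
                    "llc": value,
                    "roi_radius_px": lesion_roi.radius_px,
                    "missing_reason": reason,
                }
            )
    table = pd.DataFrame(records)
    if covariates is not None:
        table = table.merge(covariates, on="lesion_id", how="left", validate="m:1")
    return table
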