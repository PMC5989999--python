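"""Scalar summaries of dynamics matrices and the 36-measure feature vector.

Three image-style measures quantify each k x k dynamics matrix:

mean
    ``sum(f) / k**2`` -- overall window-to-window correlation level;
contrast
    ``sum over in-bounds (x, y) of (f(x, y) - f(x+1, y+1))**2`` -- squared
    differences along the diagonal neighbor direction, a texture-contrast
    measure sensitive to the amplitude of state-to-state differences;
sharpness (Brenner operator)
    ``sum of (f(x+2, y) - f(x, y))**2 + (f(x, y+2) - f(x, y))**2`` -- squared
    two-step differences along both axes, sensitive to how abruptly the
    matrix switches between correlated blocks.

With two matrix kinds (CDM, PDM) and six frequency bands this yields 36
named measures per 10-s segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BAND_ORDER, BANDS, Segment, bandpass_filter_segment
from .windows import (DynamicsMatrix, band_power_series,
                      correlation_vector_series, dynamics_matrix,
                      plan_windows)

__all__ = [
    "MeasureSet",
    "FeatureVector",
    "FEATURE_NAMES",
    "matrix_mean",
    "matrix_contrast",
    "matrix_sharpness",
    "measure_matrix",
    "feature_vector",
    "compute_segment_features",
]

MEASURE_ORDER = ("mean", "contrast", "sharpness")
KIND_ORDER = ("cdm", "pdm")

#: Canonical feature names, e.g. ``cdm_sharpness_alpha``; fixed order.
FEATURE_NAMES = tuple(
    f"{kind}_{measure}_{band}"
    for measure in MEASURE_ORDER
    for kind in KIND_ORDER
    for band in BAND_ORDER
)


@dataclass(frozen=True)
class MeasureSet:
    """The three scalar measures of one dynamics matrix."""

    mean: float
    contrast: float
    sharpness: float
    kind: str
    band: str


@dataclass
class FeatureVector:
    """The 36 named dynamics measures of one segment, in canonical order."""

    segment_id: str
    values: dict[str, float]
    group_label: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature names must be canonical; missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])


def matrix_mean(M: DynamicsMatrix | np.ndarray) -> float:
    """Sum of all k^2 entries divided by k^2 (diagonal included)."""
    values = M.values if isinstance(M, DynamicsMatrix) else np.asarray(M)
    return float(values.mean())


def matrix_contrast(M: DynamicsMatrix | np.ndarray,
                    normalize_by_count: bool = False,
                    zero_pad: bool = False) -> float:
    """Sum of squared diagonal-neighbor differences.

    Only in-bounds index pairs contribute unless ``zero_pad`` extends the
    matrix with a zero border.  ``normalize_by_count`` divides by the number
    of summed terms (for comparing across different k).
    """
    values = M.values if isinstance(M, DynamicsMatrix) else np.asarray(M)
    k = values.shape[0]
    if k < 2 and not zero_pad:
        raise ValueError("contrast requires k >= 2")
    if zero_pad:
        values = np.pad(values, ((0, 1), (0, 1)))
    d = values[1:, 1:] - values[:-1, :-1]
    total = float(np.sum(d ** 2))
    if normalize_by_count:
        total /= d.size
    return total


def matrix_sharpness(M: DynamicsMatrix | np.ndarray,
                     normalize_by_count: bool = False,
                     zero_pad: bool = False) -> float:
    """Brenner sharpness: squared two-step differences along both axes."""
    values = M.values if isinstance(M, DynamicsMatrix) else np.asarray(M)
    k = values.shape[0]
    if k < 3 and not zero_pad:
        raise ValueError("sharpness requires k >= 3")
    if zero_pad:
        values = np.pad(values, ((0, 2), (0, 2)))
    dx = values[2:, :] - values[:-2, :]
    dy = values[:, 2:] - values[:, :-2]
    total = float(np.sum(dx ** 2) + np.sum(dy ** 2))
    if normalize_by_count:
        total /= dx.size + dy.size
    return total


def measure_matrix(M: DynamicsMatrix, **kwargs) -> MeasureSet:
    """All three measures of one dynamics matrix."""
    return MeasureSet(
        mean=matrix_mean(M),
        contrast=matrix_contrast(M, **kwargs),
        sharpness=matrix_sharpness(M, **kwargs),
        kind=M.kind,
        band=M.band.name if M.band else "raw",
    )


def feature_vector(segment_bands: dict[str, Segment], step: int = 1,
                   window_len: float = 2.0,
                   group_label: str | None = None,
                   subject_id: str | None = None) -> FeatureVector:
    """Assemble the 36-measure vector from the six band-filtered segments.

    ``segment_bands`` maps each canonical band name to the segment filtered
    to that band.
    """
    missing = [b for b in BAND_ORDER if b not in segment_bands]
    if missing:
        raise ValueError(f"missing band(s): {missing}")
    per_band: dict[tuple[str, str], MeasureSet] = {}
    segment_id = ""
    for band_name in BAND_ORDER:
        seg = segment_bands[band_name]
        segment_id = seg.segment_id
        plan = plan_windows(seg, window_len=window_len, step=step)
        cdm = dynamics_matrix(correlation_vector_series(seg, plan), "CDM",
                              band=BANDS[band_name])
        pdm = dynamics_matrix(band_power_series(seg, plan), "PDM",
                              band=BANDS[band_name])
        per_band[("cdm", band_name)] = measure_matrix(cdm)
        per_band[("pdm", band_name)] = measure_matrix(pdm)
    values = {
        f"{kind}_{measure}_{band}": float(getattr(per_band[(kind, band)], measure))
        for measure in MEASURE_ORDER
        for kind in KIND_ORDER
        for band in BAND_ORDER
    }
    return FeatureVector(segment_id=segment_id, values=values,
                         group_label=group_label, subject_id=subject_id)


def compute_segment_features(segment: Segment, step: int = 1,
                             window_len: float = 2.0,
                             group_label: str | None = None,
                             subject_id: str | None = None) -> FeatureVector:
    """Filter a raw segment into the six bands and compute all 36 measures."""
    bands = {name: bandpass_filter_segment(segment, BANDS[name])
             for name in BAND_ORDER}
    return feature_vector(bands, step=step, window_len=window_len,
                          group_label=group_label, subject_id=subject_id)
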