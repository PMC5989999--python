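"""Sliding-window network features and the k x k dynamics matrices.

From each band-filtered 10-s segment a sliding 2-s window (canonical step:
one sample) yields, per window, (a) the vectorized upper triangle of the
channel-to-channel Pearson correlation matrix and (b) the per-channel mean
band power.  Correlating these window vectors across all window pairs gives
the correlation dynamics matrix (CDM) and the power dynamics matrix (PDM),
whose off-diagonal structure encodes recurrence and persistence of network
states over the segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import BandSpec, Segment

__all__ = [
    "WindowPlan",
    "CorrelationVectorSeries",
    "PowerSeries",
    "DynamicsMatrix",
    "plan_windows",
    "correlation_vector_series",
    "band_power_series",
    "dynamics_matrix",
    "cdm_pdm_difference",
]

logger = logging.getLogger(__name__)

#: Canonical sliding-window length, seconds.
WINDOW_LEN_S = 2.0
#: Windows processed per chunk when vectorizing (bounds peak memory).
_CHUNK = 256


@dataclass(frozen=True)
class WindowPlan:
    """Start indices of all sliding windows within one segment."""

    window_samples: int
    step: int
    starts: np.ndarray
    n_channels: int

    @property
    def k(self) -> int:
        return len(self.starts)


@dataclass
class CorrelationVectorSeries:
    """k x m matrix; row t = upper-triangle Pearson pattern of window t."""

    values: np.ndarray
    segment_id: str = ""
    n_degenerate: int = 0


@dataclass
class PowerSeries:
    """k x n matrix; entry (t, c) = mean band power of channel c, window t."""

    values: np.ndarray
    segment_id: str = ""


@dataclass
class DynamicsMatrix:
    """k x k window-to-window correlation matrix (CDM or PDM)."""

    values: np.ndarray
    kind: str                      # "CDM" | "PDM"
    band: BandSpec | None = None
    segment_id: str = ""
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("CDM", "PDM"):
            raise ValueError(f"kind must be CDM or PDM, got {self.kind!r}")


def plan_windows(segment: Segment, window_len: float = WINDOW_LEN_S,
                 step: int = 1) -> WindowPlan:
    """Window starts ``0, step, 2*step, ...`` up to the last full window.

    Both endpoints are included, so a 10-s segment with 2-s windows at unit
    step gives ``k = 8*fs + 1`` windows.
    """
    if step < 1:
        raise ValueError("step must be >= 1 sample")
    w = int(round(window_len * segment.fs))
    if w > segment.n_samples:
        raise ValueError(
            f"window ({window_len} s = {w} samples) longer than segment "
            f"({segment.n_samples} samples)")
    last = segment.n_samples - w
    starts = np.arange(0, last + 1, step, dtype=int)
    return WindowPlan(window_samples=w, step=int(step), starts=starts,
                      n_channels=segment.n_channels)


def _window_view(data: np.ndarray, plan: WindowPlan) -> np.ndarray:
    """Strided (k, n, w) view of all planned windows."""
    sw = np.lib.stride_tricks.sliding_window_view(
        data, plan.window_samples, axis=1)       # (n, T-w+1, w)
    return sw[:, plan.starts, :].transpose(1, 0, 2)


def correlation_vector_series(segment: Segment,
                              plan: WindowPlan) -> CorrelationVectorSeries:
    """Per-window pairwise Pearson correlations, vectorized upper triangle.

    Row-major upper-triangle order (excluding the diagonal), m = n(n-1)/2
    columns.  A channel that is constant within a window has undefined
    correlations; those entries are set to 0 and counted.
    """
    n = plan.n_channels
    iu, ju = np.triu_indices(n, k=1)
    k = plan.k
    out = np.empty((k, iu.size))
    windows = _window_view(segment.data, plan)
    n_degenerate = 0
    for a in range(0, k, _CHUNK):
        b = min(a + _CHUNK, k)
        raw = windows[a:b]
        w = raw - raw.mean(axis=2, keepdims=True)
        cov = np.matmul(w, w.transpose(0, 2, 1))      # (b-a, n, n)
        var = np.einsum("tii->ti", cov)
        # a channel constant within the window has zero variance up to
        # float cancellation; compare against the raw signal energy
        floor = (raw ** 2).sum(axis=2) * 1e-20
        constant = var <= floor
        sd = np.sqrt(var)
        denom = sd[:, iu] * sd[:, ju]
        bad = constant[:, iu] | constant[:, ju] | (denom == 0)
        n_degenerate += int(bad.sum())
        denom[bad] = 1.0
        r = cov[:, iu, ju] / denom
        r[bad] = 0.0
        out[a:b] = np.clip(r, -1.0, 1.0)
    if n_degenerate:
        logger.warning("%d degenerate (constant-channel) window pairs set "
                       "to correlation 0 in %s", n_degenerate,
                       segment.segment_id)
    return CorrelationVectorSeries(out, segment_id=segment.segment_id,
                                   n_degenerate=n_degenerate)


def band_power_series(segment: Segment, plan: WindowPlan) -> PowerSeries:
    """Mean squared amplitude of the band-limited signal per channel/window."""
    k = plan.k
    out = np.empty((k, plan.n_channels))
    windows = _window_view(segment.data, plan)
    for a in range(0, k, _CHUNK):
        b = min(a + _CHUNK, k)
        out[a:b] = np.mean(windows[a:b] ** 2, axis=2)
    return PowerSeries(out, segment_id=segment.segment_id)


def dynamics_matrix(rows: CorrelationVectorSeries | PowerSeries,
                    kind: str, band: BandSpec | None = None) -> DynamicsMatrix:
    """All-pairs zero-lag Pearson correlation between window vectors.

    Constant rows have undefined correlation; their off-diagonal entries are
    set to 0 (diagonal stays 1) and counted.
    """
    X = np.asarray(rows.values, dtype=float)
    k, m = X.shape
    if k < 2:
        raise ValueError("need at least 2 windows")
    if m < 2:
        raise ValueError("window vectors need at least 2 elements")
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.linalg.norm(Xc, axis=1)
    # constant rows up to float cancellation are undefined, not just exact 0
    degenerate = sd ** 2 <= (X ** 2).sum(axis=1) * 1e-20
    n_degenerate = int(degenerate.sum())
    sd_safe = np.where(degenerate, 1.0, sd)
    Z = Xc / sd_safe[:, None]
    C = Z @ Z.T
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    C[degenerate, :] = 0.0
    C[:, degenerate] = 0.0
    np.fill_diagonal(C, 1.0)
    if n_degenerate:
        logger.warning("%d constant window vectors set to correlation 0 in "
                       "%s %s", n_degenerate, kind, rows.segment_id)
    return DynamicsMatrix(C, kind=kind, band=band,
                          segment_id=getattr(rows, "segment_id", ""),
                          n_degenerate=n_degenerate)


def cdm_pdm_difference(cdm: DynamicsMatrix, pdm: DynamicsMatrix) -> float:
    """Mean over all k^2 elements of (CDM - PDM).

    Positive values mean correlation states recur more strongly across time
    than band-power states.
    """
    if cdm.values.shape != pdm.values.shape:
        raise ValueError("CDM and PDM shapes differ: "
                         f"{cdm.values.shape} vs {pdm.values.shape}")
    return float(np.mean(cdm.values - pdm.values))
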