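"""Subject-level temporal preprocessing.

The pipeline order is fixed: motion screening, band-pass filtering of the
regional signals, then regression of nuisance time courses (six rigid-body
motion parameters, white-matter and ventricle signals) from the *filtered*
series.  Filtering before regression matters — the two operations do not
commute — and the package enforces this order in :func:`preprocess_subject`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as spsig

from .config import ConfigurationError
from .synthetic import NuisanceSet, RoiTimeSeries

__all__ = [
    "MotionSummary",
    "screen_motion",
    "bandpass",
    "regress_nuisance",
    "aggregate_rois",
    "preprocess_subject",
]


@dataclass(frozen=True)
class MotionSummary:
    """Per-axis maxima of absolute head motion."""

    max_displacement_mm: tuple[float, float, float]
    max_rotation_deg: tuple[float, float, float]

    @property
    def worst_displacement(self) -> float:
        return max(self.max_displacement_mm)

    @property
    def worst_rotation(self) -> float:
        return max(self.max_rotation_deg)


def screen_motion(nuisance: NuisanceSet, displacement_limit_mm: float = 1.5,
                  rotation_limit_deg: float = 1.5) -> tuple[bool, MotionSummary]:
    """Motion-based subject exclusion.

    A subject fails if the maximum absolute translation on any axis is
    strictly larger than ``displacement_limit_mm`` or the maximum absolute
    rotation on any axis is strictly larger than ``rotation_limit_deg``.
    Values exactly at the limit pass.

    Returns ``(passed, summary)``.
    """
    motion = np.asarray(nuisance.motion, dtype=float)
    if motion.ndim != 2 or motion.shape[0] != 6:
        raise ValueError("motion matrix must have 6 rows "
                         "(3 translations, 3 rotations)")
    abs_max = np.abs(motion).max(axis=1)
    summary = MotionSummary(tuple(abs_max[:3]), tuple(abs_max[3:]))
    passed = (summary.worst_displacement <= displacement_limit_mm
              and summary.worst_rotation <= rotation_limit_deg)
    return passed, summary


def bandpass(ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08,
             order: int = 4) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass of every region's series.

    A forward-backward (``sosfiltfilt``) pass of an order-``order``
    Butterworth band-pass is used, so the effective attenuation is doubled
    and no phase shift is introduced — phase distortion would corrupt the
    Pearson correlations computed downstream.  Output length equals input
    length.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0.0 < low_hz < high_hz < nyquist:
        raise ConfigurationError(
            f"band [{low_hz}, {high_hz}] Hz invalid for TR={ts.tr_seconds}s "
            f"(Nyquist {nyquist:g} Hz)")
    sos = spsig.butter(order, [low_hz, high_hz], btype="bandpass",
                       fs=1.0 / ts.tr_seconds, output="sos")
    # even-reflection padding keeps the forward-backward transients of the
    # very-low-frequency high-pass pole small on short series
    filtered = spsig.sosfiltfilt(sos, ts.data, axis=1, padtype="even")
    return RoiTimeSeries(ts.region_labels, filtered, ts.tr_seconds)


def regress_nuisance(ts: RoiTimeSeries, nuisance: NuisanceSet) -> RoiTimeSeries:
    """Remove nuisance time courses from every region by linear regression.

    The design holds an intercept plus the eight nuisance regressors; the
    returned series are the least-squares residuals, exactly orthogonal to
    every regressor.  A rank-deficient design triggers a warning and a
    pseudo-inverse fit (residuals remain well defined).
    """
    if nuisance.n_timepoints != ts.n_timepoints:
        raise ValueError("nuisance and time series lengths differ "
                         f"({nuisance.n_timepoints} vs {ts.n_timepoints})")
    design = np.column_stack([np.ones(ts.n_timepoints), nuisance.design().T])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("nuisance design is rank-deficient; using pseudo-inverse",
                      RuntimeWarning, stacklevel=2)
    beta, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    residuals = ts.data.T - design @ beta
    return RoiTimeSeries(ts.region_labels, residuals.T, ts.tr_seconds)


def aggregate_rois(voxel_data: np.ndarray, labels, region_order=None,
                   tr_seconds: float = 2.0) -> RoiTimeSeries:
    """Average voxel time series into region mean series.

    Parameters
    ----------
    voxel_data
        (n_voxels, n_timepoints) matrix.
    labels
        Region label for each voxel row.
    region_order
        Canonical output ordering; defaults to first-appearance order of
        ``labels``.  Every region in the order must own at least one voxel.
    """
    voxel_data = np.asarray(voxel_data, dtype=float)
    labels = list(labels)
    if voxel_data.ndim != 2 or len(labels) != voxel_data.shape[0]:
        raise ValueError("labels must map one region per voxel row")
    if region_order is None:
        region_order = list(dict.fromkeys(labels))
    arr_labels = np.asarray(labels, dtype=object)
    rows = []
    for region in region_order:
        members = np.nonzero(arr_labels == region)[0]
        if members.size == 0:
            raise ValueError(f"region {region!r} has no member voxels")
        rows.append(voxel_data[members].mean(axis=0))
    return RoiTimeSeries(tuple(region_order), np.vstack(rows), tr_seconds)


def preprocess_subject(ts: RoiTimeSeries, nuisance: NuisanceSet,
                       low_hz: float = 0.01, high_hz: float = 0.08) -> RoiTimeSeries:
    """Band-pass then nuisance-regress one subject (the pipeline order)."""
    return regress_nuisance(bandpass(ts, low_hz, high_hz), nuisance)
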