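"""ROI time series to Fisher-z functional connectivity.

This module covers the signal-level denoising steps applied to extracted
ROI time series (nuisance regression and temporal band-pass filtering)
and the conversion of the denoised signals into an ROI-by-ROI Fisher-z
connectivity matrix. Spatial preprocessing of the raw images is assumed
to have happened upstream; the entry point here is a T x N matrix of
per-ROI BOLD signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

logger = logging.getLogger(__name__)

#: Default band-pass edges (Hz) for resting-state BOLD denoising.
DEFAULT_BANDPASS_LOW_HZ = 0.008
DEFAULT_BANDPASS_HIGH_HZ = 0.10

#: Correlations are clipped to +/-(1 - FISHER_CLIP) before atanh so that
#: numerically perfect correlations stay finite in z-units.
FISHER_CLIP = 1e-7


class ConnectivityError(ValueError):
    """Raised for invalid time series or connectivity inputs."""


@dataclass
class ROITimeSeries:
    """A subject's extracted ROI signals.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    data : ndarray of shape (T, N)
        One column per ROI, one row per sample. Arbitrary signal units.
    roi_labels : list of str
        N unique ROI names, in column order. The label order must be
        identical across a cohort.
    sampling_interval : float
        Repetition time (TR) in seconds.
    """

    subject_id: str
    data: np.ndarray
    roi_labels: list[str] = field(repr=False)
    sampling_interval: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConnectivityError("time-series data must be 2-D (T x N)")
        t, n = self.data.shape
        if t < 10:
            raise ConnectivityError(f"need at least 10 samples, got T={t}")
        if len(self.roi_labels) != n:
            raise ConnectivityError(
                f"{len(self.roi_labels)} labels for {n} data columns"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ConnectivityError("ROI labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ConnectivityError("time-series data contains non-finite values")
        if self.sampling_interval <= 0:
            raise ConnectivityError("sampling_interval must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.sampling_interval)


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N Fisher-z connectivity matrix with zero diagonal."""

    subject_id: str
    z: np.ndarray
    roi_labels: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.roi_labels)
        if self.z.shape != (n, n):
            raise ConnectivityError(
                f"matrix shape {self.z.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.z)):
            raise ConnectivityError("connectivity matrix contains non-finite values")
        if not np.allclose(self.z, self.z.T, atol=1e-8):
            raise ConnectivityError("connectivity matrix is not symmetric")
        if np.any(np.diag(self.z) != 0.0):
            raise ConnectivityError("connectivity matrix diagonal must be zero")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


def bandpass_filter(
    ts: ROITimeSeries,
    low_hz: float = DEFAULT_BANDPASS_LOW_HZ,
    high_hz: float = DEFAULT_BANDPASS_HIGH_HZ,
) -> ROITimeSeries:
    """Zero-phase band-pass filter each ROI signal.

    A second-order Butterworth filter is applied forward and backward
    (``filtfilt``), so the output has no phase distortion. Column means
    are removed first; the DC component is outside the pass band.

    Raises
    ------
    ConnectivityError
        If the upper edge reaches the Nyquist frequency of the sampling
        grid.
    """
    nyquist = ts.nyquist_hz
    if not 0 < low_hz < high_hz:
        raise ConnectivityError(
            f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})"
        )
    if high_hz >= nyquist:
        raise ConnectivityError(
            f"high_hz={high_hz} Hz is at or above the Nyquist limit "
            f"{nyquist:.4g} Hz for TR={ts.sampling_interval} s"
        )
    fs = 1.0 / ts.sampling_interval
    sos = _signal.butter(2, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    demeaned = ts.data - ts.data.mean(axis=0, keepdims=True)
    filtered = _signal.sosfiltfilt(sos, demeaned, axis=0)
    return ROITimeSeries(
        subject_id=ts.subject_id,
        data=filtered,
        roi_labels=list(ts.roi_labels),
        sampling_interval=ts.sampling_interval,
    )


def regress_nuisance(ts: ROITimeSeries, confounds: np.ndarray) -> ROITimeSeries:
    """Remove confound signals from every ROI column by least squares.

    An intercept column is always included, so residuals are mean-free
    even when the confound matrix lacks a constant term. Each ROI column
    is replaced by its residual against ``[intercept | confounds]``.

    Raises
    ------
    ConnectivityError
        If the confound matrix is rank deficient; the error names the
        offending (collinear) columns.
    """
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] == 1 and confounds.shape[1] == ts.n_samples:
        confounds = confounds.T
    t, k = confounds.shape
    if t != ts.n_samples:
        raise ConnectivityError(
            f"confounds have {t} rows but time series has {ts.n_samples}"
        )
    if k >= ts.n_samples:
        raise ConnectivityError("need fewer confounds than time points")
    if not np.all(np.isfinite(confounds)):
        raise ConnectivityError("confound matrix contains non-finite values")

    x = np.column_stack([np.ones(t), confounds])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = _collinear_columns(x)
        raise ConnectivityError(
            "confound matrix is rank deficient; collinear confound columns "
            f"(0-based, excluding intercept): {bad}"
        )
    beta, *_ = np.linalg.lstsq(x, ts.data, rcond=None)
    residuals = ts.data - x @ beta
    return ROITimeSeries(
        subject_id=ts.subject_id,
        data=residuals,
        roi_labels=list(ts.roi_labels),
        sampling_interval=ts.sampling_interval,
    )


def _collinear_columns(x: np.ndarray) -> list[int]:
    """Indices of confound columns (excluding intercept) that add no rank."""
    bad = []
    kept = x[:, :1]
    for j in range(1, x.shape[1]):
        trial = np.column_stack([kept, x[:, j]])
        if np.linalg.matrix_rank(trial) == kept.shape[1]:
            bad.append(j - 1)
        else:
            kept = trial
    return bad


def compute_fc(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson-correlate all ROI pairs and Fisher-z transform.

    ``z[i, j] = atanh(r_ij)`` with ``r`` clipped to ``+/-(1 - 1e-7)``
    so duplicated signals stay finite. The diagonal is forced to zero
    and negative correlations are retained (downstream stages decide how
    to treat them).

    Raises
    ------
    ConnectivityError
        If any ROI column has zero variance; the error names the ROI.
    """
    variances = ts.data.var(axis=0)
    dead = np.flatnonzero(variances == 0)
    if dead.size:
        names = [ts.roi_labels[i] for i in dead]
        raise ConnectivityError(f"zero-variance ROI column(s): {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip(r, -(1.0 - FISHER_CLIP), 1.0 - FISHER_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        subject_id=ts.subject_id, z=z, roi_labels=list(ts.roi_labels)
    )


def preprocess_and_connect(
    ts: ROITimeSeries,
    confounds: np.ndarray | None = None,
    low_hz: float = DEFAULT_BANDPASS_LOW_HZ,
    high_hz: float = DEFAULT_BANDPASS_HIGH_HZ,
    order: str = "filter_then_regress",
) -> ConnectivityMatrix:
    """Full signal-level pipeline: band-pass, nuisance regression, Fisher-z.

    The default order filters first and regresses second; the reverse
    order is available via ``order='regress_then_filter'`` and is logged
    as a deviation from the module's default contract.
    """
    if order not in ("filter_then_regress", "regress_then_filter"):
        raise ConnectivityError(f"unknown pipeline order: {order!r}")
    if order == "regress_then_filter":
        logger.warning(
            "subject %s: pipeline order deviates from default "
            "(regress_then_filter)", ts.subject_id,
        )
        if confounds is not None:
            ts = regress_nuisance(ts, confounds)
        ts = bandpass_filter(ts, low_hz, high_hz)
    else:
        ts = bandpass_filter(ts, low_hz, high_hz)
        if confounds is not None:
            ts = regress_nuisance(ts, confounds)
    return compute_fc(ts)
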