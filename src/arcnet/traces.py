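"""Fluorescence trace processing and MAP spike inference.

Per-ROI traces are the mean of each ROI's pixels per frame.  Background
and photobleaching are removed by subtracting, at every time point, the
mean signal of the least-active tenth of the cells (silent cells carry
the shared background), after which traces are baseline-normalised to
dF/F.  Spike trains are inferred by a fast nonnegative MAP deconvolution
under an AR(1) calcium model with Gaussian noise and a sparse
(exponential) spike prior — the fast-oopsi posterior.  The objective

    1/2 ||y - K s||^2 + lam * sum(s),   s >= 0

(K the AR(1) impulse-response convolution) is minimised by accelerated
projected gradient (FISTA); per-frame spike mass above a relative
threshold becomes spike times at frame centres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .core import FluorescenceMatrix, SpikeTrain
from .errors import InvalidParameterError, PipelineStageError
from .segmentation import ROISet
from .synthetic import CalciumModelParams

logger = logging.getLogger(__name__)


def extract_traces(
    movie: np.ndarray, rois: ROISet, frame_rate_hz: float = 5.0, epoch: str = "baseline"
) -> FluorescenceMatrix:
    """Average each ROI's pixels per frame into a raw trace matrix."""
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise InvalidParameterError("movie must be (frames, height, width)")
    if movie.shape[1:] != rois.label_image.shape:
        raise InvalidParameterError("movie geometry does not match ROIs")
    ids = rois.roi_ids
    out = np.empty((len(ids), movie.shape[0]))
    for t in range(movie.shape[0]):
        out[:, t] = ndimage.mean(movie[t], labels=rois.label_image, index=ids)
    return FluorescenceMatrix(
        out, frame_rate_hz=frame_rate_hz, epoch=epoch, kind="raw", roi_ids=ids
    )


def correct_and_normalize(
    raw: FluorescenceMatrix, dff_mode: str = "dff", silent_fraction: float = 0.10
) -> FluorescenceMatrix:
    """Remove shared background/photobleach and normalise to dF/F.

    The background at each time point is the mean raw signal of the
    least-active tenth of the cells (activity ranked by temporal variance
    of the raw trace — silent cells track the common background and
    bleach).  With ``dff_mode='dff'`` (default) each background-subtracted
    trace is further normalised as (F - F0)/F0 with F0 the cell's 10th
    percentile; ``'subtract_only'`` stops at the subtraction.
    """
    if raw.n_cells < 10:
        raise InvalidParameterError("need at least 10 cells for the silent decile")
    if dff_mode not in ("dff", "subtract_only"):
        raise InvalidParameterError(f"unknown dff_mode {dff_mode!r}")
    F = raw.values
    k = max(1, int(np.floor(raw.n_cells * silent_fraction)))
    activity = F.var(axis=1)
    silent = np.argsort(activity, kind="stable")[:k]
    background = F[silent].mean(axis=0)
    sub = F - background[None, :]
    if dff_mode == "dff":
        f0 = np.percentile(sub, 10, axis=1)
        scale = np.abs(sub).max() if sub.size else 0.0
        # a near-zero baseline (silent cell) would blow up the ratio; fall
        # back to a unit divisor there so the trace stays a plain subtraction
        denom = np.where(f0 > max(1e-12, 1e-3 * scale), f0, 1.0)
        corrected = (sub - f0[:, None] * (denom == f0)[:, None]) / denom[:, None]
    else:
        corrected = sub
    return FluorescenceMatrix(
        corrected,
        frame_rate_hz=raw.frame_rate_hz,
        epoch=raw.epoch,
        kind="corrected",
        roi_ids=raw.roi_ids,
    )


def network_trace(fluo: FluorescenceMatrix) -> np.ndarray:
    """Total (summed) fluorescence change over time across all cells."""
    return fluo.values.sum(axis=0)


def detect_network_peaks(
    trace: np.ndarray,
    min_prominence: float | None = None,
    min_separation_frames: int = 5,
) -> np.ndarray:
    """Local maxima of a 1-D trace passing prominence and separation
    criteria.  Default prominence is twice the robust (MAD-based) SD."""
    y = np.asarray(trace, dtype=float).ravel()
    if min_prominence is None:
        mad = np.median(np.abs(y - np.median(y)))
        min_prominence = 2.0 * 1.4826 * mad
        if min_prominence == 0:
            min_prominence = 1e-12
    peaks, _ = find_peaks(
        y, prominence=min_prominence, distance=max(1, int(min_separation_frames))
    )
    return peaks


def _impulse_kernel_gram(gamma: float, T: int) -> tuple[np.ndarray, np.ndarray]:
    """Convolution matrix K (K[t, s] = gamma^(t-s), t >= s) and its Gram."""
    t = np.arange(T)
    K = np.where(t[:, None] >= t[None, :], gamma ** (t[:, None] - t[None, :]), 0.0)
    return K, K.T @ K


def deconvolve(
    trace: np.ndarray,
    params: CalciumModelParams = CalciumModelParams(),
    sparsity_weight: float = 2.0,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Nonnegative sparse spike-mass estimate for one corrected trace.

    Solves min_{s>=0} 1/2 ||y - K s||^2 + lam ||s||_1 by FISTA, with
    lam = sparsity_weight * sigma_hat * ||k||_2 (sigma_hat a robust noise
    estimate from first differences; lam = 0 on noiseless traces, making
    the solve an exact nonnegative least squares).
    """
    y = np.asarray(trace, dtype=float).ravel() / params.amplitude
    if not np.all(np.isfinite(y)):
        raise InvalidParameterError("trace must be finite")
    T = y.size
    if T < 2:
        raise InvalidParameterError("trace too short")
    y = y - np.percentile(y, 8)  # running-free baseline removal
    K, G = _impulse_kernel_gram(params.gamma, T)
    c = K.T @ y
    sigma = 1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2.0)
    col_norm = np.sqrt((1 - params.gamma ** (2 * T)) / (1 - params.gamma**2))
    lam = sparsity_weight * sigma * col_norm
    L = np.linalg.norm(G, 2)
    if L == 0:
        return np.zeros(T)
    s = np.zeros(T)
    z = s.copy()
    t_k = 1.0
    for it in range(max_iter):
        grad = G @ z - c + lam
        s_new = np.maximum(z - grad / L, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t_k**2)) / 2
        z = s_new + (t_k - 1) / t_new * (s_new - s)
        delta = np.max(np.abs(s_new - s)) if it else np.inf
        s, t_k = s_new, t_new
        if delta < tol * max(1.0, np.max(s)):
            break
    else:
        raise PipelineStageError(
            "deconvolve",
            f"FISTA did not converge in {max_iter} iterations "
            f"(last step {delta:.3e})",
        )
    return s


def infer_spikes(
    trace: np.ndarray,
    params: CalciumModelParams = CalciumModelParams(),
    sparsity_weight: float = 2.0,
    spike_threshold_frac: float = 0.1,
    duration_s: float | None = None,
) -> SpikeTrain:
    """MAP spike train for one corrected fluorescence trace.

    Per-frame spike mass above ``spike_threshold_frac`` of its maximum is
    discretised to spike times at frame centres.  An (effectively) silent
    trace yields an empty train.
    """
    y = np.asarray(trace, dtype=float).ravel()
    T = y.size
    dt = 1.0 / params.frame_rate_hz
    if duration_s is None:
        duration_s = T * dt
    s = deconvolve(y, params, sparsity_weight)
    peak = s.max()
    floor = 1e-6 * max(1.0, np.max(np.abs(y)) / params.amplitude)
    if peak <= floor:
        return SpikeTrain(np.array([]), duration_s)
    frames = np.where(s > spike_threshold_frac * peak)[0]
    times = np.minimum((frames + 0.5) * dt, duration_s)
    return SpikeTrain(times, duration_s)


def infer_spike_matrix(
    fluo: FluorescenceMatrix,
    params: CalciumModelParams | None = None,
    sparsity_weight: float = 2.0,
) -> list[SpikeTrain]:
    """Infer one spike train per cell of a corrected matrix."""
    if params is None:
        params = CalciumModelParams(frame_rate_hz=fluo.frame_rate_hz)
    dur = fluo.duration_s
    return [
        infer_spikes(row, params, sparsity_weight, duration_s=dur)
        for row in fluo.values
    ]


def firing_rate(train: SpikeTrain) -> float:
    """Spike count divided by total recording time (Hz)."""
    return train.rate_hz


def normalized_rate_change(baseline_rate_hz: float, epoch_rate_hz: float) -> float:
    """Per-neuron normalized change, (rate_epoch - rate_base) / rate_base.

    Undefined (raises) for a zero baseline; callers exclude such neurons.
    """
    if baseline_rate_hz <= 0:
        raise InvalidParameterError("baseline rate must be positive")
    return (epoch_rate_hz - baseline_rate_hz) / baseline_rate_hz


def network_rate_change(
    baseline: list[SpikeTrain], epoch: list[SpikeTrain]
) -> float:
    """Network average of per-neuron normalized rate changes; neurons
    silent at baseline are excluded (and logged)."""
    if len(baseline) != len(epoch):
        raise InvalidParameterError("epochs must share the neuron roster")
    changes = []
    skipped = 0
    for b, e in zip(baseline, epoch):
        if b.rate_hz <= 0:
            skipped += 1
            continue
        changes.append(normalized_rate_change(b.rate_hz, e.rate_hz))
    if skipped:
        logger.info("excluded %d neurons silent at baseline", skipped)
    return float(np.mean(changes)) if changes else np.nan
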