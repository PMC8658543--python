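"""Nuclear segmentation, marker quantification and positivity labeling.

ROIs are segmented from the nuclear (DAPI) channel; marker intensities
(NeuN, Arc, c-Fos) are quantified as the mean pixel value inside each
ROI.  Each channel's intensity distribution is modelled as a mixture of
two normal components (negative and positive populations) fitted by EM,
and a cell is called positive when its intensity exceeds the negative
component's mean plus three standard deviations — i.e. above the 99.7%
point of the negative population.  Only NeuN-positive ROIs enter any
neuron-level analysis; on those, the Arc/c-Fos combinatorial group is one
of Arc+cFos+, Arc+cFos-, Arc-cFos+, Arc-cFos-.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .errors import DegenerateInputError, InvalidParameterError

CHANNELS = ("neun", "arc", "cfos")


@dataclass
class ROISet:
    """Segmented nuclei as a label image plus a centroid table.

    ``label_image`` assigns each pixel its ROI id (0 = background);
    ``table`` has one row per ROI with 0-based (x=column, y=row) centroids.
    """

    label_image: np.ndarray
    table: pd.DataFrame  # roi_id, x_px, y_px, area_px

    def __len__(self) -> int:
        return len(self.table)

    @property
    def roi_ids(self) -> np.ndarray:
        return self.table["roi_id"].to_numpy()

    @property
    def centroids_xy(self) -> np.ndarray:
        return self.table[["x_px", "y_px"]].to_numpy()


@dataclass
class MixtureFit:
    """Two-component normal mixture, components ordered by mean."""

    mu_neg: float
    sigma_neg: float
    mu_pos: float
    sigma_pos: float
    weight_neg: float
    converged: bool
    log_likelihood: float
    ll_history: np.ndarray = field(default_factory=lambda: np.array([]))


def segment_nuclei(
    image: np.ndarray,
    min_area_px: int = 50,
    max_area_px: int = 5000,
    threshold_method: str = "otsu",
) -> ROISet:
    """Threshold the nuclear image and keep connected components passing
    the area filter.

    The default recipe is a global Otsu threshold followed by connected
    components; no watershed splitting of touching nuclei is attempted.
    A blank (constant) image yields an empty ROI set.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("expected a 2-D grayscale image")
    empty = ROISet(
        np.zeros(img.shape, dtype=np.int32),
        pd.DataFrame(columns=["roi_id", "x_px", "y_px", "area_px"]),
    )
    if np.ptp(img) == 0:
        return empty
    if threshold_method == "otsu":
        thr = threshold_otsu(img)
    elif threshold_method == "mean":
        thr = img.mean()
    else:
        raise InvalidParameterError(f"unknown threshold method {threshold_method!r}")
    mask = img > thr
    labeled = cc_label(mask)
    out = np.zeros(img.shape, dtype=np.int32)
    rows = []
    next_id = 1
    for prop in regionprops(labeled):
        if not (min_area_px <= prop.area <= max_area_px):
            continue
        out[labeled == prop.label] = next_id
        cy, cx = prop.centroid
        rows.append((next_id, cx, cy, int(prop.area)))
        next_id += 1
    if not rows:
        return empty
    return ROISet(out, pd.DataFrame(rows, columns=["roi_id", "x_px", "y_px", "area_px"]))


def quantify_roi_intensity(image: np.ndarray, rois: ROISet) -> pd.Series:
    """Mean pixel intensity of ``image`` inside each ROI mask."""
    img = np.asarray(image, dtype=float)
    if img.shape != rois.label_image.shape:
        raise InvalidParameterError("image does not cover the ROI masks")
    if len(rois) == 0:
        return pd.Series(dtype=float, name="intensity")
    ids = rois.roi_ids
    means = ndimage.mean(img, labels=rois.label_image, index=ids)
    return pd.Series(means, index=pd.Index(ids, name="roi_id"), name="intensity")


def quantify_channels(images: dict[str, np.ndarray], rois: ROISet) -> pd.DataFrame:
    """Intensity table: one row per ROI, one column per channel."""
    cols = {ch: quantify_roi_intensity(img, rois) for ch, img in images.items()}
    return pd.DataFrame(cols)


def fit_two_normal_mixture(
    values: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureFit:
    """Maximum-likelihood two-component 1-D normal mixture via EM.

    Initialised by splitting the data at the median; iterates until the
    log-likelihood improves by less than ``tol`` or ``max_iter`` sweeps.
    Components are returned ordered by mean.  If the two components
    collapse onto one mode the caller is warned.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise DegenerateInputError("need at least 10 values")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant input cannot be split")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    scale_floor = 1e-6 * np.std(x)
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.maximum(np.array([lo.std(), hi.std()]), scale_floor)
    w = np.array([lo.size, hi.size], dtype=float) / x.size

    ll_prev = -np.inf
    ll_history = []
    converged = False
    for _ in range(max_iter):
        # E step
        log_p = np.log(w)[:, None] + norm.logpdf(x[None, :], mu[:, None], sd[:, None])
        log_tot = np.logaddexp(log_p[0], log_p[1])
        ll = float(log_tot.sum())
        ll_history.append(ll)
        resp = np.exp(log_p - log_tot[None, :])
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
        # M step
        nk = resp.sum(axis=1)
        w = nk / x.size
        mu = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - mu**2
        sd = np.maximum(np.sqrt(np.maximum(var, 0.0)), scale_floor)

    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    if abs(mu[1] - mu[0]) < max(sd):
        warnings.warn(
            "mixture components collapsed (means within one SD); the data "
            "may not be bimodal"
        )
    return MixtureFit(
        mu_neg=float(mu[0]),
        sigma_neg=float(sd[0]),
        mu_pos=float(mu[1]),
        sigma_pos=float(sd[1]),
        weight_neg=float(w[0]),
        converged=converged,
        log_likelihood=float(ll_history[-1]),
        ll_history=np.array(ll_history),
    )


def positivity_threshold(fit: MixtureFit) -> float:
    """Positivity cut: the negative component's mean plus three SDs, i.e.
    the 99.7% point of the negative population."""
    return fit.mu_neg + 3.0 * fit.sigma_neg


def assign_labels(
    intensities: pd.DataFrame, thresholds: dict[str, float]
) -> pd.DataFrame:
    """Boolean positivity per channel (strict >) and the Arc/c-Fos
    combinatorial group for NeuN-positive ROIs.

    ROIs below the NeuN threshold are flagged non-neuronal (group NA) and
    must be excluded from every neuron-level analysis downstream.
    """
    for ch in CHANNELS:
        if ch in intensities.columns and ch not in thresholds:
            raise InvalidParameterError(f"missing threshold for channel {ch!r}")
    out = pd.DataFrame(index=intensities.index)
    for ch in CHANNELS:
        if ch in intensities.columns:
            out[f"{ch}_pos"] = intensities[ch] > thresholds[ch]
        else:
            raise InvalidParameterError(f"missing channel {ch!r}")
    group = np.where(
        out["arc_pos"],
        np.where(out["cfos_pos"], "Arc+cFos+", "Arc+cFos-"),
        np.where(out["cfos_pos"], "Arc-cFos+", "Arc-cFos-"),
    )
    out["group"] = pd.array(group, dtype="string")
    out.loc[~out["neun_pos"], "group"] = pd.NA
    return out


def label_culture_channels(
    intensities: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, float], dict[str, MixtureFit]]:
    """Fit the two-normal mixture per channel, derive thresholds, and
    assign labels in one pass (per-culture fitting)."""
    fits = {ch: fit_two_normal_mixture(intensities[ch].to_numpy()) for ch in CHANNELS}
    thresholds = {ch: positivity_threshold(f) for ch, f in fits.items()}
    return assign_labels(intensities, thresholds), thresholds, fits
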