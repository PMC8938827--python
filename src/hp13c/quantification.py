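"""Model-free metrics, ROI summaries and phantom QA.

Covers the quantities reported alongside k_PL: the lactate-to-pyruvate ratio
of time-summed (AUC) signals, the lactate Z-score (ROI lactate expressed in
whole-brain voxel SDs from the whole-brain mean — scale-invariant, hence
exempt from echo-time correction), time-summed SNR against a noise region
outside the head, and the phantom QA operations (SNR, double-angle B1+
flip-angle mapping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import DynamicSeries, KplMap

__all__ = [
    "ROIStats",
    "auc_map",
    "block_average",
    "lac_pyr_ratio",
    "lactate_zscore",
    "series_snr",
    "roi_summary",
    "double_angle_b1",
    "compute_exam_metrics",
]

METRIC_NAMES = ("k_pl", "lac_pyr_ratio", "lac_zscore", "snr_pyr", "snr_lac")


@dataclass
class ROIStats:
    """Mean / sample-SD / voxel count of a metric map over one ROI."""

    roi_label: str
    mean: float
    sd: float
    n_voxels: int


def auc_map(series: DynamicSeries, metabolite: str) -> np.ndarray:
    """Voxel-wise time-summed (area-under-curve) signal of one metabolite."""
    return series.get_channel(metabolite).sum(axis=-1)


def block_average(arr: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Average non-overlapping blocks, e.g. to bring a finer pyruvate grid
    onto the lactate grid. Block averaging preserves ROI means of the AUC."""
    fx, fy, fz = factors
    nx, ny, nz = arr.shape
    if nx % fx or ny % fy or nz % fz:
        raise ValueError(f"shape {arr.shape} not divisible by block factors {factors}")
    return arr.reshape(nx // fx, fx, ny // fy, fy, nz // fz, fz).mean(axis=(1, 3, 5))


def _pyr_auc_on_lactate_grid(series: DynamicSeries) -> np.ndarray:
    """Pyruvate AUC, block-averaged onto the lactate grid when the protocol
    acquired pyruvate at finer resolution (and the arrays reflect that)."""
    pyr = auc_map(series, "pyruvate")
    lac_shape = series.lactate.shape[:3]
    if pyr.shape == lac_shape:
        return pyr
    factors = tuple(int(round(p / l)) for p, l in zip(pyr.shape, lac_shape))
    if tuple(f * l for f, l in zip(factors, lac_shape)) != pyr.shape:
        raise ValueError(f"pyruvate grid {pyr.shape} is not an integer refinement of lactate grid {lac_shape}")
    return block_average(pyr, factors)


def lac_pyr_ratio(series: DynamicSeries, roi: np.ndarray) -> float:
    """ROI-mean lactate AUC over ROI-mean pyruvate AUC."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    lac = auc_map(series, "lactate")
    pyr = _pyr_auc_on_lactate_grid(series)
    denom = pyr[roi].mean()
    if abs(denom) < 1e-300:
        raise ZeroDivisionError("zero pyruvate AUC in ROI")
    return float(lac[roi].mean() / denom)


def lactate_zscore(series: DynamicSeries, roi: np.ndarray, brain_mask: np.ndarray) -> float:
    """ROI lactate AUC in whole-brain voxel SDs from the whole-brain mean.

    The denominator is the population SD over brain voxels, so the score is
    invariant to any global rescaling of the lactate channel.
    """
    roi = np.asarray(roi, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.sum() < 2:
        raise ValueError("brain mask must contain at least 2 voxels")
    lac = auc_map(series, "lactate")
    brain_vals = lac[brain_mask]
    sd = brain_vals.std(ddof=0)
    if sd == 0:
        raise ZeroDivisionError("zero whole-brain lactate SD: Z-score undefined")
    return float((lac[roi].mean() - brain_vals.mean()) / sd)


def series_snr(map3d: np.ndarray, signal_mask: np.ndarray, noise_region: np.ndarray) -> float:
    """Mean signal over ``signal_mask`` divided by noise-region SD."""
    signal_mask = np.asarray(signal_mask, dtype=bool)
    noise_region = np.asarray(noise_region, dtype=bool)
    if np.any(signal_mask & noise_region):
        raise ValueError("signal mask and noise region overlap")
    if noise_region.sum() < 2:
        raise ValueError("noise region must contain at least 2 voxels")
    sd = map3d[noise_region].std(ddof=0)
    if sd == 0:
        raise ZeroDivisionError("zero noise SD")
    return float(map3d[signal_mask].mean() / sd)


def roi_summary(map3d: np.ndarray, roi: np.ndarray, roi_label: str = "") -> ROIStats:
    """Mean, sample SD and voxel count over the defined (non-NaN) ROI voxels.

    A single-voxel ROI reports SD = 0 by convention.
    """
    roi = np.asarray(roi, dtype=bool)
    vals = np.asarray(map3d, dtype=float)[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined voxels in ROI")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return ROIStats(roi_label=roi_label, mean=float(vals.mean()), sd=sd, n_voxels=int(vals.size))


def double_angle_b1(
    img_low: np.ndarray, img_high: np.ndarray, nominal_low_deg: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Double-angle B1+ map: theta = arccos(S_2t / (2 S_t)) per voxel.

    ``img_low``/``img_high`` are acquired at nominal flips theta and 2*theta
    (signal ~ sin).  Returns (flip-angle map in degrees, validity mask);
    voxels where the arccos argument leaves [-1, 1] or the low image is zero
    are flagged invalid (NaN).
    """
    img_low = np.asarray(img_low, dtype=float)
    img_high = np.asarray(img_high, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = img_high / (2.0 * img_low)
    valid = np.isfinite(ratio) & (np.abs(ratio) <= 1.0) & (img_low != 0)
    theta = np.full(img_low.shape, np.nan)
    theta[valid] = np.degrees(np.arccos(ratio[valid]))
    return theta, valid


def compute_exam_metrics(
    series: DynamicSeries,
    phantom,
    kpl_map: KplMap | None = None,
    rois: tuple[str, ...] = ("whole_brain", "cortex", "deep_white_matter"),
    corrected: bool = False,
    zscore_series: DynamicSeries | None = None,
) -> pd.DataFrame:
    """Tidy per-exam metric table: one row per (metric, ROI).

    ``zscore_series`` lets the caller pass the *uncorrected* series for the
    Z-score pathway (the echo-time correction is a global scaling, so by
    construction the score is unchanged; keeping the pathway explicit
    documents the convention).  SNR rows use the whole-brain mask only.
    """
    if zscore_series is None:
        zscore_series = series
    brain = phantom.brain_mask
    noise = phantom.noise_mask
    base = {
        "exam_id": series.exam_id,
        "subject_id": series.subject_id,
        "site_id": series.site_id,
        "protocol_id": series.protocol.protocol_id,
        "corrected": corrected,
    }
    rows = []
    for roi in rois:
        mask = phantom.roi_mask(roi)
        rows.append(base | {"metric_name": "lac_pyr_ratio", "roi_label": roi, "value": lac_pyr_ratio(series, mask)})
        rows.append(
            base
            | {"metric_name": "lac_zscore", "roi_label": roi, "value": lactate_zscore(zscore_series, mask, brain)}
        )
        if kpl_map is not None:
            stats = roi_summary(kpl_map.values, mask & kpl_map.fit_mask, roi)
            rows.append(base | {"metric_name": "k_pl", "roi_label": roi, "value": stats.mean})
            rows.append(base | {"metric_name": "k_pl_sd", "roi_label": roi, "value": stats.sd})
            rows.append(base | {"metric_name": "k_pl_nvox", "roi_label": roi, "value": stats.n_voxels})
    for metric, metab in (("snr_pyr", "pyruvate"), ("snr_lac", "lactate")):
        try:
            snr = series_snr(auc_map(series, metab), brain, noise)
        except ZeroDivisionError:
            snr = np.inf  # noise-free simulation
        rows.append(base | {"metric_name": metric, "roi_label": "whole_brain", "value": snr})
    return pd.DataFrame(rows)
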