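"""Quantitative evaluation of reconstructions: DICE, CNR, line profiles.

DICE compares the half-maximum region of a (max-normalized) reconstruction
with the true target region; CNR contrasts target and background intensities
with volume-proportional variance weights.  Both follow the conventions
standard in XLCT evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import ValidationError

logger = logging.getLogger(__name__)


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Scale so the maximum is 1; an all-zero volume is returned unchanged
    (with a warning).  Idempotent and order-preserving."""
    v = np.asarray(volume, dtype=float)
    m = v.max()
    if m <= 0:
        logger.warning("normalize_volume: maximum is %g; returning input unchanged", m)
        return v.copy()
    return v / m


def dice(recon_volume: np.ndarray, truth_mask: np.ndarray,
         threshold_frac: float = 0.5) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|) between the reconstruction's
    relative-threshold region and the true target mask.

    ``threshold_frac`` is relative to the reconstruction maximum (half-max by
    default), which makes the metric invariant to intensity rescaling.  If
    both regions are empty the volumes agree trivially and 1 is returned.
    """
    recon_volume = np.asarray(recon_volume, dtype=float)
    truth_mask = np.asarray(truth_mask).astype(bool)
    if recon_volume.shape != truth_mask.shape:
        raise ValidationError(
            f"shape mismatch {recon_volume.shape} vs {truth_mask.shape}")
    if not (0 < threshold_frac < 1):
        raise ValidationError("threshold_frac must lie in (0, 1)")
    norm = normalize_volume(recon_volume)
    roi_r = norm >= threshold_frac
    denom = roi_r.sum() + truth_mask.sum()
    if denom == 0:
        logger.info("dice: both regions empty, returning 1")
        return 1.0
    return float(2.0 * np.logical_and(roi_r, truth_mask).sum() / denom)


def cnr(volume: np.ndarray, roi_mask: np.ndarray, bck_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio |mu_ROI - mu_BCK| / sqrt(w_ROI s2_ROI + w_BCK s2_BCK)
    with volume-proportional weights w_ROI + w_BCK = 1."""
    volume = np.asarray(volume, dtype=float)
    roi_mask = np.asarray(roi_mask).astype(bool)
    bck_mask = np.asarray(bck_mask).astype(bool)
    if np.logical_and(roi_mask, bck_mask).any():
        raise ValidationError("ROI and background masks overlap")
    if not roi_mask.any() or not bck_mask.any():
        raise ValidationError("ROI and background masks must be non-empty")
    roi = volume[roi_mask]
    bck = volume[bck_mask]
    w_roi = roi.size / (roi.size + bck.size)
    pooled = w_roi * roi.var() + (1.0 - w_roi) * bck.var()
    contrast = abs(roi.mean() - bck.mean())
    if pooled == 0:
        if contrast == 0:
            return 0.0
        logger.warning("cnr: zero variance with nonzero contrast -> inf")
        return float("inf")
    return float(contrast / np.sqrt(pooled))


@dataclass
class ProfileLine:
    """Sampled intensity profile along a voxel-space segment."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    samples: np.ndarray


def intensity_profile(volume: np.ndarray, start, end, n_samples: int = 100) -> ProfileLine:
    """Trilinear samples of the max-normalized volume along a segment.

    ``start``/``end`` are voxel-space (z, y, x) coordinates and must lie
    inside the volume.
    """
    volume = normalize_volume(np.asarray(volume, dtype=float))
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    for p in (start, end):
        if np.any(p < 0) or np.any(p > np.array(volume.shape) - 1):
            raise ValidationError(f"profile endpoint {p} outside the volume")
    if n_samples < 2:
        raise ValidationError("need at least 2 samples")
    ts = np.linspace(0.0, 1.0, n_samples)
    coords = start[:, None] * (1 - ts) + end[:, None] * ts
    samples = ndimage.map_coordinates(volume, coords, order=1, mode="nearest")
    return ProfileLine(tuple(start), tuple(end), samples)


def count_components(volume: np.ndarray, threshold_frac: float = 0.5) -> int:
    """Number of 3D-connected components of the relative-threshold region."""
    mask = normalize_volume(volume) >= threshold_frac
    _, n = ndimage.label(mask)
    return int(n)


@dataclass
class MetricReport:
    """Per-case evaluation record; serializable via dataclasses.asdict."""

    method: str
    case_id: str
    dice: float
    cnr: float
    eed_mm: float | None = None
    snr_db: float | None = None
    threshold_frac: float = 0.5
    extra: dict = field(default_factory=dict)


def evaluate_volume(recon: np.ndarray, truth: np.ndarray,
                    interior_mask: np.ndarray | None = None,
                    threshold_frac: float = 0.5,
                    method: str = "", case_id: str = "",
                    eed_mm: float | None = None,
                    snr_db: float | None = None) -> MetricReport:
    """DICE + CNR of a reconstruction against the true concentration volume.

    The CNR background is every (phantom-interior) voxel outside the true
    target region.
    """
    truth_mask = np.asarray(truth) > 0
    bck = ~truth_mask if interior_mask is None else interior_mask & ~truth_mask
    return MetricReport(
        method=method, case_id=case_id,
        dice=dice(recon, truth_mask, threshold_frac),
        cnr=cnr(normalize_volume(recon), truth_mask, bck),
        eed_mm=eed_mm, snr_db=snr_db, threshold_frac=threshold_frac)
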