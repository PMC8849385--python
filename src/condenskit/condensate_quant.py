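"""Segmentation and intensity scores for condensates and cells.

Implements the field's standard partitioning readouts:

* **enrichment score** ``E = (mean_in − mean_out) / mean_out`` per
  condensate, where ``mean_out`` is the mean over all non-condensate pixels
  of the field of view;
* **localized-to-diffuse ratio**
  ``R = (mean_cluster − mean_noncluster) / mean_cell`` per cell, with
  clusters thresholded inside each phase-contrast-segmented cell;
* cross-channel quantification (clusters defined on one channel, intensities
  measured on another);
* sub-cluster (demixing) counts inside condensates via smoothed local-maxima
  spot detection with a height and a minimum-separation criterion;
* a fold-over-reference membrane-leakage classifier.

Both E and R are invariant under global multiplicative intensity scaling but
shift under additive offsets, which is why image background subtraction is
mandatory upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk

from .io_formats import ImageStack
from .population_stats import binomial_interval

__all__ = [
    "LabelMask",
    "DemixingResult",
    "segment_intensity",
    "segment_cells_phase",
    "enrichment_scores",
    "cluster_to_diffuse_ratio",
    "cross_channel_quant",
    "count_subclusters",
    "leakage_fraction",
]

logger = logging.getLogger(__name__)

_STRUCT_4CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class LabelMask:
    """Integer label image (0 = background) with provenance parameters."""

    labels: np.ndarray
    pixel_size_um: float
    provenance: dict

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


@dataclass
class DemixingResult:
    counts: pd.DataFrame  # label, k
    fraction_multi: float
    ci_low: float
    ci_high: float
    n: int


def _as_frame(image: np.ndarray | ImageStack, channel: int = 0) -> tuple[np.ndarray, float | None]:
    if isinstance(image, ImageStack):
        if image.n_frames != 1:
            raise ValueError("expected a single-frame image")
        return image.frame(0, channel).astype(float), image.pixel_size
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a single-channel 2D frame")
    return arr, None


def segment_intensity(
    image: np.ndarray | ImageStack,
    method: str = "otsu",
    level: float | None = None,
    min_area_um2: float = 0.0,
    smoothing_sd_px: float = 1.0,
    pixel_size_um: float | None = None,
) -> LabelMask:
    """Gaussian smoothing → threshold → 4-connected components → area filter.

    ``method`` is ``"otsu"`` or ``"fixed"`` (which requires ``level``).  An
    image with no foreground yields an empty mask (logged, not an error).
    """
    frame, px = _as_frame(image)
    px = pixel_size_um if pixel_size_um is not None else px
    if px is None:
        raise ValueError("pixel_size_um required when passing a bare array")
    smoothed = (
        gaussian(frame, sigma=smoothing_sd_px, preserve_range=True)
        if smoothing_sd_px > 0
        else frame
    )
    if method == "otsu":
        if np.ptp(smoothed) == 0:
            thr = np.inf  # uniform image: no foreground
        else:
            thr = threshold_otsu(smoothed)
    elif method == "fixed":
        if level is None:
            raise ValueError("fixed thresholding requires a level")
        thr = level
    else:
        raise ValueError(f"unknown method {method!r}; use 'otsu' or 'fixed'")
    fg = smoothed > thr
    labels, n = ndimage.label(fg, structure=_STRUCT_4CONN)
    if min_area_um2 > 0 and n:
        min_px = min_area_um2 / px**2
        sizes = np.bincount(labels.ravel())
        keep = np.nonzero(sizes >= min_px)[0]
        keep = keep[keep > 0]
        relabel = np.zeros(n + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, keep.size + 1)
        labels = relabel[labels]
    if labels.max() == 0:
        logger.info("segment_intensity found no foreground objects")
    return LabelMask(
        labels=labels.astype(np.int32),
        pixel_size_um=px,
        provenance={
            "method": method,
            "threshold": float(thr) if np.isfinite(thr) else None,
            "min_area_um2": min_area_um2,
            "smoothing_sd_px": smoothing_sd_px,
        },
    )


def segment_cells_phase(
    phase_image: np.ndarray | ImageStack,
    min_area_um2: float = 0.5,
    smoothing_sd_px: float = 1.0,
    min_solidity: float = 0.8,
    pixel_size_um: float | None = None,
) -> LabelMask:
    """Segment dark cells from a phase-contrast-like image.

    Inverted-intensity Otsu threshold, 4-connected components, area filter.
    Components with solidity below ``min_solidity`` (typically merged
    touching cells) are kept but recorded in the provenance flag list.
    """
    frame, px = _as_frame(phase_image)
    px = pixel_size_um if pixel_size_um is not None else px
    if px is None:
        raise ValueError("pixel_size_um required when passing a bare array")
    inverted = frame.max() - frame
    mask = segment_intensity(
        inverted,
        method="otsu",
        min_area_um2=min_area_um2,
        smoothing_sd_px=smoothing_sd_px,
        pixel_size_um=px,
    )
    low_solidity = [
        int(p.label)
        for p in regionprops(mask.labels)
        if p.solidity < min_solidity
    ]
    mask.provenance.update(
        {"segmenter": "phase_inverted_otsu", "low_solidity_labels": low_solidity}
    )
    return mask


def enrichment_scores(
    image: np.ndarray | ImageStack, mask: LabelMask
) -> pd.DataFrame:
    """Per-condensate enrichment ``E = (mean_in − mean_out) / mean_out``.

    ``mean_out`` is the mean over *all* unlabeled pixels of the field of
    view.  Columns: label, area_um2, mean_in, mean_out, enrichment.
    """
    frame, _ = _as_frame(image)
    labels = mask.labels
    if labels.shape != frame.shape:
        raise ValueError("mask not aligned to image")
    bg = labels == 0
    if not bg.any():
        raise ValueError("mask leaves no background pixels")
    mean_out = float(frame[bg].mean())
    if mean_out <= 0:
        raise ValueError(
            "mean outside-condensate intensity <= 0; subtract the camera "
            "offset (not the full background) before scoring enrichment"
        )
    ids = np.arange(1, labels.max() + 1)
    if ids.size == 0:
        return pd.DataFrame(
            columns=["label", "area_um2", "mean_in", "mean_out", "enrichment"]
        )
    means = ndimage.mean(frame, labels=labels, index=ids)
    areas = ndimage.sum(np.ones_like(frame), labels=labels, index=ids)
    return pd.DataFrame(
        {
            "label": ids,
            "area_um2": areas * mask.pixel_area_um2,
            "mean_in": means,
            "mean_out": mean_out,
            "enrichment": (means - mean_out) / mean_out,
        }
    )


def cluster_to_diffuse_ratio(
    fluor_image: np.ndarray | ImageStack,
    cell_mask: LabelMask,
    cluster_method: str = "otsu",
    cluster_level: float | None = None,
    smoothing_sd_px: float = 1.0,
) -> pd.DataFrame:
    """Per-cell localized-to-diffuse ratio R.

    Within each cell, cluster pixels are thresholded (Otsu on the smoothed
    in-cell intensities, or a fixed level) and
    ``R = (mean_cluster − mean_noncluster) / mean_cell``.  Cells where no
    cluster passes the threshold (or the cluster fills the cell) get
    ``R = 0`` with ``has_cluster = False``.
    """
    frame, _ = _as_frame(fluor_image)
    return _ratio_table(
        frame, frame, cell_mask, cluster_method, cluster_level, smoothing_sd_px
    )


def cross_channel_quant(
    mask_channel_image: np.ndarray | ImageStack,
    target_channel_image: np.ndarray | ImageStack,
    cell_mask: LabelMask,
    cluster_method: str = "otsu",
    cluster_level: float | None = None,
    smoothing_sd_px: float = 1.0,
) -> pd.DataFrame:
    """Localized-to-diffuse ratio with clusters defined on one channel and
    intensities measured on another (two aligned channels)."""
    m_frame, _ = _as_frame(mask_channel_image)
    t_frame, _ = _as_frame(target_channel_image)
    if m_frame.shape != t_frame.shape:
        raise ValueError("channel shapes do not match")
    return _ratio_table(
        m_frame, t_frame, cell_mask, cluster_method, cluster_level, smoothing_sd_px
    )


def _ratio_table(
    mask_frame: np.ndarray,
    target_frame: np.ndarray,
    cell_mask: LabelMask,
    method: str,
    level: float | None,
    smoothing_sd_px: float,
) -> pd.DataFrame:
    labels = cell_mask.labels
    if labels.shape != mask_frame.shape:
        raise ValueError("cell mask not aligned to image")
    smoothed = (
        gaussian(mask_frame, sigma=smoothing_sd_px, preserve_range=True)
        if smoothing_sd_px > 0
        else mask_frame
    )
    records = []
    for cid in range(1, labels.max() + 1):
        cell = labels == cid
        if not cell.any():
            continue
        vals = smoothed[cell]
        if method == "fixed":
            if level is None:
                raise ValueError("fixed thresholding requires a level")
            thr = level
        else:
            thr = threshold_otsu(vals) if np.ptp(vals) > 0 else np.inf
        cluster = cell & (smoothed > thr)
        noncluster = cell & ~cluster
        mean_cell = float(target_frame[cell].mean())
        n_clusters = int(ndimage.label(cluster, structure=_STRUCT_4CONN)[1])
        if cluster.any() and noncluster.any() and mean_cell != 0:
            mean_cluster = float(target_frame[cluster].mean())
            mean_noncluster = float(target_frame[noncluster].mean())
            ratio = (mean_cluster - mean_noncluster) / mean_cell
            has_cluster = True
        else:
            mean_cluster = float("nan")
            mean_noncluster = float("nan")
            ratio = 0.0
            has_cluster = False
            n_clusters = 0
        records.append(
            {
                "cell_id": cid,
                "mean_cell": mean_cell,
                "mean_cluster": mean_cluster,
                "mean_noncluster": mean_noncluster,
                "ratio": ratio,
                "n_clusters": n_clusters,
                "has_cluster": has_cluster,
            }
        )
    return pd.DataFrame(records)


def count_subclusters(
    target_channel: np.ndarray | ImageStack,
    condensate_mask: LabelMask,
    smoothing_sd_px: float = 1.0,
    prominence_fraction: float = 0.3,
    min_separation_um: float = 0.4,
    min_size_um: float = 0.0,
) -> DemixingResult:
    """Count client sub-clusters inside each condensate (demixing readout).

    Within each condensate, spots are local maxima of the smoothed target
    channel whose height exceeds ``min + prominence_fraction × (max − min)``
    of the in-condensate dynamic range, with pairwise separation at least
    ``min_separation_um``.  ``min_size_um`` (area-equivalent diameter)
    restricts counting to sufficiently large condensates.  The summary is
    the fraction of counted condensates with more than one sub-cluster,
    with a 95% binomial interval.
    """
    frame, _ = _as_frame(target_channel)
    labels = condensate_mask.labels
    if labels.shape != frame.shape:
        raise ValueError("condensate mask not aligned to image")
    if labels.max() == 0:
        raise ValueError("condensate mask is empty")
    px = condensate_mask.pixel_size_um
    smoothed = (
        gaussian(frame, sigma=smoothing_sd_px, preserve_range=True)
        if smoothing_sd_px > 0
        else frame
    )
    min_dist_px = max(1, int(round(min_separation_um / px)))
    records = []
    for cid in range(1, labels.max() + 1):
        region = labels == cid
        if not region.any():
            continue
        if min_size_um > 0:
            diam_eq = 2.0 * np.sqrt(region.sum() * px**2 / np.pi)
            if diam_eq < min_size_um:
                continue
        vals = smoothed[region]
        lo, hi = float(vals.min()), float(vals.max())
        thr = lo + prominence_fraction * (hi - lo)
        masked = np.where(region, smoothed, -np.inf)
        # disk footprint so that spot suppression is Euclidean, not Chebyshev
        peaks = peak_local_max(
            masked,
            min_distance=min_dist_px,
            footprint=disk(min_dist_px),
            threshold_abs=thr if hi > lo else np.inf,
            exclude_border=False,
        )
        records.append({"label": cid, "k": int(len(peaks))})
    counts = pd.DataFrame(records, columns=["label", "k"])
    n = len(counts)
    if n == 0:
        return DemixingResult(counts, 0.0, 0.0, 0.0, 0)
    n_multi = int((counts["k"] > 1).sum())
    lo_ci, hi_ci = binomial_interval(n_multi, n)
    return DemixingResult(counts, n_multi / n, lo_ci, hi_ci, n)


def leakage_fraction(
    per_cell_intensity,
    reference_population,
    fold_threshold: float = 5.0,
) -> tuple[float, tuple[float, float]]:
    """Percentage of cells brighter than ``fold_threshold`` × the reference
    median (membrane-leakage classification), with a 95% binomial interval
    (also in percent)."""
    cells = np.asarray(per_cell_intensity, dtype=float)
    ref = np.asarray(reference_population, dtype=float)
    if cells.size == 0 or ref.size == 0:
        raise ValueError("populations must be nonempty")
    threshold = fold_threshold * float(np.median(ref))
    n_leaky = int(np.sum(cells > threshold))
    lo, hi = binomial_interval(n_leaky, cells.size)
    return 100.0 * n_leaky / cells.size, (100.0 * lo, 100.0 * hi)
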