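"""Chromosome-enrichment statistic from two-channel fluorescence images.

The statistic is E = log2(mean TF intensity on chromosomes / mean TF
intensity over the whole cell), with the chromosome mask derived by
thresholding the chromatin-marker (H2B) channel and the whole-cell mean
*including* the chromosome pixels.  Positive E means enrichment on mitotic
chromosomes, negative E apparent exclusion.  A time-lapse variant tracks the
normalized chromosome intensity through fixative-addition movies and reports
its value at a query time (default 60 s) after addition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu


@dataclass
class ImagePair:
    """Two-channel image: chromatin marker (H2B) and transcription factor."""

    h2b: np.ndarray
    tf: np.ndarray
    pixel_size_um: float = 0.16
    frame_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.h2b.shape != self.tf.shape or self.h2b.ndim != 2:
            raise ValueError("channels must be 2D arrays of identical shape")
        if (self.h2b < 0).any() or (self.tf < 0).any():
            raise ValueError("intensities must be >= 0")


def write_image_pair(pair: ImagePair, path) -> None:
    """Write a 2-page 16-bit TIFF, channel order (H2B, TF)."""
    stack = np.stack([pair.h2b, pair.tf]).astype(np.float64)
    stack = np.clip(stack, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, stack)


def read_image_pair(path, pixel_size_um: float = 0.16,
                    frame_time_s: float | None = None) -> ImagePair:
    stack = tifffile.imread(path).astype(float)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-channel multi-page TIFF")
    return ImagePair(h2b=stack[0], tf=stack[1], pixel_size_um=pixel_size_um,
                     frame_time_s=frame_time_s)


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, (mask.astype(np.uint8) * 255))


def cell_mask(pair: ImagePair) -> np.ndarray:
    """Whole-cell mask from the summed channels.

    The scene has three intensity classes (background, cytoplasm,
    chromosomes); a 3-class multi-Otsu threshold is taken at its *lowest*
    level to separate cell from background — a plain 2-class Otsu would split
    the bright chromosomes from everything else instead.  Holes are filled
    and the largest connected component kept.  A manual ROI may be supplied
    downstream instead of this mask.
    """
    summed = pair.h2b + pair.tf
    try:
        thr = threshold_multiotsu(summed, classes=3)[0]
    except ValueError as e:
        raise ValueError(f"cannot segment cell: {e}") from None
    mask = summed > thr
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no cell found")
    sizes = ndimage.sum(mask, labels, range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def chromosome_mask(h2b: np.ndarray, cell: np.ndarray,
                    min_size: int = 20) -> np.ndarray:
    """Chromosome mask by Otsu thresholding the H2B channel within the cell.

    Holes are filled and connected components smaller than ``min_size``
    pixels removed.  A cell whose H2B signal is not bimodal (the above- and
    below-threshold means differ by < 50%) has no usable chromosome signal
    and is rejected.
    """
    if not cell.any():
        raise ValueError("empty cell mask")
    vals = h2b[cell]
    if np.ptp(vals) == 0:
        raise ValueError("no chromosome signal: uniform H2B within the cell")
    thr = threshold_otsu(vals)
    hi, lo = vals[vals > thr], vals[vals <= thr]
    if len(hi) == 0 or len(lo) == 0 or hi.mean() < 1.5 * max(lo.mean(), 1e-12):
        raise ValueError("no chromosome signal: H2B not bimodal within the cell")
    mask = (h2b > thr) & cell
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum(mask, labels, range(1, n + 1))
        keep = np.flatnonzero(sizes >= min_size) + 1
        mask = np.isin(labels, keep)
    if not mask.any():
        raise ValueError("chromosome mask empty after cleanup")
    return mask


def estimate_background(pair: ImagePair, cell: np.ndarray) -> float:
    """Median TF intensity outside the cell mask (camera background)."""
    outside = ~cell
    if not outside.any():
        return 0.0
    return float(np.median(pair.tf[outside]))


def log2_enrichment(tf: np.ndarray, chrom_mask: np.ndarray,
                    cell_mask_: np.ndarray, background: float = 0.0) -> float:
    """E = log2[(mean TF on chromosomes - bg) / (mean TF over cell - bg)].

    The whole-cell mean includes the chromosome pixels.
    """
    if not chrom_mask.any() or not cell_mask_.any():
        raise ValueError("masks must be non-empty")
    if (chrom_mask & ~cell_mask_).any():
        raise ValueError("chromosome mask must lie within the cell mask")
    mean_chrom = float(tf[chrom_mask].mean()) - background
    mean_cell = float(tf[cell_mask_].mean()) - background
    if mean_chrom <= 0 or mean_cell <= 0:
        raise ValueError("background-subtracted means must be positive")
    return float(np.log2(mean_chrom / mean_cell))


def estimate_enrichment(pair: ImagePair, roi: np.ndarray | None = None,
                        background: float | None = None) -> dict:
    """Fully automatic enrichment estimate for one image pair.

    Returns a dict with ``log2_enrichment``, ``norm_chrom_intensity`` (the
    linear ratio), and mask areas.  ``roi`` overrides the automatic cell
    mask; ``background`` overrides the outside-cell median.
    """
    cell = roi if roi is not None else cell_mask(pair)
    chrom = chromosome_mask(pair.h2b, cell)
    bg = estimate_background(pair, cell) if background is None else background
    e = log2_enrichment(pair.tf, chrom, cell, bg)
    return {
        "log2_enrichment": e,
        "norm_chrom_intensity": float(2.0**e),
        "mask_area_px": int(chrom.sum()),
        "cell_area_px": int(cell.sum()),
        "background": float(bg),
    }


@dataclass
class EnrichmentTrace:
    """Per-frame enrichment through a fixative-addition time lapse."""

    frames: pd.DataFrame  # time_s, norm_chrom_intensity, log2_enrichment
    addition_time_s: float
    value_at_query: float
    query_time_s: float

    def __post_init__(self) -> None:
        t = self.frames["time_s"].to_numpy()
        if (np.diff(t) <= 0).any():
            raise ValueError("frame times must be increasing")
        if not np.isfinite(self.frames.to_numpy(float)).all():
            raise ValueError("non-finite trace values")


def timelapse_enrichment(
    stack: list[ImagePair],
    addition_time_s: float,
    query_time_s: float = 60.0,
    max_mask_failures: float = 0.1,
) -> EnrichmentTrace:
    """Per-frame normalized chromosome intensity through a PFA-addition movie.

    Each frame is re-masked from its own H2B channel (chromosomes move; no
    registration).  The reported value is the normalized chromosome intensity
    (mean TF in mask / mean TF in cell) linearly interpolated at
    ``addition_time_s + query_time_s``.  Masking failures on more than
    ``max_mask_failures`` of frames, or a query outside the covered range,
    reject the movie.
    """
    if query_time_s < 0:
        raise ValueError("query time must be at or after the addition time")
    times, ratios, logs = [], [], []
    failures = 0
    for i, pair in enumerate(stack):
        t = pair.frame_time_s if pair.frame_time_s is not None else float(i)
        try:
            res = estimate_enrichment(pair)
        except ValueError:
            failures += 1
            continue
        times.append(t)
        ratios.append(res["norm_chrom_intensity"])
        logs.append(res["log2_enrichment"])
    if failures > max_mask_failures * len(stack):
        raise ValueError(
            f"chromosome masking failed on {failures}/{len(stack)} frames"
        )
    df = pd.DataFrame({
        "time_s": times,
        "norm_chrom_intensity": ratios,
        "log2_enrichment": logs,
    })
    t_query = addition_time_s + query_time_s
    t = df["time_s"].to_numpy()
    if t_query < t[0] or t_query > t[-1]:
        raise ValueError("stack does not cover addition_time + query_time")
    val = float(np.interp(t_query, t, df["norm_chrom_intensity"].to_numpy()))
    return EnrichmentTrace(frames=df, addition_time_s=addition_time_s,
                           value_at_query=val, query_time_s=query_time_s)


__all__ = [
    "ImagePair", "EnrichmentTrace", "write_image_pair", "read_image_pair",
    "write_mask", "cell_mask", "chromosome_mask", "estimate_background",
    "log2_enrichment", "estimate_enrichment", "timelapse_enrichment",
]
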