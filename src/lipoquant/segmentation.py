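"""Condition-level intensity thresholding of the liposome channel.

Liposome pixels are identified with a single threshold per experimental
condition: two standard deviations above the mean pixel intensity of the
lipid channel, pooled over every pixel of every image in the condition.
The standard deviation is the population SD (denominator N); at image scale
the difference from the sample SD is negligible, but fixing it makes the
rule exactly reproducible.  A pixel is liposome iff its lipid intensity is
strictly greater than the threshold (ties go to background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import ConditionSet, TwoChannelImage

N_SIGMA = 2.0


@dataclass(frozen=True)
class ConditionThreshold:
    """Pooled lipid-channel statistics and the resulting threshold."""

    value: float
    mean: float
    sd: float
    n_pixels: int
    condition_id: str


@dataclass
class LiposomeMask:
    """Binary liposome/background partition of one image."""

    mask: np.ndarray
    coverage: float
    image_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        expected = float(self.mask.mean()) if self.mask.size else 0.0
        if not np.isclose(self.coverage, expected):
            raise ValueError("coverage inconsistent with mask")


def condition_threshold(
    cond: ConditionSet,
    exclude_saturated: bool = False,
    exclude_border: int = 0,
) -> ConditionThreshold:
    """Pooled mean + 2 SD threshold for one condition.

    Parameters
    ----------
    exclude_saturated : bool
        Drop pixels at the bit-depth maximum from the pooled population.
        Off by default (nothing is excluded by default).
    exclude_border : int
        Drop a border of that many pixels from every image before pooling.
        Off by default.

    A zero-variance condition is legal (threshold equals the mean); an
    empty pixel population is an error.
    """
    chunks = []
    top = 2**cond.bit_depth - 1
    for img in cond.images:
        arr = np.asarray(img.lipid, dtype=np.float64)
        if exclude_border:
            b = exclude_border
            arr = arr[b:-b or None, b:-b or None]
        arr = arr.ravel()
        if exclude_saturated:
            arr = arr[arr < top]
        chunks.append(arr)
    pooled = np.concatenate(chunks) if chunks else np.empty(0)
    if pooled.size == 0:
        raise ValueError(f"condition {cond.condition_id!r}: no pixels to pool")
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=0))
    return ConditionThreshold(
        value=mean + N_SIGMA * sd,
        mean=mean,
        sd=sd,
        n_pixels=int(pooled.size),
        condition_id=cond.condition_id,
    )


def binarize(
    img: TwoChannelImage,
    thr: ConditionThreshold,
    min_object_size: int | None = None,
) -> LiposomeMask:
    """Threshold one image's lipid channel into a liposome mask.

    The threshold must come from the image's own condition.  No
    morphological post-processing is applied by default; an optional
    minimum connected-component size (8-connectivity) is available.
    """
    if img.condition_id != thr.condition_id:
        raise ValueError(
            f"threshold from condition {thr.condition_id!r} applied to image "
            f"of condition {img.condition_id!r}"
        )
    mask = np.asarray(img.lipid, dtype=np.float64) > thr.value
    if min_object_size:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= min_object_size
            keep[0] = False
            mask = keep[labels]
    return LiposomeMask(mask=mask, coverage=float(mask.mean()), image_id=img.image_id)
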