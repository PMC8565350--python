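"""Colocalization ratio C_R and comparison metrics.

C_R = F_DNA,lipid / F_DNA,background: the mean DNA-channel intensity over
liposome pixels divided by the mean over background pixels, using the binary
mask from the condition threshold.  A value of 1.0 means the DNA is
distributed independently of the liposomes; membrane-bound DNA gives
C_R > 1.  The statistic is ratiometric between liposome-bound and background
dye, so it is invariant under multiplicative changes of the DNA channel
(detector gain, exposure) but *not* under additive offsets — raw intensities
are used deliberately, with no background subtraction.

Pearson's pixel-wise correlation is provided for comparison; unlike C_R it
is known to scale with the area covered by liposomes, which
``area_bias_check`` quantifies by regressing each metric on coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import ConditionSet, TwoChannelImage
from .segmentation import LiposomeMask
from .stats import _ols_line


@dataclass(frozen=True)
class ColocResult:
    """Per-image colocalization metrics."""

    image_id: str
    condition_id: str
    C_R: float
    F_dna_lipid: float
    F_dna_background: float
    coverage: float
    pearson_r: float
    manders_m1: float  # fraction of total DNA intensity inside the mask
    manders_m2: float  # fraction of total lipid intensity inside the mask


@dataclass(frozen=True)
class ConditionSummary:
    condition_id: str
    mean_C_R: float
    sd_C_R: float  # sample SD over images; 0 if a single image
    n_images: int


@dataclass(frozen=True)
class MetricBias:
    """Regression of one metric against liposome coverage."""

    metric: str
    slope: float
    ci95: tuple[float, float]
    correlation: float
    unbiased: bool  # True iff the slope 95% CI contains 0


@dataclass(frozen=True)
class BiasReport:
    per_metric: dict[str, MetricBias]
    n_images: int
    coverage_range: tuple[float, float]


def colocalization_ratio(img: TwoChannelImage, mask: LiposomeMask) -> ColocResult:
    """Compute C_R for one image from its liposome mask.

    Means are arithmetic means of the raw DNA-channel intensities over the
    mask and its strict complement.  An empty liposome or background region
    is an explicit error (a C_R of NaN would silently poison condition
    means).
    """
    m = mask.mask
    if m.shape != img.shape:
        raise ValueError(
            f"mask shape {m.shape} does not match image {img.image_id!r} shape {img.shape}"
        )
    n_in = int(m.sum())
    if n_in == 0:
        raise ValueError(f"image {img.image_id!r}: empty liposome region")
    if n_in == m.size:
        raise ValueError(f"image {img.image_id!r}: empty background region")
    dna = np.asarray(img.dna, dtype=np.float64)
    f_in = float(dna[m].mean())
    f_out = float(dna[~m].mean())
    if f_out == 0:
        raise ValueError(f"image {img.image_id!r}: zero-mean background")
    try:
        r = pearson_coloc(img)
    except ValueError:
        r = float("nan")
    total_dna = float(dna.sum())
    lipid = np.asarray(img.lipid, dtype=np.float64)
    total_lipid = float(lipid.sum())
    return ColocResult(
        image_id=img.image_id,
        condition_id=img.condition_id,
        C_R=f_in / f_out,
        F_dna_lipid=f_in,
        F_dna_background=f_out,
        coverage=mask.coverage,
        pearson_r=r,
        manders_m1=float(dna[m].sum()) / total_dna if total_dna > 0 else float("nan"),
        manders_m2=float(lipid[m].sum()) / total_lipid if total_lipid > 0 else float("nan"),
    )


def pearson_coloc(img: TwoChannelImage) -> float:
    """Pearson correlation over all pixel pairs (lipid_i, dna_i)."""
    lipid = np.asarray(img.lipid, dtype=np.float64).ravel()
    dna = np.asarray(img.dna, dtype=np.float64).ravel()
    if lipid.std() == 0 or dna.std() == 0:
        raise ValueError(f"image {img.image_id!r}: zero-variance channel")
    return float(np.corrcoef(lipid, dna)[0, 1])


def summarize_condition(results: list[ColocResult]) -> ConditionSummary:
    """Condition mean +/- SD of per-image C_R values."""
    if not results:
        raise ValueError("no per-image results to summarize")
    cids = {r.condition_id for r in results}
    if len(cids) > 1:
        raise ValueError(f"results span multiple conditions: {sorted(cids)}")
    vals = np.array([r.C_R for r in results], dtype=float)
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return ConditionSummary(
        condition_id=results[0].condition_id,
        mean_C_R=float(vals.mean()),
        sd_C_R=sd,
        n_images=int(vals.size),
    )


def area_bias_check(results: list[ColocResult]) -> BiasReport:
    """Regress each metric on liposome coverage to detect area bias.

    For C_R and Pearson's r, reports the OLS slope of metric vs coverage,
    its t-based 95% CI, and the Pearson correlation between metric and
    coverage.  A metric is flagged unbiased when the slope CI contains 0.
    Requires >= 10 images spanning a non-degenerate coverage range.
    """
    if len(results) < 10:
        raise ValueError("area bias check requires >= 10 images")
    coverage = np.array([r.coverage for r in results], dtype=float)
    if np.ptp(coverage) == 0:
        raise ValueError("degenerate coverage range: all coverages equal")
    report: dict[str, MetricBias] = {}
    for metric in ("C_R", "pearson_r"):
        y = np.array([getattr(r, metric) for r in results], dtype=float)
        if np.ptp(y) == 0:
            slope, ci, corr = 0.0, (0.0, 0.0), float("nan")
        else:
            slope, _, ci, _ = _ols_line(coverage, y)
            corr = float(np.corrcoef(coverage, y)[0, 1])
        report[metric] = MetricBias(
            metric=metric,
            slope=slope,
            ci95=ci,
            correlation=corr,
            unbiased=ci[0] <= 0.0 <= ci[1],
        )
    return BiasReport(
        per_metric=report,
        n_images=len(results),
        coverage_range=(float(coverage.min()), float(coverage.max())),
    )


def condition_colocalization(
    cond: ConditionSet,
    thr=None,
    min_object_size: int | None = None,
) -> tuple[list[ColocResult], ConditionSummary]:
    """Threshold, mask and score every image of a condition.

    Convenience wrapper running the full per-condition pipeline: pooled
    threshold (unless one is supplied), strict binarization, per-image C_R,
    and the condition summary.
    """
    from .segmentation import binarize, condition_threshold

    if thr is None:
        thr = condition_threshold(cond)
    results = [
        colocalization_ratio(img, binarize(img, thr, min_object_size=min_object_size))
        for img in cond.images
    ]
    return results, summarize_condition(results)
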