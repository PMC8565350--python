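"""Gel-shift densitometry: band integration, bound fraction, occupancy.

In the gel shift assay, membrane-bound DNA origami tiles are retained in
the wells together with the liposomes while unbound tiles migrate as a
discrete band.  Binding is quantified by comparing the integrated tile-band
intensity in the +liposome (sample) lane, B, with the -liposome (control)
lane, U, run on the same gel:

    T = (1 - B/U) * 100%

Band integrals are background-corrected using the median pixel intensity of
two flanking boxes of equal size directly above and below the band box.
Because non-specific retention varies between gels and liposome
preparations, sample and control lanes must share a gel; the API enforces
within-gel pairing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

LANE_ROLES = ("sample", "control")


@dataclass(frozen=True)
class GelLane:
    """One annotated lane box on a gel image.

    ``box`` is (x0, y0, width, height), 0-based, half-open, delimiting the
    tile-band region of the lane.
    """

    lane_id: str
    role: str
    box: tuple[int, int, int, int]
    gel_id: str = "gel"

    def __post_init__(self) -> None:
        if self.role not in LANE_ROLES:
            raise ValueError(f"lane role must be one of {LANE_ROLES}, got {self.role!r}")
        x0, y0, w, h = self.box
        if w <= 0 or h <= 0:
            raise ValueError(f"lane {self.lane_id!r}: box must have positive size")


@dataclass(frozen=True)
class BandMeasurement:
    """Integrated band intensity for one lane, with background estimate."""

    lane_id: str
    gel_id: str
    raw_integral: float
    background_per_pixel: float
    integrated_intensity: float  # background-corrected, floored at 0
    floored: bool  # True when the corrected integral was negative


@dataclass(frozen=True)
class OccupancyEstimate:
    """Extrapolated handle occupancy from a low-count linear fit."""

    slope_per_handle: float
    intercept: float
    estimated_cholesterols: float
    estimated_occupancy_fraction: float
    ci95: tuple[float, float]  # on estimated_cholesterols
    nominal_n: int
    n_fit_points: int


def integrate_band(image: np.ndarray, lane: GelLane) -> BandMeasurement:
    """Integrate a lane's band box with flanking-median background correction.

    The background per pixel is the median intensity over two boxes of the
    same width and height placed directly above and below the band box.
    Both flanking boxes must lie within the image.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("gel image must be 2-D")
    x0, y0, w, h = lane.box
    ih, iw = image.shape
    if not (0 <= x0 and x0 + w <= iw and 0 <= y0 and y0 + h <= ih):
        raise ValueError(f"lane {lane.lane_id!r}: box {lane.box} outside image {image.shape}")
    if y0 - h < 0 or y0 + 2 * h > ih:
        raise ValueError(
            f"lane {lane.lane_id!r}: flanking background boxes fall outside the image"
        )
    band = image[y0 : y0 + h, x0 : x0 + w]
    flank = np.concatenate(
        [
            image[y0 - h : y0, x0 : x0 + w].ravel(),
            image[y0 + h : y0 + 2 * h, x0 : x0 + w].ravel(),
        ]
    )
    raw = float(band.sum())
    bg = float(np.median(flank))
    corrected = raw - bg * band.size
    floored = corrected < 0
    if floored:
        warnings.warn(
            f"lane {lane.lane_id!r}: background-corrected integral negative "
            f"({corrected:.3g}); floored to 0",
            stacklevel=2,
        )
    return BandMeasurement(
        lane_id=lane.lane_id,
        gel_id=lane.gel_id,
        raw_integral=raw,
        background_per_pixel=bg,
        integrated_intensity=max(0.0, corrected),
        floored=floored,
    )


def bound_fraction(B: float, U: float) -> float:
    """Percentage of tiles bound to the membrane: T = (1 - B/U) * 100.

    B and U are the integrated tile-band intensities of the +liposome and
    -liposome lanes.  U must be positive; a negative T (B > U, possible
    under loading noise) is reported as-is with a warning.
    """
    if U <= 0:
        raise ValueError(f"control band intensity U must be > 0, got {U}")
    if B < 0:
        raise ValueError(f"sample band intensity B must be >= 0, got {B}")
    T = (1.0 - B / U) * 100.0
    if T < 0:
        warnings.warn(
            f"bound fraction negative ({T:.2f}%): sample band exceeds control; "
            "likely loading variation",
            stacklevel=2,
        )
    return T


def bound_fraction_from_bands(sample: BandMeasurement, control: BandMeasurement) -> float:
    """T from paired band measurements; lanes must come from the same gel."""
    if sample.gel_id != control.gel_id:
        raise ValueError(
            f"cross-gel comparison not allowed: {sample.gel_id!r} vs {control.gel_id!r}; "
            "samples are compared within gels only"
        )
    return bound_fraction(sample.integrated_intensity, control.integrated_intensity)


def bound_fraction_replicates(pairs: Sequence[tuple[BandMeasurement, BandMeasurement]]):
    """Mean +/- SD of T over replicate gels (>= 2 expected in practice).

    Each pair is (sample, control) from one gel.  Returns (mean, sd, n);
    sd is the sample SD, 0 for a single gel.
    """
    if not pairs:
        raise ValueError("no replicate gels supplied")
    ts = np.array([bound_fraction_from_bands(s, c) for s, c in pairs], dtype=float)
    sd = float(ts.std(ddof=1)) if ts.size > 1 else 0.0
    return float(ts.mean()), sd, int(ts.size)


def normalized_band_intensity(cy5: BandMeasurement, stain: BandMeasurement) -> float:
    """Cy5 band integral normalized to the total-DNA stain channel integral.

    Used to compare cholesterol-dependent fluorophore attachment between
    lanes while controlling for the amount of DNA loaded.
    """
    if stain.integrated_intensity <= 0:
        raise ValueError("stain band integral must be > 0 for normalization")
    return cy5.integrated_intensity / stain.integrated_intensity


def occupancy_regression(
    points: Sequence[tuple[float, float]],
    nominal_n: int,
    max_fit_n: float = 4.0,
) -> OccupancyEstimate:
    """Estimate handle occupancy at a high handle count from a low-count fit.

    Fluorescence per attached strand is assumed linear for low handle counts
    (n = 0..4), so intensity = intercept + slope * n there.  The intercept
    is tied to the n = 0 measurement (mean over its replicates) and the
    slope is fit by least squares through the origin on the n > 0 low-count
    deviations.  The apparent number of occupied handles at the nominal
    count is then (observed intensity - intercept) / slope, with a 95% CI
    propagating the slope and observation uncertainty via t-based standard
    errors (df = number of low-count fit points - 1).

    ``points`` are (handle_count, intensity) pairs and must include n = 0,
    at least three distinct counts <= ``max_fit_n``, and at least one
    observation at ``nominal_n``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (handle_count, intensity) pairs")
    n_vals, y_vals = pts[:, 0], pts[:, 1]
    if nominal_n <= max_fit_n:
        raise ValueError("nominal_n must exceed the largest fitted handle count")
    low = n_vals <= max_fit_n
    if np.unique(n_vals[low]).size < 3:
        raise ValueError("need >= 3 distinct low handle counts to fit")
    if not np.any(n_vals == 0):
        raise ValueError("an n = 0 measurement is required for the intercept")
    at_nominal = n_vals == nominal_n
    if not np.any(at_nominal):
        raise ValueError(f"no observation at nominal handle count {nominal_n}")

    y0 = float(y_vals[n_vals == 0].mean())
    m0 = int(np.sum(n_vals == 0))
    fit = low & (n_vals > 0)
    nf, yf = n_vals[fit], y_vals[fit] - y0
    slope = float(np.sum(nf * yf) / np.sum(nf**2))
    if slope <= 0:
        raise ValueError(f"fitted slope {slope:.4g} <= 0; occupancy undefined")
    dof = int(nf.size - 1)
    resid = yf - slope * nf
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0

    y_obs = float(y_vals[at_nominal].mean())
    m_obs = int(np.sum(at_nominal))
    est = (y_obs - y0) / slope

    var_slope = s2 / float(np.sum(nf**2))
    var_obs = s2 / m_obs
    var_y0 = s2 / m0
    # slope itself depends on y0 through the deviations
    var_slope += var_y0 * (float(np.sum(nf)) / float(np.sum(nf**2))) ** 2
    var_est = (var_obs + var_y0) / slope**2 + (y_obs - y0) ** 2 * var_slope / slope**4
    tcrit = sps.t.ppf(0.975, dof) if dof > 0 else float("inf")
    half = tcrit * np.sqrt(var_est) if var_est > 0 else 0.0
    return OccupancyEstimate(
        slope_per_handle=slope,
        intercept=y0,
        estimated_cholesterols=est,
        estimated_occupancy_fraction=est / nominal_n,
        ci95=(est - half, est + half),
        nominal_n=int(nominal_n),
        n_fit_points=int(nf.size),
    )
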