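"""Synthetic two-channel microscopy fields and gel images with ground truth.

The imaging generator emulates TIRF fields of surface-tethered liposomes:
bright non-overlapping disks in the lipid (rhodamine) channel over a dim
background, and a DNA channel whose mean intensity on true liposome pixels
is ``enrichment_rho`` times the background mean.  ``enrichment_rho`` is the
ground truth for the colocalization ratio C_R: rho = 1 means the DNA channel
is statistically independent of liposome positions (unbound DNA), rho > 1
means membrane enrichment.

The gel generator emulates an agarose gel shift assay: paired lanes in which
the migrating tile band of the +liposome lane is depleted by a configurable
bound fraction, with the bound signal retained in the well region (liposomes
do not enter the gel matrix).

Every generated object is deterministic under its scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imaging_io import ConditionSet, TwoChannelImage
from .gel_quant import GelLane


class PackingError(RuntimeError):
    """Raised when non-overlapping liposome placement is infeasible."""


# --------------------------------------------------------------------------
# Imaging


@dataclass(frozen=True)
class ImagingScenario:
    """Parameters of one synthetic imaging condition.

    Intensities are in arbitrary units on the stored bit depth.  Defaults
    describe a sparse field (~7% area coverage) of diffraction-blurred
    liposomes far from saturation on a 16-bit scale, with additive Gaussian
    noise at 5% of the channel background.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_images: int = 10
    n_liposomes_per_image: int | Sequence[int] = 40
    liposome_radius: tuple[float, float] = (6.0, 1.0)  # mean, sd (px), truncated > 0
    lipid_fg_mean: float = 4000.0
    lipid_bg_mean: float = 500.0
    dna_bg_mean: float = 1000.0
    enrichment_rho: float = 1.0
    enrichment_jitter_sd: float = 0.0  # per-image SD of the realized enrichment
    noise_model: str = "gaussian"  # or "poisson"
    noise_sd: float | None = None  # gaussian sd; None -> 5% of channel background
    blur_sigma: float = 1.0  # diffraction proxy on the lipid channel (px)
    bit_depth: int = 16
    seed: int = 0
    condition_id: str = "sim"
    variable_name: str = "enrichment_rho"
    variable_value: float | str | None = None

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError("image_shape must be positive")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.enrichment_rho < 0:
            raise ValueError("enrichment_rho must be >= 0")
        if self.enrichment_jitter_sd < 0:
            raise ValueError("enrichment_jitter_sd must be >= 0")
        if self.liposome_radius[0] <= 0 or self.liposome_radius[1] < 0:
            raise ValueError("liposome_radius mean must be > 0 and sd >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        counts = self.counts_per_image()
        if len(counts) != self.n_images or any(c < 0 for c in counts):
            raise ValueError(
                "n_liposomes_per_image must be a non-negative int or a "
                "sequence of length n_images"
            )

    def counts_per_image(self) -> list[int]:
        if isinstance(self.n_liposomes_per_image, (int, np.integer)):
            return [int(self.n_liposomes_per_image)] * self.n_images
        return [int(c) for c in self.n_liposomes_per_image]


@dataclass
class ImagingGroundTruth:
    """Per-image true liposome masks and the generating parameters."""

    masks: list[np.ndarray]
    enrichment_rho: float
    enrichment_per_image: list[float]  # realized rho per image (jitter applied)
    centers: list[np.ndarray]  # (n, 2) row, col per image
    radii: list[np.ndarray]
    clip_fraction: dict[str, float]  # fraction of clipped pixels per channel
    scenario: ImagingScenario


def _place_disks(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius_mean: float,
    radius_sd: float,
    max_attempts: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping disk centres/radii (1 px edge gap)."""
    h, w = shape
    centers = np.empty((n, 2))
    radii = np.empty(n)
    attempts = 0
    placed = 0
    while placed < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {n} non-overlapping liposomes of radius "
                f"~{radius_mean} in {shape} within {max_attempts} attempts"
            )
        attempts += 1
        r = rng.normal(radius_mean, radius_sd)
        if r <= 0.5:
            continue
        if 2 * r + 2 >= min(h, w):
            continue
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        if placed:
            d = np.hypot(centers[:placed, 0] - cy, centers[:placed, 1] - cx)
            if np.any(d < radii[:placed] + r + 1.0):
                continue
        centers[placed] = (cy, cx)
        radii[placed] = r
        placed += 1
    return centers, radii


def _disk_mask(shape: tuple[int, int], centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (cy, cx), r in zip(centers, radii):
        y0, y1 = int(max(0, cy - r - 1)), int(min(shape[0], cy + r + 2))
        x0, x1 = int(max(0, cx - r - 1)), int(min(shape[1], cx + r + 2))
        sub = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2 <= r**2
        mask[y0:y1, x0:x1] |= sub
    return mask


def _render_channel(
    rng: np.random.Generator,
    ideal: np.ndarray,
    noise_model: str,
    noise_sd: float,
    top: int,
) -> tuple[np.ndarray, float]:
    if noise_model == "gaussian":
        noisy = ideal + rng.normal(0.0, noise_sd, ideal.shape)
    else:  # poisson shot noise with the ideal image as the rate
        noisy = rng.poisson(np.clip(ideal, 0, None)).astype(float)
    clipped = (noisy < 0) | (noisy > top)
    out = np.clip(np.rint(noisy), 0, top)
    return out, float(clipped.mean())


def generate_imaging_condition(
    scenario: ImagingScenario,
) -> tuple[ConditionSet, ImagingGroundTruth]:
    """Render one condition of two-channel images plus its ground truth.

    The DNA channel is a sharp two-level field: mean ``dna_bg_mean`` outside
    the true liposome pixels and ``enrichment_rho * dna_bg_mean`` inside
    (enrichment is defined on mean intensity, matching C_R).  The lipid
    channel is hard disks at ``lipid_fg_mean`` over ``lipid_bg_mean``,
    convolved with a Gaussian of ``blur_sigma`` before noise.
    """
    top = 2**scenario.bit_depth - 1
    lipid_sd = (
        scenario.noise_sd if scenario.noise_sd is not None else 0.05 * scenario.lipid_bg_mean
    )
    dna_sd = (
        scenario.noise_sd if scenario.noise_sd is not None else 0.05 * scenario.dna_bg_mean
    )
    counts = scenario.counts_per_image()
    images: list[TwoChannelImage] = []
    masks: list[np.ndarray] = []
    rhos: list[float] = []
    all_centers: list[np.ndarray] = []
    all_radii: list[np.ndarray] = []
    clip_tot = {"lipid": 0.0, "dna": 0.0}
    for i in range(scenario.n_images):
        rng = np.random.default_rng([scenario.seed, i])
        centers, radii = _place_disks(
            rng,
            scenario.image_shape,
            counts[i],
            scenario.liposome_radius[0],
            scenario.liposome_radius[1],
        )
        mask = _disk_mask(scenario.image_shape, centers, radii)
        rho_i = scenario.enrichment_rho
        if scenario.enrichment_jitter_sd > 0:
            rho_i = max(0.0, rho_i + scenario.enrichment_jitter_sd * rng.standard_normal())
        rhos.append(rho_i)

        lipid_ideal = scenario.lipid_bg_mean + (
            scenario.lipid_fg_mean - scenario.lipid_bg_mean
        ) * mask.astype(float)
        if scenario.blur_sigma > 0:
            lipid_ideal = ndimage.gaussian_filter(lipid_ideal, scenario.blur_sigma)
        dna_ideal = scenario.dna_bg_mean * (1.0 + (rho_i - 1.0) * mask.astype(float))

        lipid, clip_l = _render_channel(rng, lipid_ideal, scenario.noise_model, lipid_sd, top)
        dna, clip_d = _render_channel(rng, dna_ideal, scenario.noise_model, dna_sd, top)
        clip_tot["lipid"] += clip_l
        clip_tot["dna"] += clip_d

        dtype = np.uint8 if scenario.bit_depth == 8 else np.uint16
        images.append(
            TwoChannelImage(
                lipid=lipid.astype(dtype),
                dna=dna.astype(dtype),
                bit_depth=scenario.bit_depth,
                image_id=f"{scenario.condition_id}:img{i:03d}",
                condition_id=scenario.condition_id,
            )
        )
        masks.append(mask)
        all_centers.append(centers)
        all_radii.append(radii)

    var_value = (
        scenario.variable_value
        if scenario.variable_value is not None
        else scenario.enrichment_rho
    )
    cond = ConditionSet(scenario.condition_id, scenario.variable_name, var_value, images)
    gt = ImagingGroundTruth(
        masks=masks,
        enrichment_rho=scenario.enrichment_rho,
        enrichment_per_image=rhos,
        centers=all_centers,
        radii=all_radii,
        clip_fraction={k: v / scenario.n_images for k, v in clip_tot.items()},
        scenario=scenario,
    )
    return cond, gt


# --------------------------------------------------------------------------
# Gels


@dataclass(frozen=True)
class GelScenario:
    """Parameters of one synthetic gel-shift image.

    Each lane pair holds a sample lane (+liposomes) and a control lane
    (-liposomes).  The migrating tile band is a Gaussian profile along the
    migration (row) axis, uniform across the lane width.  In the sample lane
    the band amplitude is depleted by ``bound_fraction_true`` and the bound
    signal is rendered in the well region at the top of the lane, never in
    the band region.  ``loading_cv`` applies a per-lane multiplicative
    loading factor to the loaded material (not the background).
    """

    n_lane_pairs: int = 1
    bound_fraction_true: float = 0.5
    image_height: int = 220
    band_center: float = 140.0
    band_sigma: float = 6.0
    well_center: float = 18.0
    well_sigma: float = 2.5
    lane_width: int = 40
    lane_gap: int = 14
    margin: int = 20
    unbound_band_amplitude: float = 3000.0
    well_retained_amplitude: float = 3000.0
    loading_cv: float = 0.02
    background_mean: float = 100.0
    noise_sd: float = 5.0
    seed: int = 0
    gel_id: str = "gel"

    def __post_init__(self) -> None:
        if not 0.0 <= self.bound_fraction_true <= 1.0:
            raise ValueError("bound_fraction_true must lie in [0, 1]")
        if self.n_lane_pairs < 1:
            raise ValueError("n_lane_pairs must be >= 1")
        if self.loading_cv < 0 or self.noise_sd < 0:
            raise ValueError("loading_cv and noise_sd must be >= 0")
        # band box plus equal-height flanking boxes must fit the image
        y0, h = self._band_rows()
        if y0 - h < 0 or y0 + 2 * h > self.image_height:
            raise ValueError(
                "band box with flanking background boxes exceeds image bounds; "
                "increase image_height or move band_center"
            )

    def _band_rows(self) -> tuple[int, int]:
        y0 = int(round(self.band_center - 4 * self.band_sigma))
        h = int(round(8 * self.band_sigma))
        return y0, h

    @property
    def image_width(self) -> int:
        n_lanes = 2 * self.n_lane_pairs
        return 2 * self.margin + n_lanes * self.lane_width + (n_lanes - 1) * self.lane_gap

    def lane_x0(self, lane_index: int) -> int:
        return self.margin + lane_index * (self.lane_width + self.lane_gap)

    def band_box(self, lane_index: int) -> tuple[int, int, int, int]:
        """(x0, y0, w, h), 0-based half-open, of the tile-band box."""
        y0, h = self._band_rows()
        return (self.lane_x0(lane_index), y0, self.lane_width, h)


@dataclass
class GelGroundTruth:
    bound_fraction_true: float
    lanes: list[GelLane]
    band_integrals: dict[str, float]  # expected noiseless band integral per lane
    loading_factors: dict[str, float]
    scenario: GelScenario


def generate_gel_image(scenario: GelScenario) -> tuple[np.ndarray, GelGroundTruth]:
    """Render a gel image with paired +/- liposome lanes and its ground truth.

    Returns the image as a float64 array (densitometry is bit-depth
    agnostic) and ground truth holding the annotated lane boxes, per-lane
    loading factors and the closed-form expected band integrals.
    """
    rng = np.random.default_rng(scenario.seed)
    h, w = scenario.image_height, scenario.image_width
    img = np.full((h, w), scenario.background_mean, dtype=float)
    rows = np.arange(h, dtype=float)
    band_profile = np.exp(-((rows - scenario.band_center) ** 2) / (2 * scenario.band_sigma**2))
    well_profile = np.exp(-((rows - scenario.well_center) ** 2) / (2 * scenario.well_sigma**2))

    f = scenario.bound_fraction_true
    lanes: list[GelLane] = []
    integrals: dict[str, float] = {}
    loadings: dict[str, float] = {}
    y0, bh = scenario._band_rows()
    band_rows_sum = float(band_profile[y0 : y0 + bh].sum())

    for p in range(scenario.n_lane_pairs):
        for j, role in enumerate(("sample", "control")):
            lane_index = 2 * p + j
            x0 = scenario.lane_x0(lane_index)
            loading = max(0.0, 1.0 + scenario.loading_cv * rng.standard_normal()) \
                if scenario.loading_cv > 0 else 1.0
            band_amp = scenario.unbound_band_amplitude * loading
            well_amp = 0.0
            if role == "sample":
                well_amp = scenario.well_retained_amplitude * f * loading
                band_amp *= 1.0 - f
            profile = band_amp * band_profile + well_amp * well_profile
            img[:, x0 : x0 + scenario.lane_width] += profile[:, np.newaxis]

            lane_id = f"{scenario.gel_id}:pair{p}:{role}"
            lanes.append(
                GelLane(
                    lane_id=lane_id,
                    role=role,
                    box=scenario.band_box(lane_index),
                    gel_id=scenario.gel_id,
                )
            )
            integrals[lane_id] = band_amp * scenario.lane_width * band_rows_sum
            loadings[lane_id] = loading

    if scenario.noise_sd > 0:
        img += rng.normal(0.0, scenario.noise_sd, img.shape)
    np.clip(img, 0.0, None, out=img)

    gt = GelGroundTruth(
        bound_fraction_true=f,
        lanes=lanes,
        band_integrals=integrals,
        loading_factors=loadings,
        scenario=scenario,
    )
    return img, gt


def area_bias_counts(n_images: int = 14, low: int = 5, high: int = 80) -> list[int]:
    """Evenly spaced liposome counts for an area-bias validation suite."""
    return [int(round(c)) for c in np.linspace(low, high, n_images)]


def area_bias_suite_scenario(
    seed: int,
    enrichment_rho: float = 2.0,
    n_images: int = 14,
) -> ImagingScenario:
    """Single-condition suite spanning liposome counts 5-80 for bias checks.

    One pooled threshold serves images of widely varying coverage, which is
    exactly the situation in which Pearson's correlation acquires an area
    dependence while C_R does not.  Radius 5 px keeps the pooled threshold
    slightly below the blurred half-edge level, so masks capture whole
    liposomes at every count; per-image enrichment jitter (SD 0.1) emulates
    the image-to-image binding variability of real condition sets.
    """
    counts = area_bias_counts(n_images)
    return ImagingScenario(
        n_images=len(counts),
        n_liposomes_per_image=counts,
        liposome_radius=(5.0, 1.0),
        enrichment_rho=enrichment_rho,
        enrichment_jitter_sd=0.1,
        seed=seed,
        condition_id="area_bias_suite",
    )
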