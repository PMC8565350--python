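"""I/O for two-channel fluorescence image sets and their condition manifests.

A *condition* groups all fields of view acquired under one experimental
setting (e.g. one NaCl concentration).  Images are stored as multi-page
grayscale TIFF; a flat CSV manifest maps each TIFF to its condition, the
experimental variable, and the channel order of the pages.

Manifest columns::

    condition_id, variable_name, variable_value, path, channel_order

``channel_order`` is a comma-separated list drawn from ``{lipid, dna}``
giving the meaning of the channel axis in the referenced TIFF.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

CHANNEL_LABELS = ("lipid", "dna")
MANIFEST_COLUMNS = ("condition_id", "variable_name", "variable_value", "path", "channel_order")


class ManifestError(ValueError):
    """Raised for malformed or inconsistent manifests."""


@dataclass
class TwoChannelImage:
    """One field of view: liposome (rhodamine) and DNA (far-red) channels.

    Parameters
    ----------
    lipid, dna : ndarray
        2-D intensity arrays of identical shape.
    bit_depth : int
        8 or 16; pixel values must lie in ``[0, 2**bit_depth - 1]``.
    image_id, condition_id : str
        Identifiers used to tie masks and results back to their source.
    """

    lipid: np.ndarray
    dna: np.ndarray
    bit_depth: int
    image_id: str
    condition_id: str

    def __post_init__(self) -> None:
        self.lipid = np.asarray(self.lipid)
        self.dna = np.asarray(self.dna)
        if self.lipid.ndim != 2 or self.dna.ndim != 2:
            raise ValueError(f"image {self.image_id!r}: channels must be 2-D")
        if self.lipid.shape != self.dna.shape:
            raise ValueError(
                f"image {self.image_id!r}: channel shape mismatch "
                f"{self.lipid.shape} vs {self.dna.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        top = 2**self.bit_depth - 1
        for name, arr in (("lipid", self.lipid), ("dna", self.dna)):
            if arr.size and (arr.min() < 0 or arr.max() > top):
                raise ValueError(
                    f"image {self.image_id!r}: {name} channel outside "
                    f"[0, {top}] for bit depth {self.bit_depth}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.lipid.shape


@dataclass
class ConditionSet:
    """All images of a single experimental condition.

    The condition is the unit over which the segmentation threshold is
    pooled and over which C_R summaries (mean +/- SD) are reported.
    """

    condition_id: str
    variable_name: str
    variable_value: float | str
    images: list[TwoChannelImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError(f"condition {self.condition_id!r} has no images")
        depths = {img.bit_depth for img in self.images}
        if len(depths) > 1:
            raise ValueError(
                f"condition {self.condition_id!r} mixes bit depths {sorted(depths)}; "
                "rescaling is not performed because thresholds pool raw intensities"
            )
        for img in self.images:
            if img.condition_id != self.condition_id:
                raise ValueError(
                    f"image {img.image_id!r} belongs to {img.condition_id!r}, "
                    f"not {self.condition_id!r}"
                )

    @property
    def bit_depth(self) -> int:
        return self.images[0].bit_depth

    def __len__(self) -> int:
        return len(self.images)


def _bit_depth_from_dtype(dtype: np.dtype, path: Path) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise ManifestError(f"{path}: unsupported pixel dtype {dtype}; expected uint8/uint16")


def _parse_channel_order(value: str) -> tuple[str, ...]:
    labels = tuple(s.strip().lower() for s in str(value).split(","))
    if sorted(labels) != sorted(CHANNEL_LABELS):
        raise ManifestError(
            f"channel_order {value!r} must name each of {CHANNEL_LABELS} exactly once"
        )
    return labels


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: manifest missing columns {missing}")
    return df


def load_condition(
    manifest: str | Path | pd.DataFrame,
    condition_id: str,
    root: str | Path | None = None,
    average_frames: int = 1,
) -> ConditionSet:
    """Load all images of one condition from a manifest.

    Each manifest row references a grayscale TIFF whose pages hold either a
    single two-channel image (shape ``(2, H, W)``) or a stack of them
    (``(n, 2, H, W)``).  Channels are assigned from the row's
    ``channel_order``.

    Parameters
    ----------
    average_frames : int
        If > 1, consecutive groups of that many frames are averaged into one
        image (registered repeat acquisitions of the same field).  Off by
        default.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        manifest = read_manifest(manifest_path)
        if root is None:
            root = manifest_path.parent
    rows = manifest[manifest["condition_id"] == condition_id]
    if rows.empty:
        raise ManifestError(f"condition {condition_id!r} not present in manifest")
    if average_frames < 1:
        raise ValueError("average_frames must be >= 1")

    images: list[TwoChannelImage] = []
    var_name = str(rows.iloc[0]["variable_name"])
    var_value = rows.iloc[0]["variable_value"]
    for _, row in rows.iterrows():
        path = Path(row["path"])
        if root is not None and not path.is_absolute():
            path = Path(root) / path
        if not path.exists():
            raise FileNotFoundError(f"image file not found: {path}")
        order = _parse_channel_order(row["channel_order"])
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - surface the file name
            raise IOError(f"failed to read TIFF {path}: {exc}") from exc
        if arr.ndim == 3:
            arr = arr[np.newaxis]
        if arr.ndim != 4 or arr.shape[1] != 2:
            raise ManifestError(
                f"{path}: expected pages (2, H, W) or (n, 2, H, W), got {arr.shape}"
            )
        depth = _bit_depth_from_dtype(arr.dtype, path)
        channel_axis = {label: i for i, label in enumerate(order)}
        for k in range(arr.shape[0]):
            images.append(
                TwoChannelImage(
                    lipid=arr[k, channel_axis["lipid"]],
                    dna=arr[k, channel_axis["dna"]],
                    bit_depth=depth,
                    image_id=f"{condition_id}:{path.stem}:{k}",
                    condition_id=condition_id,
                )
            )
    if average_frames > 1:
        if len(images) % average_frames:
            raise ValueError(
                f"{len(images)} frames not divisible by average_frames={average_frames}"
            )
        grouped = []
        top = 2 ** images[0].bit_depth - 1
        for g in range(0, len(images), average_frames):
            block = images[g : g + average_frames]
            lipid = np.mean([b.lipid for b in block], axis=0).clip(0, top)
            dna = np.mean([b.dna for b in block], axis=0).clip(0, top)
            grouped.append(
                TwoChannelImage(
                    lipid=lipid,
                    dna=dna,
                    bit_depth=block[0].bit_depth,
                    image_id=block[0].image_id + f"+avg{average_frames}",
                    condition_id=condition_id,
                )
            )
        images = grouped
    return ConditionSet(condition_id, var_name, var_value, images)


def _encode_mask(mask: np.ndarray) -> dict:
    packed = np.packbits(np.asarray(mask, dtype=bool), axis=None)
    return {
        "shape": list(mask.shape),
        "packed_bits_b64": base64.b64encode(packed.tobytes()).decode("ascii"),
    }


def decode_mask(entry: Mapping) -> np.ndarray:
    shape = tuple(entry["shape"])
    raw = np.frombuffer(base64.b64decode(entry["packed_bits_b64"]), dtype=np.uint8)
    flat = np.unpackbits(raw)[: shape[0] * shape[1]]
    return flat.astype(bool).reshape(shape)


def write_condition(
    cond: ConditionSet,
    out_dir: str | Path,
    ground_truth: Mapping | None = None,
) -> dict:
    """Write one condition as a multi-page TIFF plus optional JSON sidecar.

    Pages are ordered image-major with the two channels as separate pages
    (axes ``TCYX``, channel order lipid, dna).  Returns the manifest row for
    the written file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dtype = np.uint8 if cond.bit_depth == 8 else np.uint16
    stack = np.stack(
        [np.stack([img.lipid, img.dna]).astype(dtype) for img in cond.images]
    )
    tif_path = out_dir / f"{cond.condition_id}.tif"
    tifffile.imwrite(
        tif_path,
        stack,
        metadata={"axes": "TCYX", "channels": list(CHANNEL_LABELS)},
    )
    if ground_truth is not None:
        sidecar = dict(ground_truth)
        if "masks" in sidecar:
            sidecar["masks"] = [_encode_mask(m) for m in sidecar["masks"]]
        (out_dir / f"{cond.condition_id}.groundtruth.json").write_text(
            json.dumps(sidecar)
        )
    return {
        "condition_id": cond.condition_id,
        "variable_name": cond.variable_name,
        "variable_value": cond.variable_value,
        "path": tif_path.name,
        "channel_order": ",".join(CHANNEL_LABELS),
    }


def write_manifest(rows: Iterable[Mapping], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(list(rows), columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, index=False)
    return df


DETAIL_COLUMNS = (
    "condition_id",
    "image_id",
    "C_R",
    "coverage",
    "F_dna_lipid",
    "F_dna_background",
    "pearson_r",
)


def write_results_table(
    results: pd.DataFrame | Sequence[Mapping],
    detail_path: str | Path,
    summary_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the per-image results CSV and a per-condition summary CSV.

    The summary holds mean, SD (sample SD; 0 for a single image) and n of
    C_R per condition.  Raises on empty input rather than writing an empty
    file.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame([dict(r) for r in results])
    if results.empty:
        raise ValueError("no results to write")
    missing = [c for c in DETAIL_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results missing columns {missing}")
    results = results.loc[:, list(DETAIL_COLUMNS)]
    results.to_csv(detail_path, index=False)
    summary = (
        results.groupby("condition_id")["C_R"]
        .agg(mean_C_R="mean", sd_C_R=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0, n_images="size")
        .reset_index()
    )
    if summary_path is not None:
        summary.to_csv(summary_path, index=False)
    return summary
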