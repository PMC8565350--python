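"""Round-trips and validation for TIFF/manifest/results I/O."""

import numpy as np
import pandas as pd
import pytest
import tifffile

from conftest import make_condition, make_image
from lipoquant import load_condition, write_results_table
from lipoquant.imaging_io import (
    ManifestError,
    decode_mask,
    read_manifest,
    write_condition,
    write_manifest,
)


@pytest.fixture
def written_condition(tmp_path, small_condition):
    cond, gt = small_condition
    row = write_condition(
        cond, tmp_path, ground_truth={"enrichment_rho": gt.enrichment_rho, "masks": gt.masks}
    )
    write_manifest([row], tmp_path / "manifest.csv")
    return tmp_path, cond, gt


class TestRoundTrip:
    def test_pixels_and_metadata_survive(self, written_condition):
        tmp_path, cond, gt = written_condition
        loaded = load_condition(tmp_path / "manifest.csv", cond.condition_id)
        assert len(loaded) == len(cond)
        assert loaded.bit_depth == cond.bit_depth
        assert loaded.variable_name == cond.variable_name
        for orig, back in zip(cond.images, loaded.images):
            np.testing.assert_array_equal(orig.lipid, back.lipid)
            np.testing.assert_array_equal(orig.dna, back.dna)

    def test_ground_truth_sidecar_masks_decode(self, written_condition):
        tmp_path, cond, gt = written_condition
        import json

        sidecar = json.loads((tmp_path / f"{cond.condition_id}.groundtruth.json").read_text())
        assert sidecar["enrichment_rho"] == gt.enrichment_rho
        for entry, mask in zip(sidecar["masks"], gt.masks):
            np.testing.assert_array_equal(decode_mask(entry), mask)

    def test_reversed_channel_order_swaps_assignment(self, tmp_path):
        lipid = np.full((8, 8), 100, np.uint16)
        dna = np.full((8, 8), 900, np.uint16)
        tifffile.imwrite(tmp_path / "img.tif", np.stack([dna, lipid]))  # dna first
        write_manifest(
            [
                {
                    "condition_id": "c",
                    "variable_name": "v",
                    "variable_value": 0,
                    "path": "img.tif",
                    "channel_order": "dna,lipid",
                }
            ],
            tmp_path / "manifest.csv",
        )
        cond = load_condition(tmp_path / "manifest.csv", "c")
        assert cond.images[0].lipid[0, 0] == 100
        assert cond.images[0].dna[0, 0] == 900

    def test_two_files_yield_two_images(self, tmp_path):
        rows = []
        for k in range(2):
            arr = np.full((2, 8, 8), 10 * (k + 1), np.uint16)
            tifffile.imwrite(tmp_path / f"f{k}.tif", arr)
            rows.append(
                {
                    "condition_id": "c",
                    "variable_name": "v",
                    "variable_value": 0,
                    "path": f"f{k}.tif",
                    "channel_order": "lipid,dna",
                }
            )
        write_manifest(rows, tmp_path / "manifest.csv")
        assert len(load_condition(tmp_path / "manifest.csv", "c")) == 2


class TestErrors:
    def _manifest(self, tmp_path, **overrides):
        row = {
            "condition_id": "c",
            "variable_name": "v",
            "variable_value": 0,
            "path": "img.tif",
            "channel_order": "lipid,dna",
        }
        row.update(overrides)
        write_manifest([row], tmp_path / "manifest.csv")
        return tmp_path / "manifest.csv"

    def test_missing_file(self, tmp_path):
        manifest = self._manifest(tmp_path, path="absent.tif")
        with pytest.raises(FileNotFoundError, match="absent.tif"):
            load_condition(manifest, "c")

    def test_corrupt_tiff_names_file(self, tmp_path):
        (tmp_path / "img.tif").write_text("this is not a TIFF")
        with pytest.raises(IOError, match="img.tif"):
            load_condition(self._manifest(tmp_path), "c")

    def test_unknown_channel_label(self, tmp_path):
        tifffile.imwrite(tmp_path / "img.tif", np.zeros((2, 4, 4), np.uint16))
        with pytest.raises(ManifestError, match="channel_order"):
            load_condition(self._manifest(tmp_path, channel_order="lipid,gfp"), "c")

    def test_unknown_condition(self, tmp_path):
        tifffile.imwrite(tmp_path / "img.tif", np.zeros((2, 4, 4), np.uint16))
        with pytest.raises(ManifestError, match="not present"):
            load_condition(self._manifest(tmp_path), "zzz")

    def test_manifest_missing_columns(self, tmp_path):
        pd.DataFrame({"condition_id": ["c"]}).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ManifestError, match="missing columns"):
            read_manifest(tmp_path / "m.csv")

    def test_mixed_bit_depths_rejected(self):
        img8 = make_image(
            np.zeros((4, 4), np.uint8), np.zeros((4, 4), np.uint8), "a", bit_depth=8
        )
        img16 = make_image(
            np.zeros((4, 4), np.uint16), np.zeros((4, 4), np.uint16), "b", bit_depth=16
        )
        with pytest.raises(ValueError, match="bit depth"):
            make_condition([img8, img16])

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            make_image(np.zeros((4, 4), np.uint16), np.zeros((4, 5), np.uint16))


class TestFrameAveraging:
    def test_pairs_average_and_count_halves(self, tmp_path):
        a = np.zeros((2, 4, 4), np.uint16)
        b = np.full((2, 4, 4), 100, np.uint16)
        tifffile.imwrite(tmp_path / "img.tif", np.stack([a, b]))
        write_manifest(
            [
                {
                    "condition_id": "c",
                    "variable_name": "v",
                    "variable_value": 0,
                    "path": "img.tif",
                    "channel_order": "lipid,dna",
                }
            ],
            tmp_path / "manifest.csv",
        )
        cond = load_condition(tmp_path / "manifest.csv", "c", average_frames=2)
        assert len(cond) == 1
        assert float(cond.images[0].lipid.mean()) == 50.0


class TestResultsTable:
    def _detail(self, n=3):
        return [
            {
                "condition_id": "c",
                "image_id": f"i{k}",
                "C_R": 1.5 + 0.1 * k,
                "coverage": 0.05,
                "F_dna_lipid": 1500.0,
                "F_dna_background": 1000.0,
                "pearson_r": 0.3,
            }
            for k in range(n)
        ]

    def test_detail_and_summary_rows(self, tmp_path):
        summary = write_results_table(
            self._detail(3), tmp_path / "detail.csv", tmp_path / "summary.csv"
        )
        assert len(pd.read_csv(tmp_path / "detail.csv")) == 3
        assert len(summary) == 1
        assert summary.loc[0, "n_images"] == 3

    def test_empty_input_is_an_error(self, tmp_path):
        with pytest.raises(ValueError, match="no results"):
            write_results_table([], tmp_path / "detail.csv")
        assert not (tmp_path / "detail.csv").exists()

    def test_round_trip_preserves_six_significant_digits(self, tmp_path):
        detail = self._detail(2)
        detail[0]["C_R"] = 1.2345678901
        write_results_table(detail, tmp_path / "detail.csv")
        back = pd.read_csv(tmp_path / "detail.csv")
        assert back.loc[0, "C_R"] == pytest.approx(1.2345678901, rel=1e-6)
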