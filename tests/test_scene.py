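import numpy as np
import pytest

from thermoleaf.exceptions import (
    BoundsError,
    ConfigurationError,
    FrameParseError,
    ValidationError,
)
from thermoleaf.scene import (
    FrameSequence,
    RegionOfInterest,
    ThermalFrame,
    read_frame,
    read_manifest,
    roi_extract,
    validate_roi_set,
    write_frame,
    write_manifest,
)


def make_frame(grid, t=0.0, fid="f0"):
    return ThermalFrame(np.asarray(grid, dtype=float), timestamp_min=t, frame_id=fid)


class TestFrameValidation:
    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError, match="non-finite"):
            make_frame([[28.0, np.nan], [30.0, 31.0]])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError, match="physical range"):
            make_frame([[28.0, 95.0]])

    def test_rejects_empty_and_non_2d(self):
        with pytest.raises(ValidationError):
            make_frame(np.empty((0, 0)))
        with pytest.raises(ValidationError):
            make_frame([1.0, 2.0])

    def test_default_emissivity(self):
        assert make_frame([[30.0]]).emissivity == 0.95


class TestFrameIO:
    @pytest.mark.parametrize("fmt", ["temperature_csv", "float_tiff"])
    def test_round_trip_within_tolerance(self, tmp_path, fmt):
        rng = np.random.default_rng(0)
        frame = make_frame(20 + 10 * rng.random((12, 9)), t=40.0, fid="rt")
        path = tmp_path / ("f.csv" if fmt == "temperature_csv" else "f.tiff")
        write_frame(frame, path, format=fmt)
        back = read_frame(path, format=fmt)
        assert np.allclose(back.temperatures, frame.temperatures, atol=1e-4)
        assert back.timestamp_min == 40.0
        assert back.frame_id == "rt"

    def test_csv_direct_read(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("28.0,29.0\n30.0,31.0\n")
        frame = read_frame(p)
        assert frame.temperatures.max() == 31.0
        assert frame.temperatures.min() == 28.0

    def test_sidecar_records_emissivity(self, tmp_path):
        frame = make_frame([[30.0, 31.0]])
        write_frame(frame, tmp_path / "e.csv")
        assert '"emissivity": 0.95' in (tmp_path / "e.csv.json").read_text()

    def test_nan_cell_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("28.0,NaN\n30.0,31.0\n")
        with pytest.raises(ValidationError, match="non-finite"):
            read_frame(p)

    def test_ragged_rows_named(self, tmp_path):
        p = tmp_path / "ragged.csv"
        p.write_text("28.0,29.0\n30.0\n")
        with pytest.raises(FrameParseError, match="row 1"):
            read_frame(p)


class TestRoiExtract:
    def test_full_frame_rectangle(self):
        frame = make_frame([[28.0, 29.0], [30.0, 31.0]])
        roi = RegionOfInterest("all", "rectangle", (0, 0, 2, 2))
        assert roi_extract(frame, roi).tolist() == [28.0, 29.0, 30.0, 31.0]

    def test_point_cursor_uniform_field(self):
        frame = make_frame(np.full((5, 5), 30.0))
        roi = RegionOfInterest("air", "point_cursor", (1, 1, 4, 4), role="air_cursor")
        assert roi_extract(frame, roi).tolist() == [30.0] * 9

    def test_single_pixel(self):
        frame = make_frame([[28.0, 29.0], [30.0, 31.0]])
        roi = RegionOfInterest("px", "rectangle", (1, 0, 2, 1))
        assert roi_extract(frame, roi).tolist() == [30.0]

    def test_rectangle_pixel_count(self):
        frame = make_frame(np.full((20, 30), 25.0))
        roi = RegionOfInterest("r", "rectangle", (2, 3, 9, 17))
        assert roi_extract(frame, roi).size == 7 * 14

    def test_oval_subset_of_rectangle(self):
        frame = make_frame(np.full((20, 30), 25.0))
        rect = RegionOfInterest("r", "rectangle", (2, 3, 12, 17))
        oval = RegionOfInterest("o", "oval", (2, 3, 12, 17))
        assert 0 < roi_extract(frame, oval).size <= roi_extract(frame, rect).size

    def test_out_of_bounds(self):
        frame = make_frame(np.full((5, 5), 25.0))
        roi = RegionOfInterest("big", "rectangle", (0, 0, 6, 6))
        with pytest.raises(BoundsError):
            roi_extract(frame, roi)


class TestRoiValidation:
    def test_air_cursor_must_be_3x3(self):
        with pytest.raises(ValidationError, match="3x3"):
            RegionOfInterest("air", "point_cursor", (0, 0, 2, 2), role="air_cursor")

    def test_scene_needs_one_air_cursor(self):
        plants = [RegionOfInterest("p", "rectangle", (0, 0, 5, 5))]
        with pytest.raises(ConfigurationError):
            validate_roi_set(plants)
        air = RegionOfInterest("a", "point_cursor", (0, 0, 3, 3), role="air_cursor")
        validate_roi_set(plants + [air])
        with pytest.raises(ConfigurationError):
            validate_roi_set(plants + [air, air])


class TestFrameSequence:
    def test_timestamps_strictly_increasing(self):
        frames = [make_frame([[30.0]], t=t, fid=f"f{i}")
                  for i, t in enumerate([0.0, 10.0, 10.0])]
        with pytest.raises(ValidationError, match="increasing"):
            FrameSequence(frames)

    def test_cadence_consistency(self):
        frames = [make_frame([[30.0]], t=t, fid=f"f{i}")
                  for i, t in enumerate([0.0, 10.0, 25.0])]
        with pytest.raises(ValidationError, match="cadence"):
            FrameSequence(frames, cadence_min=10.0)

    def test_manifest_round_trip(self, tmp_path):
        frames = [make_frame(np.full((4, 4), 25.0 + i), t=10.0 * i, fid=f"f{i}")
                  for i in range(3)]
        seq = FrameSequence(frames)
        manifest = write_manifest(seq, tmp_path)
        back = read_manifest(manifest)
        assert [f.frame_id for f in back.frames] == ["f0", "f1", "f2"]
        for a, b in zip(seq.frames, back.frames):
            assert np.allclose(a.temperatures, b.temperatures, atol=1e-4)

    def test_manifest_missing_frame_named(self, tmp_path):
        frames = [make_frame(np.full((4, 4), 25.0), t=10.0 * i, fid=f"f{i}")
                  for i in range(2)]
        manifest = write_manifest(FrameSequence(frames), tmp_path)
        (tmp_path / "frames" / "f1.csv").unlink()
        with pytest.raises(FileNotFoundError, match="f1"):
            read_manifest(manifest)
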