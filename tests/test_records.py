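"""Data model, container IO, padding, resolution reduction, partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepseg.errors import (
    AlignmentError,
    FormatError,
    ParameterError,
    SizeError,
    ValidationError,
)
from sleepseg.records import (
    CANONICAL_CHANNELS,
    LabelTrack,
    PolysomnogramRecord,
    StageTrack,
    center_pad,
    center_pad_arrays,
    downsample_average,
    downsample_labels,
    read_predictions,
    read_record,
    split_records,
    write_predictions,
    write_record,
)


def _record(rng, n=256, record_id="r0"):
    return PolysomnogramRecord(
        record_id, 200.0, CANONICAL_CHANNELS,
        rng.normal(size=(13, n)),
    )


class TestContainerIO:
    def test_hdf5_round_trip_is_lossless(self, rng, tmp_path):
        record = _record(rng)
        labels = LabelTrack(rng.choice([-1, 0, 1], size=256))
        stages = StageTrack(rng.integers(0, 8, size=256))
        path = tmp_path / "r0.h5"
        write_record(path, record, labels, stages)
        back, lab, stg = read_record(path)
        np.testing.assert_array_equal(back.samples, record.samples)
        np.testing.assert_array_equal(lab.values, labels.values)
        np.testing.assert_array_equal(stg.values, stages.values)
        assert back.channel_names == record.channel_names
        assert back.sampling_rate == record.sampling_rate
        assert back.record_id == "r0"

    def test_channels_reordered_to_canonical(self, rng, tmp_path):
        record = _record(rng)
        shuffled = PolysomnogramRecord(
            "r1", 200.0, tuple(reversed(CANONICAL_CHANNELS)),
            record.samples[::-1],
        )
        path = tmp_path / "r1.h5"
        write_record(path, shuffled)
        back, _, _ = read_record(path)
        assert back.channel_names == CANONICAL_CHANNELS
        np.testing.assert_array_equal(back.samples, record.samples)

    def test_missing_channel_is_named_in_error(self, rng, tmp_path):
        record = _record(rng)
        partial = PolysomnogramRecord(
            "r2", 200.0, CANONICAL_CHANNELS[:12], record.samples[:12]
        )
        path = tmp_path / "r2.h5"
        write_record(path, partial)
        with pytest.raises(FormatError, match="ECG"):
            read_record(path)

    def test_label_length_mismatch_raises(self, rng, tmp_path):
        record = _record(rng)
        with pytest.raises(AlignmentError):
            write_record(tmp_path / "x.h5", record,
                         LabelTrack(np.zeros(255, dtype=np.int8)))

    def test_wfdb_mat_adapter_reads_physical_units(self, rng, tmp_path):
        from scipy.io import savemat

        # PhysioNet-2018-style montage with vendor channel labels
        names = ["F3-M2", "F4-M1", "C3-M2", "C4-M1", "O1-M2", "O2-M1",
                 "E1-M2", "Chin1-Chin2", "ABD", "CHEST", "AIRFLOW",
                 "SaO2", "ECG"]
        gains = np.full(13, 6553.59)
        physical = rng.normal(size=(13, 128)).round(3)
        digital = np.round(physical * gains[:, None]).astype(np.int16)
        savemat(tmp_path / "tr00-0001.mat", {"val": digital})
        lines = ["tr00-0001 13 200 128"]
        for name in names:
            lines.append(f"tr00-0001.mat 16 6553.59(0)/uV 16 0 0 0 0 {name}")
        (tmp_path / "tr00-0001.hea").write_text("\n".join(lines) + "\n")
        record, labels, _ = read_record(tmp_path / "tr00-0001.mat")
        assert labels is None
        assert record.channel_names == CANONICAL_CHANNELS
        assert record.sampling_rate == 200.0
        np.testing.assert_allclose(
            record.samples, digital / gains[:, None], rtol=0, atol=1e-12
        )


class TestPredictionFiles:
    def test_round_trip_within_tolerance(self, rng, tmp_path):
        probs = rng.random(5)
        path = tmp_path / "p.vec"
        write_predictions(probs, path)
        assert len(path.read_text().strip().splitlines()) == 5
        np.testing.assert_allclose(read_predictions(path), probs, atol=1e-6)

    def test_out_of_range_probability_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_predictions(np.array([0.2, 1.5]), tmp_path / "bad.vec")


class TestCenterPad:
    @pytest.mark.parametrize(
        "n,target,expected_offset", [(8, 8, 0), (6, 8, 1), (5, 8, 1)]
    )
    def test_offset_follows_floor_rule(self, rng, n, target, expected_offset):
        record = _record(rng, n=n)
        labels = LabelTrack(np.zeros(n, dtype=np.int8))
        padded, plabels, offset = center_pad(record, labels, target)
        assert offset == expected_offset
        assert padded.n_timepoints == target
        assert len(plabels) == target
        # padding is zero signal, -1 labels
        assert np.all(plabels.values[:offset] == -1)
        assert np.all(plabels.values[offset + n:] == -1)
        assert np.all(padded.samples[:, :offset] == 0)

    def test_truncation_refused(self, rng):
        record = _record(rng, n=16)
        with pytest.raises(SizeError):
            center_pad(record, LabelTrack(np.zeros(16, dtype=np.int8)), 8)

    @given(n=st.integers(1, 64), extra=st.integers(0, 64))
    @settings(max_examples=50, deadline=None)
    def test_crop_at_offset_recovers_original(self, n, extra):
        x = np.arange(2 * n, dtype=float).reshape(2, n)
        y = np.resize(np.array([0, 1, -1], dtype=np.int8), n)
        px, py, off = center_pad_arrays(x, y, n + extra)
        np.testing.assert_array_equal(px[:, off : off + n], x)
        np.testing.assert_array_equal(py[off : off + n], y)


class TestDownsample:
    @pytest.mark.parametrize(
        "x,factor,expected",
        [([1, 3, 5, 7], 2, [2, 6]),
         ([1, 2, 3, 4, 5, 6, 7, 8], 8, [4.5]),
         ([1, 2, 3], 1, [1, 2, 3])],
    )
    def test_block_averaging(self, x, factor, expected):
        np.testing.assert_allclose(
            downsample_average(np.array(x, float), factor), expected
        )

    def test_factor_below_one_rejected(self):
        with pytest.raises(ParameterError):
            downsample_average(np.arange(4.0), 0)

    @given(st.integers(1, 6), st.integers(1, 8))
    @settings(max_examples=40, deadline=None)
    def test_global_mean_conserved_when_divisible(self, blocks, factor):
        rng = np.random.default_rng(blocks * 10 + factor)
        x = rng.normal(size=(3, blocks * factor))
        reduced = downsample_average(x, factor)
        np.testing.assert_allclose(reduced.mean(axis=1), x.mean(axis=1))

    @pytest.mark.parametrize(
        "block,expected",
        [([0, 1], 1), ([0, -1], -1), ([0, 0], 0), ([1, -1], 1)],
    )
    def test_label_vote_precedence_arousal_over_nonscored(self, block, expected):
        assert downsample_labels(np.array(block, np.int8), 2)[0] == expected

    def test_label_edge_padding_for_ragged_length(self):
        y = np.array([0, 0, 1], np.int8)
        np.testing.assert_array_equal(downsample_labels(y, 2), [0, 1])


class TestSplitRecords:
    def test_paper_fractions_give_exact_sizes(self):
        ids = [f"r{i}" for i in range(100)]
        part = split_records(ids, (0.60, 0.15, 0.25), seed=1)
        assert (len(part.train_ids), len(part.val_ids), len(part.test_ids)) \
            == (60, 15, 25)

    def test_reproducible_and_partitioning(self):
        ids = [f"r{i}" for i in range(37)]
        a = split_records(ids, seed=5)
        b = split_records(ids, seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        combined = a.all_ids()
        assert sorted(combined) == sorted(ids)
        assert len(set(a.train_ids) & set(a.val_ids)) == 0
        assert len(set(a.train_ids) & set(a.test_ids)) == 0

    def test_empty_ids_rejected(self):
        with pytest.raises(ParameterError):
            split_records([])

    @given(st.integers(1, 200))
    @settings(max_examples=40, deadline=None)
    def test_largest_remainder_sizes_sum_to_n(self, n):
        part = split_records([str(i) for i in range(n)], seed=0)
        assert len(part.all_ids()) == n
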