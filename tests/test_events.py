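"""AER codec, raster binning, and the synthetic event generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lsmkit import (
    EventStream,
    SyntheticConfig,
    bin_event_counts,
    bin_to_raster,
    read_aer,
    read_dataset,
    synth_generate,
    write_aer,
    write_dataset,
)


def pack_record(x, y, t, p):
    """Independent bit-packing of one 5-byte record, straight off the format."""
    return bytes(
        [x, y, (p << 7) | ((t >> 16) & 0x7F), (t >> 8) & 0xFF, t & 0xFF]
    )


class TestAERCodec:
    def test_empty_input(self):
        stream = read_aer(b"")
        assert len(stream) == 0
        assert write_aer(stream) == b""

    def test_hand_packed_record(self):
        stream = read_aer(pack_record(5, 7, 1000, 1))
        assert (stream.x[0], stream.y[0], stream.t[0], stream.p[0]) == (5, 7, 1000, 1)

    def test_polarity_and_high_timestamp_bits(self):
        t = (1 << 23) - 1  # all 23 timestamp bits set
        stream = read_aer(pack_record(33, 0, t, 0))
        assert stream.t[0] == t and stream.p[0] == 0

    def test_trailing_partial_record_names_offset(self):
        with pytest.raises(ValueError, match="offset 10"):
            read_aer(b"\x00" * 12)

    @given(
        n=st.integers(0, 40),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_round_trip_random_streams(self, n, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.integers(0, 1 << 23, n))
        stream = EventStream(
            x=rng.integers(0, 34, n),
            y=rng.integers(0, 34, n),
            t=t,
            p=rng.integers(0, 2, n),
        )
        data = write_aer(stream)
        assert read_aer(data) == stream
        assert write_aer(read_aer(data)) == data

    def test_timestamp_overflow_rejected(self):
        stream = EventStream(x=[0], y=[0], t=[1 << 23], p=[1])
        with pytest.raises(ValueError, match="23-bit"):
            write_aer(stream)


class TestEventStreamValidation:
    def test_out_of_bounds_coordinates_rejected(self):
        with pytest.raises(ValueError):
            EventStream(x=[40], y=[0], t=[0], p=[1], width=34, height=34)

    def test_decreasing_timestamps_rejected(self):
        with pytest.raises(ValueError):
            EventStream(x=[0, 0], y=[0, 0], t=[5, 4], p=[0, 0])


class TestBinning:
    def test_single_event_at_origin(self):
        stream = EventStream(x=[0], y=[0], t=[0], p=[0], width=4, height=4)
        raster, dropped = bin_to_raster(stream, T=5, window_ms=10)
        assert dropped == 0
        assert raster.data[0, 0] == 1
        assert raster.data.sum() == 1

    def test_bin_boundary_is_half_open(self):
        # an event exactly at window/T lands in bin 1, not bin 0
        stream = EventStream(x=[1], y=[2], t=[2000], p=[1], width=4, height=4)
        raster, _ = bin_to_raster(stream, T=5, window_ms=10)  # bins of 2 ms
        ch = 1 * 16 + 2 * 4 + 1
        assert raster.data[1, ch] == 1
        assert raster.data[0, ch] == 0

    def test_events_beyond_window_dropped_and_counted(self):
        stream = EventStream(x=[0, 1], y=[0, 0], t=[0, 60000], p=[0, 0], width=4, height=4)
        raster, dropped = bin_to_raster(stream, T=5, window_ms=10)
        assert dropped == 1
        assert raster.data.sum() == 1

    def test_count_conservation_against_per_event_oracle(self, rng):
        H = W = 6
        n = 300
        stream = EventStream(
            x=rng.integers(0, W, n),
            y=rng.integers(0, H, n),
            t=np.sort(rng.integers(0, 50000, n)),
            p=rng.integers(0, 2, n),
            width=W,
            height=H,
        )
        T, window = 10, 50.0
        counts, dropped = bin_event_counts(stream, T, window)
        assert counts.sum() + dropped == n
        # independent per-event placement
        expected = np.zeros((T, 2 * H * W), dtype=int)
        for x, y, t, p in zip(stream.x, stream.y, stream.t, stream.p):
            b = int(t // (window * 1000 / T))
            if b < T:
                expected[b, p * H * W + y * W + x] += 1
        np.testing.assert_array_equal(counts, expected)
        # binarized raster is the support of the count raster
        raster, _ = bin_to_raster(stream, T, window)
        np.testing.assert_array_equal(raster.data, (expected > 0).astype(np.uint8))

    def test_channel_flattening_is_a_bijection(self):
        H, W = 3, 5
        seen = set()
        for p in (0, 1):
            for y in range(H):
                for x in range(W):
                    seen.add(p * H * W + y * W + x)
        assert seen == set(range(2 * H * W))


class TestSyntheticGenerator:
    def test_seeded_determinism(self, tiny_synth_config):
        a = synth_generate(tiny_synth_config)
        b = synth_generate(tiny_synth_config)
        assert len(a) == len(b) == 4 * 3
        for (sa, la), (sb, lb) in zip(a, b):
            assert la == lb and sa == sb

    def test_zero_rates_give_empty_streams(self, tiny_synth_config):
        from dataclasses import replace

        cfg = replace(tiny_synth_config, base_rate=0.0, noise_rate=0.0)
        for stream, _ in synth_generate(cfg):
            assert len(stream) == 0

    def test_streams_are_valid_and_in_bounds(self, tiny_synth_config):
        for stream, label in synth_generate(tiny_synth_config):
            assert 0 <= label < 4
            assert stream.width == 8 and stream.height == 8
            if len(stream):
                assert stream.t[-1] < tiny_synth_config.duration_ms * 1000
                assert (np.diff(stream.t) >= 0).all()

    def test_classes_have_distinct_spatial_signatures(self, tiny_synth_config):
        # class 0 sweeps left-to-right, class 1 right-to-left: early ON events
        # of class 0 sit at low x, of class 1 at high x
        streams = synth_generate(tiny_synth_config)
        early = tiny_synth_config.duration_ms * 1000 // 4
        mean_x = {}
        for stream, label in streams:
            if label in (0, 1):
                sel = (stream.t < early) & (stream.p == 1)
                if sel.any():
                    mean_x.setdefault(label, []).append(stream.x[sel].mean())
        assert np.mean(mean_x[0]) < np.mean(mean_x[1])

    def test_dataset_directory_round_trip(self, tiny_synth_config, tmp_path):
        samples = synth_generate(tiny_synth_config)
        write_dataset(tmp_path / "train", samples)
        loaded = read_dataset(tmp_path / "train", width=8, height=8)
        assert len(loaded) == len(samples)
        for (sa, la), (sb, lb) in zip(samples, loaded):
            assert la == lb and sa == sb

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_classes=1)
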