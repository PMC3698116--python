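"""Marker and watermark resynchronisation codes."""

import numpy as np
import pytest

from biocode import resync_codes as rc


def bits(rng, n):
    return rng.integers(0, 2, size=n, dtype=np.uint8)


class TestMarker:
    cfg = rc.MarkerCodeConfig(pilot="001", block_length=99)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            rc.MarkerCodeConfig(pilot="0")
        with pytest.raises(ValueError):
            rc.MarkerCodeConfig(pilot="001", block_length=3)

    def test_pilot_placement_and_overhead(self, rng):
        m = bits(rng, 2 * 99)
        enc = rc.marker_encode(m, self.cfg)
        assert len(enc) == 2 * 99 + 2 * 3
        assert list(enc[99:102]) == [0, 0, 1]
        assert list(enc[201:204]) == [0, 0, 1]
        # ceil-block overhead for partial final block
        enc2 = rc.marker_encode(bits(rng, 150), self.cfg)
        assert len(enc2) == 150 + 2 * 3

    def test_empty_message(self):
        assert rc.marker_encode([], self.cfg).size == 0
        assert rc.marker_decode([], self.cfg).size == 0

    def test_roundtrip_no_channel(self, rng):
        for n in (1, 98, 99, 100, 500):
            m = bits(rng, n)
            assert np.array_equal(rc.marker_decode(rc.marker_encode(m, self.cfg), self.cfg)[:n], m)

    def test_deletion_realigns_downstream_blocks(self, rng):
        m = bits(rng, 5 * 99)
        enc = rc.marker_encode(m, self.cfg)
        received = np.delete(enc, 150)  # mid second block
        dec = rc.marker_decode(received, self.cfg, len(m))
        assert len(dec) == len(m)
        # all blocks after the damaged one are bit-exact
        assert np.array_equal(dec[2 * 99 :], m[2 * 99 :])
        # first block untouched
        assert np.array_equal(dec[:99], m[:99])

    def test_insertion_realigns(self, rng):
        m = bits(rng, 4 * 99)
        enc = rc.marker_encode(m, self.cfg)
        received = np.insert(enc, 30, 1)
        dec = rc.marker_decode(received, self.cfg, len(m))
        assert len(dec) == len(m)
        assert np.array_equal(dec[99:], m[99:])

    def test_shifted_pilot_inferred_as_deletion(self):
        """A 001 pilot observed one position early triggers mid-block insertion."""
        cfg = rc.MarkerCodeConfig(pilot="001", block_length=8)
        m = np.array([1, 1, 1, 1, 0, 1, 1, 1], dtype=np.uint8)
        enc = rc.marker_encode(m, cfg)
        received = np.delete(enc, 2)  # deletion inside the block
        dec = rc.marker_decode(received, cfg, 8)
        assert len(dec) == 8  # frame length restored


class TestWatermark:
    cfg = rc.WatermarkCodeConfig(sparsity=0.5, seed=7)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            rc.WatermarkCodeConfig(sparsity=0.0)

    def test_sparse_layout(self):
        pos = self.cfg.sparse_positions(4)
        assert list(pos) == [0, 2, 4, 6]
        assert self.cfg.sparse_length(4) == 7

    def test_encode_is_xor_with_watermark(self, rng):
        m = bits(rng, 40)
        w = self.cfg.watermark(40)
        enc = rc.watermark_encode(m, self.cfg)
        assert np.array_equal(enc[self.cfg.sparse_positions(40)] ^ w[self.cfg.sparse_positions(40)], m)
        # zero-inserted positions carry the watermark itself
        mask = np.ones(len(w), dtype=bool)
        mask[self.cfg.sparse_positions(40)] = False
        assert np.array_equal(enc[mask], w[mask])

    def test_full_sparsity_zero_watermark_is_identity(self, rng):
        cfg = rc.WatermarkCodeConfig(sparsity=1.0, seed=3)
        m = bits(rng, 64)
        enc = rc.watermark_encode(m, cfg)
        assert np.array_equal(enc ^ cfg.watermark(64), m)

    def test_roundtrip_no_channel(self, rng):
        for n in (1, 17, 500, 3000):
            m = bits(rng, n)
            dec = rc.watermark_decode(rc.watermark_encode(m, self.cfg), n, self.cfg)
            assert np.array_equal(dec, m)

    def test_deletion_plus_flips_restores_bitframe(self, rng):
        m = bits(rng, 1000)
        enc = rc.watermark_encode(m, self.cfg)
        damaged = np.delete(enc, 777)
        for i in (5, 300, 1500):
            damaged[i] ^= 1
        dec = rc.watermark_decode(damaged, 1000, self.cfg)
        assert len(dec) == 1000
        assert int((dec != m).sum()) <= 6  # flips stay local, frame restored

    def test_all_flips_keeps_identity_alignment(self, rng):
        """Without indels the alignment is the identity path: output length
        equals the message length and errors are exactly the flips that hit
        message positions."""
        m = bits(rng, 1000)
        enc = rc.watermark_encode(m, self.cfg)
        flip = rng.choice(len(enc), size=200, replace=False)
        enc[flip] ^= 1
        dec = rc.watermark_decode(enc, 1000, self.cfg)
        assert len(dec) == 1000
        expected_errors = int(np.isin(flip, self.cfg.sparse_positions(1000)).sum())
        assert int((dec != m).sum()) == expected_errors

    def test_alignment_output_always_watermark_frame_length(self, rng):
        """The realigned vector always has the watermark's length: gaps are
        attributed to the received side only."""
        w = self.cfg.watermark(300)
        for delta in (-20, -3, 0, 3, 20):
            received = bits(rng, len(w) + delta)
            aligned = rc._banded_align(received, w)
            assert len(aligned) == len(w)

    def test_empty_message(self):
        assert rc.watermark_encode([], self.cfg).size == 0
        assert rc.watermark_decode([], 0, self.cfg).size == 0
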