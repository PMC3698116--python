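"""Message-bitframe resynchronisation: marker codes and simplified
watermark codes.

Variable-length decoding under substitution mutations can insert or drop
message bits, after which every downstream bit index is shifted.  Two
outer codes repair the bitframe:

* **Marker codes** insert a fixed pilot pattern after every message block.
  A pilot found shifted by one position reveals an insertion or deletion in
  the preceding block, which is undone by deleting/inserting a bit at the
  block midpoint.  One desynchronisation event per block is correctable;
  flips inside the block are not repaired.

* **Watermark codes** sparsify the message (zeros inserted at shared
  positions), XOR it with a shared pseudo-random watermark ``w`` and embed
  the result.  The decoder globally aligns the received vector against
  ``w`` under edit distance -- gaps are attributed to the received side
  only, since ``w`` itself cannot desynchronise -- keeping the received
  values at mismatch columns (flips are channel noise to be resolved by an
  outer substitution code).  This is the simplified alignment variant;
  probabilistic forward-backward decoding is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Mismatches are expected channel flips and must be much cheaper than
# indels: a spurious one-position shift only pays off when it avoids
# >= 2*gap/mismatch consecutive mismatches, which at this ratio requires a
# ~20-position chance run (probability ~4**-20 per site) in random binary
# data.  A true deletion, by contrast, flips ~half of all downstream
# comparisons and amortises the gap cost within ~20 bits.  Integer costs
# keep the dynamic programme exact, so ties genuinely break toward the
# diagonal.
_MISMATCH = 1
_GAP = 10


@dataclass(frozen=True)
class MarkerCodeConfig:
    pilot: str = "001"
    block_length: int = 99

    def __post_init__(self):
        if len(self.pilot) < 2 or set(self.pilot) - {"0", "1"}:
            raise ValueError("pilot must be a bit pattern of length >= 2")
        if self.block_length <= len(self.pilot):
            raise ValueError("block_length must exceed the pilot length")


def marker_encode(message, cfg: MarkerCodeConfig = MarkerCodeConfig()) -> np.ndarray:
    """Insert the pilot after every ``block_length`` message bits (and after
    a trailing partial block)."""
    m = np.asarray(message, dtype=np.uint8)
    pilot = np.array([int(b) for b in cfg.pilot], dtype=np.uint8)
    chunks = []
    for start in range(0, len(m), cfg.block_length):
        chunks.append(m[start : start + cfg.block_length])
        chunks.append(pilot)
    return np.concatenate(chunks) if chunks else m.copy()


def marker_decode(
    received,
    cfg: MarkerCodeConfig = MarkerCodeConfig(),
    n_message: int | None = None,
) -> np.ndarray:
    """Strip pilots, realigning once per block when a pilot appears shifted.

    A pilot found one position early means a bit was dropped in the
    preceding block: a zero is inserted at the block midpoint.  One position
    late means a spurious bit: the midpoint bit is removed.  ``n_message``
    (the out-of-band message length) fixes the expected block structure;
    without it the trailing partial block is inferred from the stream
    length, which is ambiguous when desynchronisation hit the final block.
    """
    r = np.asarray(received, dtype=np.uint8)
    pilot = np.array([int(b) for b in cfg.pilot], dtype=np.uint8)
    L, B = len(pilot), cfg.block_length
    if n_message is None:
        n_blocks = max(1, round(len(r) / (B + L)))
        n_message = max(0, len(r) - n_blocks * L)
    sizes = [B] * (n_message // B)
    if n_message % B or n_message == 0:
        sizes.append(n_message % B)
    out: list[np.ndarray] = []
    pos = 0
    for s in sizes:
        block = r[pos : pos + s]
        here = r[pos + s : pos + s + L]
        early = r[pos + s - 1 : pos + s - 1 + L] if pos + s >= 1 else here[:0]
        late = r[pos + s + 1 : pos + s + 1 + L]
        if len(here) == L and np.array_equal(here, pilot):
            out.append(block)
            pos += s + L
        elif len(early) == L and np.array_equal(early, pilot) and s >= 1:
            short = r[pos : pos + s - 1]
            mid = len(short) // 2
            out.append(np.insert(short, mid, 0))
            pos += s - 1 + L
        elif len(late) == L and np.array_equal(late, pilot):
            long = r[pos : pos + s + 1]
            mid = len(long) // 2
            out.append(np.delete(long, mid))
            pos += s + 1 + L
        else:
            # uncorrectable here: keep bits, assume nominal spacing
            out.append(block)
            pos += s + L
    decoded = np.concatenate(out) if out else np.array([], dtype=np.uint8)
    return decoded[:n_message]


@dataclass(frozen=True)
class WatermarkCodeConfig:
    """Shared watermark parameters.

    ``sparsity`` is the fraction of embedded positions carrying message
    bits; message bit ``k`` sits at position ``floor(k / sparsity)``.  The
    watermark vector is derived from ``seed`` and the sparse length, so
    encoder and decoder need only share the config and the message length.
    """

    sparsity: float = 0.5
    seed: int = 7

    def __post_init__(self):
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must be in (0, 1]")

    def sparse_positions(self, n_message: int) -> np.ndarray:
        return (np.arange(n_message) / self.sparsity).astype(np.intp)

    def sparse_length(self, n_message: int) -> int:
        if n_message == 0:
            return 0
        return int(self.sparse_positions(n_message)[-1]) + 1

    def watermark(self, n_message: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        return rng.integers(0, 2, size=self.sparse_length(n_message), dtype=np.uint8)


def watermark_encode(message, cfg: WatermarkCodeConfig = WatermarkCodeConfig()) -> np.ndarray:
    m = np.asarray(message, dtype=np.uint8)
    w = cfg.watermark(len(m))
    sparse = np.zeros_like(w)
    sparse[cfg.sparse_positions(len(m))] = m
    return sparse ^ w


def _banded_align(received: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Global edit-distance alignment of ``received`` onto the frame of ``w``.

    Returns a vector of length ``len(w)``: received values at match and
    mismatch columns, watermark values where the received stream had a
    deletion.  Ties prefer the diagonal, so an indel-free channel yields the
    identity path.  The band is sized from the length difference plus slack;
    the dynamic programme is O(len(w) * band).
    """
    n, m = len(w), len(received)
    if n == 0:
        return w.copy()
    if m == 0:
        return w.copy()
    half = abs(m - n) + 32
    width = 2 * half + 1
    # sentinel far above any legitimate path cost ((n+m)*_GAP) yet safe to
    # add without int64 overflow
    INF = np.int64(10**12)
    # Band follows the straight line from (0,0) to (n,m); cell (i,k) holds the
    # cost of aligning received[:j] with w[:i], j = centers[i] - half + k.
    centers = np.rint(np.linspace(0, m, n + 1)).astype(int)
    prev_ptr = np.zeros((n + 1, width), dtype=np.uint8)  # 0 diag, 1 w-only, 2 received-only
    cols0 = np.arange(width) + centers[0] - half
    prev = np.where((cols0 >= 0) & (cols0 <= m), cols0.clip(0) * _GAP, INF).astype(np.int64)
    prev_ptr[0] = 2
    rec = received.astype(np.int16)
    wv = w.astype(np.int16)
    ar = np.arange(width)
    for i in range(1, n + 1):
        ji = centers[i] - half
        cols = ar + ji
        valid = (cols >= 0) & (cols <= m)
        shift = ji - (centers[i - 1] - half)

        def take(row, offset):
            idx = ar + shift + offset
            ok = (idx >= 0) & (idx < width)
            out = np.full(width, INF, dtype=np.int64)
            out[ok] = row[idx[ok]]
            return out

        up = take(prev, 0)       # (i-1, j): received bit deleted (gap vs w char)
        diag = take(prev, -1)    # (i-1, j-1): consume both
        mis = np.full(width, INF, dtype=np.int64)
        jj = cols - 1
        okj = (jj >= 0) & (jj < m)
        mis[okj] = np.where(rec[jj[okj]] == wv[i - 1], 0, _MISMATCH)
        cur = diag + mis
        ptr = np.zeros(width, dtype=np.uint8)
        better = up + _GAP < cur
        cur = np.where(better, up + _GAP, cur)
        ptr[better] = 1
        cur[~valid] = INF
        # spurious received bits: min-plus prefix scan resolves whole chains
        chain = np.minimum.accumulate(cur - ar * _GAP) + ar * _GAP
        ins = chain < cur
        cur = np.where(ins, chain, cur)
        ptr[ins] = 2
        cur[~valid] = INF
        prev = cur
        prev_ptr[i] = ptr
    # traceback from (n, m)
    out = np.empty(n, dtype=np.uint8)
    i, j = n, m
    while i > 0:
        k = j - (centers[i] - half)
        if not 0 <= k < width:  # fell off band: fill rest from watermark
            out[:i] = w[:i]
            break
        p = prev_ptr[i, k]
        if p == 0:
            out[i - 1] = received[j - 1] if j >= 1 else w[i - 1]
            i -= 1
            j -= 1
        elif p == 1:
            out[i - 1] = w[i - 1]  # received bit deleted here
            i -= 1
        else:
            j -= 1  # spurious received bit, drop it
            if j < 0:
                out[:i] = w[:i]
                break
    return out


def watermark_decode(
    received, n_message: int, cfg: WatermarkCodeConfig = WatermarkCodeConfig()
) -> np.ndarray:
    """Realign the received vector against the watermark and recover the
    message bits.

    ``n_message`` is the true message length (carried out-of-band); it fixes
    the watermark length and the sparse positions.
    """
    r = np.asarray(received, dtype=np.uint8)
    w = cfg.watermark(n_message)
    aligned = _banded_align(r, w)
    positions = cfg.sparse_positions(n_message)
    return (aligned[positions] ^ w[positions]).astype(np.uint8)
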