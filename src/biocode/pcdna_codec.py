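"""Protein-coding DNA codecs: static BCE and the dynamic codon-count
preserving codec.

Both codecs replace codons synonymously, so the translated protein
(primary structure) is untouched.  Binary Codon Equivalency (BCE) uses one
static graduated codebook per amino acid, built over the full synonymous
family in canonical (alphabetical) order.  The dynamic codec additionally
preserves the exact codon histogram of the host sequence: each codon may
be used only as often as it occurred originally, and when a codon's budget
is spent it is removed from its family's codebook, which is rebuilt in a
graduated fashion.  Because the per-family budget equals the number of
remaining positions for that amino acid, the encoder can never stall.

The decoder rebuilds the same dynamic tables from the received sequence's
own histogram -- identical to the encoder's when no mutation occurred.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genetic_code import CODON_TO_AA, SYNONYMOUS, translate
from .graduated_mapping import (
    Codebook,
    build_codebook,
    decode_symbol,
    encode_next,
    key_permutation,
)


def _family_order(aa: str, key: int | None) -> tuple[str, ...]:
    codons = SYNONYMOUS[aa]
    perm = key_permutation(key, "pc:" + aa, len(codons))
    return tuple(codons[i] for i in perm)


def _static_books(key: int | None) -> dict[str, Codebook]:
    return {aa: build_codebook(_family_order(aa, key)) for aa in SYNONYMOUS}


@dataclass
class PcEncodeResult:
    codons: list[str]
    bits_embedded: int


def bce_encode(message: Sequence[int], codons: Sequence[str], key: int | None = None) -> PcEncodeResult:
    """Static synonymous-substitution embedding.

    Every position draws from the full synonymous family of its amino acid;
    single-codon families (Met, Trp) are forced and carry no bits.  Once the
    message is exhausted, remaining positions encode zero padding.
    """
    bits = np.asarray(message, dtype=np.uint8)
    books = _static_books(key)
    amino = translate(codons)
    out: list[str] = []
    pos = 0
    for aa in amino:
        symbol, consumed = encode_next(books[aa], bits, pos)
        out.append(symbol)
        pos += consumed
    return PcEncodeResult(out, min(pos, len(bits)))


def bce_decode(codons: Sequence[str], key: int | None = None) -> np.ndarray:
    """Inverse of :func:`bce_encode`; every codon is decodable statically."""
    books = _static_books(key)
    bits: list[int] = []
    for codon in codons:
        aa = CODON_TO_AA[codon]
        bits.extend(int(b) for b in decode_symbol(books[aa], codon))
    return np.array(bits, dtype=np.uint8)


@dataclass
class PcdnaCodecState:
    """Dynamic per-amino-acid tables plus the remaining codon budget."""

    families: dict[str, tuple[str, ...]]
    books: dict[str, Codebook]
    counts: Counter = field(default_factory=Counter)

    def spend(self, codon: str) -> None:
        aa = CODON_TO_AA[codon]
        self.counts[codon] -= 1
        if self.counts[codon] == 0:
            remaining = tuple(c for c in self.families[aa] if c != codon)
            self.families[aa] = remaining
            self.books[aa] = (
                build_codebook(remaining) if remaining else Codebook((), ())
            )


def init_state(reference: Sequence[str], key: int | None = None) -> PcdnaCodecState:
    """Build dynamic tables restricted to codon types present in ``reference``.

    Families keep the key-permuted canonical order of the full synonymous
    set, filtered to present codons; a reference using all 64 codons
    reproduces the static tables.
    """
    counts = Counter(reference)
    families: dict[str, tuple[str, ...]] = {}
    books: dict[str, Codebook] = {}
    for aa in SYNONYMOUS:
        present = tuple(c for c in _family_order(aa, key) if counts[c] > 0)
        families[aa] = present
        books[aa] = build_codebook(present) if present else Codebook((), ())
    return PcdnaCodecState(families, books, counts)


def biocode_pc_encode(
    message: Sequence[int], codons: Sequence[str], key: int | None = None
) -> PcEncodeResult:
    """Codon-count preserving embedding.

    The output translates to the same protein as ``codons`` and has exactly
    the same codon multiset.  After message exhaustion each remaining
    position takes the first remaining codon of its family (a deterministic
    fill that the decoder discards via the out-of-band message length).
    """
    bits = np.asarray(message, dtype=np.uint8)
    state = init_state(codons, key)
    amino = translate(codons)
    out: list[str] = []
    pos = 0
    for aa in amino:
        book = state.books[aa]
        if pos < len(bits):
            symbol, consumed = encode_next(book, bits, pos)
        else:
            symbol, consumed = book.symbols[0], 0
        out.append(symbol)
        pos += consumed
        state.spend(symbol)
    return PcEncodeResult(out, min(pos, len(bits)))


def biocode_pc_decode(
    codons: Sequence[str], key: int | None = None
) -> tuple[np.ndarray, list[int]]:
    """Replay the dynamic tables from the received sequence's histogram.

    Codon-count preservation makes the received histogram equal the
    encoder's initial budget when no mutation occurred, so the table
    evolution replays exactly.  A codon absent from its family's current
    table (spent budget or non-synonymous corruption) is flagged and
    contributes no bits.
    """
    state = init_state(codons, key)
    bits: list[int] = []
    flags: list[int] = []
    for i, codon in enumerate(codons):
        aa = CODON_TO_AA[codon]
        if codon in state.families[aa]:
            bits.extend(int(b) for b in decode_symbol(state.books[aa], codon))
            state.spend(codon)
        else:
            flags.append(i)
    return np.array(bits, dtype=np.uint8), flags
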