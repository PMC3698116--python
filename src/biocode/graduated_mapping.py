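"""Graduated prefix-free bit<->symbol codebooks.

A graduated mapping assigns ``mu`` symbols to binary strings of lengths
``l = floor(log2 mu)`` and ``l+1`` such that the codeword set is prefix
free and every uniform random bit stream selects a unique symbol.  With
``n_short = 2**(l+1) - mu`` codewords of length ``l`` and
``2*(mu - 2**l)`` of length ``l+1``, the average codeword length under
uniform bits is the graduated rate R(mu) (see :mod:`biocode.rate_analysis`).

The degenerate single-symbol codebook maps its symbol to the empty
codeword: forced symbols carry zero bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Hashable, Sequence

import numpy as np


def key_permutation(key: int | None, label: str, n: int) -> list[int]:
    """Deterministic permutation of ``range(n)`` for a labelled symbol set.

    ``key is None`` yields the identity, reproducing the published tables.
    Otherwise the permutation is drawn from a generator seeded jointly by
    the integer key and the label, so encoder and decoder agree without
    sharing state.
    """
    if key is None:
        return list(range(n))
    digest = sum((i + 1) * b for i, b in enumerate(label.encode())) % (2**31)
    rng = np.random.default_rng([int(key) % (2**31), digest])
    return [int(i) for i in rng.permutation(n)]


def _codewords(mu: int) -> list[str]:
    if mu < 1:
        raise ValueError("codebook needs at least one symbol")
    if mu == 1:
        return [""]
    l = mu.bit_length() - 1
    n_short = 2 ** (l + 1) - mu
    words = [format(i, f"0{l}b") for i in range(n_short)]
    for i in range(n_short, 2**l):
        stem = format(i, f"0{l}b")
        words += [stem + "0", stem + "1"]
    return words


@dataclass(frozen=True)
class Codebook:
    """Prefix-free graduated mapping between symbols and bit strings."""

    symbols: tuple[Hashable, ...]
    codewords: tuple[str, ...]

    @property
    def mu(self) -> int:
        return len(self.symbols)

    @property
    def min_length(self) -> int:
        return self.mu.bit_length() - 1

    def codeword_for(self, symbol) -> str:
        try:
            return self.codewords[self.symbols.index(symbol)]
        except ValueError:
            raise KeyError(f"symbol {symbol!r} not in codebook") from None

    def symbol_probabilities(self) -> list[Fraction]:
        """Usage probability of each symbol under uniform random bits."""
        return [Fraction(1, 2 ** len(w)) if w else Fraction(1) for w in self.codewords]

    def expected_length(self) -> Fraction:
        """Average codeword length under uniform bits (equals R(mu))."""
        return sum(
            (p * len(w) for p, w in zip(self.symbol_probabilities(), self.codewords)),
            start=Fraction(0),
        )


def build_codebook(symbols: Sequence[Hashable]) -> Codebook:
    """Construct the graduated codebook over ``symbols`` in the given order.

    The first ``2**(l+1) - mu`` symbols receive the ``l``-bit strings in
    ascending binary order; each remaining ``l``-bit string is split into a
    "0"/"1"-extended pair assigned to the remaining symbols in order.
    """
    symbols = tuple(symbols)
    if len(set(symbols)) != len(symbols):
        raise ValueError("symbols must be distinct")
    return Codebook(symbols, tuple(_codewords(len(symbols))))


class TailUnderflow(Exception):
    """Raised when the remaining bit stream is shorter than every matching
    codeword and zero-padding is disabled."""


def encode_next(
    codebook: Codebook,
    bits: Sequence[int],
    pos: int = 0,
    pad: bool = True,
):
    """Match the upcoming bits against the codebook.

    Returns ``(symbol, bits_consumed)`` where ``bits_consumed`` counts true
    message bits (excluding any zero padding applied at the stream tail).
    Prefix-freeness guarantees a unique match; a single-symbol codebook
    consumes nothing.
    """
    if codebook.mu == 1:
        return codebook.symbols[0], 0
    for symbol, word in zip(codebook.symbols, codebook.codewords):
        tail = bits[pos : pos + len(word)]
        padded = "".join(str(int(b)) for b in tail) + "0" * (len(word) - len(tail))
        if len(tail) < len(word) and not pad:
            continue
        if padded == word:
            return symbol, min(len(word), max(0, len(bits) - pos))
    raise TailUnderflow("bit stream exhausted before any codeword matched")


def decode_symbol(codebook: Codebook, symbol) -> str:
    """Inverse lookup: the bit string encoded by ``symbol``."""
    return codebook.codeword_for(symbol)


def remove_symbol(codebook: Codebook, symbol) -> Codebook:
    """Drop ``symbol`` and rebuild the graduated mapping over the survivors.

    Removing the last symbol yields an empty codebook, which is legal only
    as bookkeeping (a fully spent codon family).
    """
    if symbol not in codebook.symbols:
        raise KeyError(f"symbol {symbol!r} not in codebook")
    rest = tuple(s for s in codebook.symbols if s != symbol)
    if not rest:
        return Codebook((), ())
    return build_codebook(rest)
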