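"""Start-codon-safe data embedding in non-coding DNA.

The encoder walks the output sequence left to right, keying a graduated
codebook on the trailing dinucleotide ``d = [y[i-2], y[i-1]]``.  Whenever
``d`` could prefix a start codon (sense ATG/CTG/TTG or their antisense
images CAT/CAG/CAA on the opposite strand), the choice of the next base is
restricted so that no start codon can arise in any of the six reading
frames.  The restriction table (eukaryote policy):

    ========  =============  =========
    trailing  allowed bases  codewords
    ========  =============  =========
    AT        A T C          0 10 11
    CT        A T C          0 10 11
    TT        A T C          0 10 11
    CA        C              (forced)
    other     A T C G        00 01 10 11
    ========  =============  =========

Decoding replays the same state machine on the received sequence; a base
outside the state's allowed set can only be produced by mutation and is
flagged rather than decoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genetic_code import StartCodonPolicy, validate_sequence
from .graduated_mapping import Codebook, build_codebook, decode_symbol, encode_next, key_permutation

#: allowed next bases per special trailing dinucleotide (table order)
_EUK_RESTRICTED = {"AT": "ATC", "CT": "ATC", "TT": "ATC", "CA": "C"}
_FREE = "ATCG"


def restricted_set(d: str, policy: StartCodonPolicy | None = None) -> tuple[str, ...]:
    """Allowed next bases after trailing dinucleotide ``d``.

    Derived from the policy's forbidden triplets: a base is excluded when
    ``d + base`` is a forbidden triplet.  For the default eukaryote policy
    this reproduces the published table above.
    """
    if policy is None or policy.organism_class == "eukaryote":
        return tuple(_EUK_RESTRICTED.get(d, _FREE))
    forbidden = set(policy.forbidden_triplets)
    return tuple(b for b in _FREE if d + b not in forbidden)


def _codebook_for(d: str, policy, key) -> Codebook:
    bases = restricted_set(d, policy)
    label = "nc:" + d if d in _EUK_RESTRICTED else "nc:free"
    perm = key_permutation(key, label, len(bases))
    return build_codebook(tuple(bases[i] for i in perm))


@dataclass
class NcdnaEncodeResult:
    """Outcome of an ncDNA embedding run."""

    sequence: str
    bits_embedded: int
    per_position_set_sizes: list[int] = field(default_factory=list)


def _initial_state(left_flank: str | None) -> str:
    if left_flank and len(left_flank) >= 2:
        return validate_sequence(left_flank)[-2:]
    if left_flank and len(left_flank) == 1:
        return "G" + validate_sequence(left_flank)
    return "GG"  # virtual context: never triggers a restriction


def _flank_forbidden(d: str, right_flank: str, policy) -> set[str]:
    """Bases at the final position that would complete a forbidden triplet
    together with the first bases of the right flank.

    Only the last emitted position can straddle the boundary in a way that
    is decidable at emission time: the two candidate windows are
    ``d[1] + base + flank[0]`` and ``base + flank[:2]``.
    """
    pol = policy or StartCodonPolicy.eukaryote()
    forbidden = set(pol.forbidden_triplets)
    r = validate_sequence(right_flank)[:2]
    out = set()
    for b in _FREE:
        if r and d[1] + b + r[0] in forbidden:
            out.add(b)
        if len(r) >= 2 and b + r in forbidden:
            out.add(b)
    return out


def encode(
    message: Sequence[int],
    target_length: int | None = None,
    *,
    flanks: tuple[str | None, str | None] | None = None,
    key: int | None = None,
    policy: StartCodonPolicy | None = None,
    trace: bool = False,
) -> NcdnaEncodeResult:
    """Embed ``message`` bits into a start-codon-free base sequence.

    With ``target_length`` set, exactly that many bases are produced; if the
    message runs out first, the remainder is encoded from zero padding.  With
    ``target_length=None`` the sequence grows until the whole message has
    been consumed.  ``bits_embedded`` counts true message bits only.
    """
    bits = np.asarray(message, dtype=np.uint8)
    if target_length is not None and target_length < 1:
        raise ValueError("target_length must be >= 1")
    left = right = None
    if flanks is not None:
        left, right = flanks
    state = _initial_state(left)
    out: list[str] = []
    sizes: list[int] = []
    pos = 0
    books: dict[str, Codebook] = {}
    while True:
        if target_length is not None and len(out) >= target_length:
            break
        if target_length is None and pos >= len(bits):
            break
        d = state
        book = books.get(d)
        if book is None:
            book = books[d] = _codebook_for(d, policy, key)
        if right is not None and target_length is not None and len(out) == target_length - 1:
            banned = _flank_forbidden(d, right, policy)
            allowed = tuple(b for b in book.symbols if b not in banned)
            if not allowed:
                raise ValueError(
                    "right flank makes safe encoding impossible at the boundary"
                )
            if len(allowed) != book.mu:
                book = build_codebook(allowed)
        symbol, consumed = encode_next(book, bits, pos)
        out.append(symbol)
        sizes.append(book.mu)
        pos += consumed
        state = state[-1] + symbol
    return NcdnaEncodeResult(
        "".join(out), min(pos, len(bits)), sizes if trace else []
    )


def decode(
    sequence: str,
    *,
    flanks: tuple[str | None, str | None] | None = None,
    key: int | None = None,
    policy: StartCodonPolicy | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Recover the embedded bit stream from a (possibly mutated) sequence.

    Returns ``(bits, flags)`` where ``flags`` lists positions whose base lay
    outside the allowed set of the replayed state -- evidence of mutation.
    Flagged positions contribute no bits; state tracking continues from the
    observed base.  The caller truncates the bit vector to the true message
    length, which travels out-of-band.
    """
    z = validate_sequence(sequence)
    left = right = None
    if flanks is not None:
        left, right = flanks
    state = _initial_state(left)
    bits: list[int] = []
    flags: list[int] = []
    books: dict[str, Codebook] = {}
    n = len(z)
    for i, base in enumerate(z):
        d = state
        book = books.get(d)
        if book is None:
            book = books[d] = _codebook_for(d, policy, key)
        if right is not None and i == n - 1:
            banned = _flank_forbidden(d, right, policy)
            allowed = tuple(b for b in book.symbols if b not in banned)
            if allowed and len(allowed) != book.mu:
                book = build_codebook(allowed)
        if base in book.symbols:
            bits.extend(int(b) for b in decode_symbol(book, base))
        else:
            flags.append(i)
        state = state[-1] + base
    return np.array(bits, dtype=np.uint8), flags
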