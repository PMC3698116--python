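"""FASTA and message-bit I/O.

Sequences travel as FASTA (via Biopython); messages as raw binary files or
0/1 text.  Bits are MSB-first within each byte; true bit length travels
out-of-band (``--bits``) because the codecs pad with zeros at the tail.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import validate_sequence


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA records as ``(id, sequence)``; sequences are uppercased
    and must be pure ACGT (N or other ambiguity codes are rejected)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append((rec.id, validate_sequence(str(rec.seq))))
        except ValueError as e:
            raise ValueError(f"{path}: record {rec.id!r}: {e}") from None
    return records


def write_fasta(path, records) -> None:
    """Write ``(id, sequence)`` pairs."""
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def bits_from_bytes(data: bytes) -> np.ndarray:
    """Unpack bytes to a bit vector, MSB first."""
    return np.unpackbits(np.frombuffer(data, dtype=np.uint8))


def bytes_from_bits(bits, n_bits: int | None = None) -> bytes:
    """Pack a bit vector to bytes (MSB first), zero-padding the final byte.

    ``n_bits`` truncates to the true message length first.
    """
    b = np.asarray(bits, dtype=np.uint8)
    if n_bits is not None:
        b = b[:n_bits]
    return np.packbits(b).tobytes()


def read_message(path) -> np.ndarray:
    """Read a message as bits: 0/1 text (possibly with whitespace) if the
    file decodes as such, else raw binary."""
    raw = Path(path).read_bytes()
    try:
        text = raw.decode("ascii")
        stripped = "".join(text.split())
        if stripped and set(stripped) <= {"0", "1"}:
            return np.array([int(c) for c in stripped], dtype=np.uint8)
    except UnicodeDecodeError:
        pass
    return bits_from_bytes(raw)


def write_message(path, bits, n_bits: int | None = None, as_text: bool = False) -> None:
    if as_text:
        b = np.asarray(bits, dtype=np.uint8)
        if n_bits is not None:
            b = b[:n_bits]
        Path(path).write_text("".join(str(int(x)) for x in b) + "\n")
    else:
        Path(path).write_bytes(bytes_from_bits(bits, n_bits))
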