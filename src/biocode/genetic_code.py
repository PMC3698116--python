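"""Static biological tables: the genetic code, synonymous codon sets and
start-codon policies.

The standard (near-universal) genetic code maps the 64 codons onto 20 amino
acids plus the translation-stop signal, which is carried here as a 21st
label ``Stp`` so that stop codons participate in synonymous substitution
like any other degenerate codon family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

ALPHABET = "ACGT"

#: three-letter amino-acid labels keyed by one-letter code
_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

STOP_LABEL = "Stp"


def _build_standard_table() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = {codon: _THREE_LETTER[aa] for codon, aa in table.forward_table.items()}
    for codon in table.stop_codons:
        mapping[codon] = STOP_LABEL
    assert len(mapping) == 64
    return mapping


#: codon -> three-letter amino-acid label (standard genetic code, id 1)
CODON_TO_AA: dict[str, str] = _build_standard_table()

#: the 21 labels (20 amino acids + Stp)
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))

#: amino acid -> synonymous codons in canonical (alphabetical) order
SYNONYMOUS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in AMINO_ACIDS
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def validate_sequence(seq: str) -> str:
    """Uppercase ``seq`` and reject anything outside the ACGT alphabet."""
    s = seq.upper()
    bad = set(s) - set(ALPHABET)
    if bad:
        raise ValueError(f"invalid nucleotide symbol(s): {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (A-T, G-C pairing, reversed order)."""
    return validate_sequence(seq).translate(_COMPLEMENT)[::-1]


def translate(codons: Iterable[str]) -> list[str]:
    """Translate a codon iterable into three-letter amino-acid labels.

    Stop codons translate to ``"Stp"``.
    """
    out = []
    for codon in codons:
        c = validate_sequence(codon)
        if len(c) != 3:
            raise ValueError(f"codon must have exactly 3 bases, got {codon!r}")
        out.append(CODON_TO_AA[c])
    return out


def translate_sequence(seq: str) -> list[str]:
    """Translate an in-frame nucleotide string (length divisible by 3)."""
    s = validate_sequence(seq)
    if len(s) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    return translate(s[i : i + 3] for i in range(0, len(s), 3))


def synonymous_set(amino_acid: str) -> tuple[str, ...]:
    """Canonically ordered codons translating ``amino_acid`` (3-letter label)."""
    try:
        return SYNONYMOUS[amino_acid]
    except KeyError:
        raise KeyError(f"unknown amino-acid label: {amino_acid!r}") from None


def load_genetic_code(path) -> dict[str, str]:
    """Read a codon/amino-acid override table from a two-column text file.

    Lines are ``<codon> <label>``; blank lines and ``#`` comments ignored.
    All 64 codons must be covered.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                codon, label = line.split()
            except ValueError:
                raise ValueError(f"{path}:{lineno}: expected '<codon> <label>'")
            mapping[validate_sequence(codon)] = label
    if len(mapping) != 64:
        raise ValueError(f"genetic code must cover 64 codons, got {len(mapping)}")
    return mapping


@dataclass(frozen=True)
class StartCodonPolicy:
    """Which triplets must never appear in modified non-coding DNA.

    The eukaryote policy treats ATG, CTG and TTG as possible translation
    starts; their reverse complements (CAT, CAG, CAA) cover the three
    antisense reading frames.  ``special_duplets`` is the derived set of
    dinucleotides that prefix a forbidden triplet -- the encoder state
    machine keys its restrictions on these.
    """

    organism_class: str = "eukaryote"
    sense_starts: tuple[str, ...] = ("ATG", "CTG", "TTG")
    antisense_triplets: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.antisense_triplets is None:
            object.__setattr__(
                self,
                "antisense_triplets",
                tuple(reverse_complement(c) for c in self.sense_starts),
            )

    @classmethod
    def eukaryote(cls) -> "StartCodonPolicy":
        return cls()

    @classmethod
    def prokaryote_minimal(cls) -> "StartCodonPolicy":
        """ATG-only start recognition (no alternative starts)."""
        return cls(organism_class="prokaryote-minimal", sense_starts=("ATG",))

    @property
    def forbidden_triplets(self) -> tuple[str, ...]:
        return tuple(self.sense_starts) + tuple(self.antisense_triplets)

    @property
    def special_duplets(self) -> tuple[str, ...]:
        """Dinucleotides that prefix some forbidden triplet, in first-seen order."""
        seen: list[str] = []
        for t in self.forbidden_triplets:
            if t[:2] not in seen:
                seen.append(t[:2])
        return tuple(seen)


def find_start_codons(seq: str, policy: StartCodonPolicy | None = None) -> list[int]:
    """0-based positions ``i`` where ``seq[i:i+3]`` is a forbidden triplet.

    Because every reading frame's start codon is some length-3 substring of
    the sequence (or, via the antisense triplets, of its complement), this
    single scan covers all six reading frames.
    """
    policy = policy or StartCodonPolicy.eukaryote()
    s = validate_sequence(seq)
    forbidden = set(policy.forbidden_triplets)
    return [i for i in range(len(s) - 2) if s[i : i + 3] in forbidden]


def contains_start_codon(seq: str, policy: StartCodonPolicy | None = None) -> bool:
    return bool(find_start_codons(seq, policy))


def codon_list(seq: str) -> list[str]:
    """Split an in-frame nucleotide string into codons."""
    s = validate_sequence(seq)
    if len(s) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    return [s[i : i + 3] for i in range(0, len(s), 3)]
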