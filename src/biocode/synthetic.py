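"""Synthetic host-sequence generation.

Stands in for real GenBank coding sequences in tests and simulations:
codons are drawn by first sampling an amino acid from a composition and
then a codon from that amino acid's family under a configurable codon
bias.  ``"uniform"`` bias plus long sequences drives the dynamic codec's
rate toward the static uniform-codon rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .genetic_code import AMINO_ACIDS, STOP_LABEL, synonymous_set


@dataclass
class SyntheticGeneSpec:
    """Recipe for a synthetic in-frame coding sequence.

    ``codon_bias`` maps amino acid -> {codon: weight} (missing families are
    uniform); ``aa_weights`` maps amino acid -> weight (default: uniform
    over the 20 amino acids, stops excluded unless ``include_stops``).
    """

    n_codons: int = 400
    codon_bias: Mapping[str, Mapping[str, float]] | str = "uniform"
    aa_weights: Mapping[str, float] | str = "uniform"
    include_stops: bool = False
    seed: int | None = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")

    @classmethod
    def uniform_codons(cls, n_codons: int, seed: int | None = 0) -> "SyntheticGeneSpec":
        """All 64 codons equally likely: amino-acid weights proportional to
        synonymous-family size, uniform bias within each family."""
        return cls(
            n_codons=n_codons,
            aa_weights={a: float(len(synonymous_set(a))) for a in AMINO_ACIDS},
            include_stops=True,
            seed=seed,
        )


def _normalise(weights: dict[str, float], what: str) -> tuple[list[str], np.ndarray]:
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError(f"degenerate {what} weights")
    return keys, w / w.sum()


def generate_synthetic_cds(spec: SyntheticGeneSpec) -> list[str]:
    """Draw a codon sequence per the spec; deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.aa_weights == "uniform":
        aa_pool = {a: 1.0 for a in AMINO_ACIDS if spec.include_stops or a != STOP_LABEL}
    else:
        aa_pool = dict(spec.aa_weights)
    aa_keys, aa_probs = _normalise(aa_pool, "amino-acid")
    codon_choices: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa in aa_keys:
        family = synonymous_set(aa)
        if spec.codon_bias != "uniform" and aa in spec.codon_bias:
            bias = {c: spec.codon_bias[aa].get(c, 0.0) for c in family}
        else:
            bias = {c: 1.0 for c in family}
        codon_choices[aa] = _normalise(bias, f"codon ({aa})")
    draws = rng.choice(len(aa_keys), size=spec.n_codons, p=aa_probs)
    out = []
    for i in draws:
        codons, probs = codon_choices[aa_keys[i]]
        out.append(codons[rng.choice(len(codons), p=probs)])
    return out


def random_ncdna(length: int, seed: int | None = 0) -> str:
    """Uniform random ACGT string (general-purpose fixture)."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))
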