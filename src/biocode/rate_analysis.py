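"""Embedding-rate analysis: graduated rates, the exact trailing-dinucleotide
Markov chain of the ncDNA codec, and per-gene empirical rates.

The graduated rate ``R(mu)`` is the expected codeword length of a
``mu``-symbol graduated codebook under uniform random message bits::

    R(mu) = R_lo * (2**R_hi - mu) / 2**R_lo + R_hi * 2*(mu - 2**R_lo) / 2**R_hi

with ``R_lo = floor(log2 mu)`` and ``R_hi = R_lo + 1``; it equals
``log2 mu`` exactly at powers of two and is bounded by ``[R_lo, R_hi]``.

The steady-state ncDNA rate weights ``R(|S_d|)`` by the stationary
probability of each trailing-dinucleotide state.  The chain is built over
all 16 dinucleotides rather than the 5 lumped restriction classes: the
lumped process is not Markov because transitions out of the unrestricted
class depend on the last base, whereas the 16-state chain is exact.
Results can be reported lumped for comparison with the 5-class view.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.linalg

from .genetic_code import ALPHABET, AMINO_ACIDS, StartCodonPolicy, synonymous_set
from .graduated_mapping import build_codebook
from .ncdna_codec import restricted_set
from .pcdna_codec import biocode_pc_encode


def graduated_rate(mu: int) -> Fraction:
    """Average bits/symbol of the graduated mapping, exact rational."""
    if mu < 1:
        raise ValueError("mu must be >= 1")
    lo = mu.bit_length() - 1
    hi = lo + 1
    return Fraction(lo) * Fraction(2**hi - mu, 2**lo) + Fraction(hi) * Fraction(
        2 * (mu - 2**lo), 2**hi
    )


@dataclass
class MarkovChainModel:
    """Exact dinucleotide chain of the ncDNA encoder."""

    states: tuple[str, ...]
    T: np.ndarray
    stationary: np.ndarray

    def lumped(self) -> dict[str, float]:
        """Stationary mass per restriction class (the 5-class reporting view)."""
        policy_classes = {"AT", "CT", "TT", "CA"}
        out = {c: 0.0 for c in ("AT", "CT", "TT", "CA", "other")}
        for s, p in zip(self.states, self.stationary):
            out[s if s in policy_classes else "other"] += float(p)
        return out


def _stationary(T: np.ndarray) -> np.ndarray:
    """Stationary row vector via eigendecomposition, with a power-iteration
    fallback check built into the normalisation."""
    w, vl = scipy.linalg.eig(T, left=True, right=False)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(vl[:, k])
    pi = np.abs(pi) / np.abs(pi).sum()
    # one refinement step damps eigensolver noise
    pi = pi @ np.linalg.matrix_power(T, 64)
    return pi / pi.sum()


def ncdna_transition_matrix(policy: StartCodonPolicy | None = None) -> MarkovChainModel:
    """Build the 16-state trailing-dinucleotide chain.

    From state ``[a, b]`` the next base is drawn from the restricted set of
    ``ab`` with the codeword-usage probabilities of its graduated codebook
    under uniform bits (length-``l`` words with probability ``2**-l``,
    forced bases with probability 1); the chain moves to ``[b, y]``.
    """
    states = tuple("".join(p) for p in itertools.product(ALPHABET, repeat=2))
    index = {s: i for i, s in enumerate(states)}
    T = np.zeros((16, 16))
    for s in states:
        book = build_codebook(restricted_set(s, policy))
        for base, prob in zip(book.symbols, book.symbol_probabilities()):
            T[index[s], index[s[1] + base]] += float(prob)
    return MarkovChainModel(states, T, _stationary(T))


def ncdna_rate(policy: StartCodonPolicy | None = None) -> float:
    """Steady-state bits/base of the ncDNA codec from the exact chain."""
    model = ncdna_transition_matrix(policy)
    return float(
        sum(
            p * float(graduated_rate(len(restricted_set(s, policy))))
            for s, p in zip(model.states, model.stationary)
        )
    )


def bce_rate() -> Fraction:
    """Average bits/codon of static BCE over uniformly distributed codons.

    Sum over the 21 amino-acid classes of ``|S_a|/64 * R(|S_a|)``; exact
    rational arithmetic gives 7/4.
    """
    return sum(
        (
            Fraction(len(synonymous_set(aa)), 64) * graduated_rate(len(synonymous_set(aa)))
            for aa in AMINO_ACIDS
        ),
        start=Fraction(0),
    )


def optimal_pcdna_rate() -> float:
    """Method-independent ceiling: ``sum |S_a|/64 * log2 |S_a|`` bits/codon."""
    return float(
        sum(
            len(synonymous_set(aa)) / 64 * np.log2(len(synonymous_set(aa)))
            for aa in AMINO_ACIDS
        )
    )


@dataclass
class GeneRateEstimate:
    bits_per_codon: float
    ci_halfwidth: float
    trials: int


def empirical_gene_rate(
    codons, trials: int = 20, seed: int | None = 0, key: int | None = None
) -> GeneRateEstimate:
    """Mean bits/codon achieved by the codon-count preserving codec on a
    specific gene, filling it with fresh uniform random messages.

    The normal-approximation 95% CI half-width accompanies the mean.
    """
    codons = list(codons)
    rng = np.random.default_rng(seed)
    n_c = len(codons)
    rates = []
    for _ in range(trials):
        message = rng.integers(0, 2, size=6 * n_c + 16, dtype=np.uint8)
        result = biocode_pc_encode(message, codons, key)
        rates.append(result.bits_embedded / n_c)
    rates = np.asarray(rates)
    half = 1.96 * rates.std(ddof=1) / np.sqrt(trials) if trials > 1 else float("nan")
    return GeneRateEstimate(float(rates.mean()), float(half), trials)
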