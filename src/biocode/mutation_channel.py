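"""Kimura substitution-mutation channel, cascaded over generations.

The single-generation channel is the Kimura two-parameter model: each base
substitutes with probability ``q`` per generation, with transitions
(A<->G, C<->T) weighted against transversions through the shape parameter
``gamma`` (``gamma = 1`` collapses to Jukes-Cantor).  ``gamma`` relates to
the transition:transversion ratio ``epsilon`` as
``gamma = 3 / (2 * (epsilon + 1))``.  Mutations accumulate independently
per locus, so ``p`` generations compose to the matrix power ``Pi**p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: row/column order of the transition matrix
BASE_ORDER = "ACTG"
_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def gamma_from_epsilon(epsilon: float) -> float:
    """Shape parameter from the transition:transversion ratio."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return 3.0 / (2.0 * (epsilon + 1.0))


def kimura_matrix(q: float, gamma: float) -> np.ndarray:
    """Single-generation 4x4 transition matrix in A,C,T,G order.

    Off-diagonals: ``gamma*q/3`` for transversions, ``(1 - 2*gamma/3)*q``
    for transitions; diagonal ``1 - q``.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    if not 0.0 < gamma <= 1.5:
        raise ValueError("gamma must be in (0, 1.5]")
    P = np.empty((4, 4))
    for y in BASE_ORDER:
        for z in BASE_ORDER:
            if y == z:
                P[_INDEX[y], _INDEX[z]] = 1.0 - q
            elif (y, z) in _TRANSITIONS:
                P[_INDEX[y], _INDEX[z]] = (1.0 - 2.0 * gamma / 3.0) * q
            else:
                P[_INDEX[y], _INDEX[z]] = gamma / 3.0 * q
    return P


def cascade(P: np.ndarray, p: int) -> np.ndarray:
    """``p``-generation channel ``P**p`` by binary exponentiation."""
    if p < 0 or int(p) != p:
        raise ValueError("generation count must be a non-negative integer")
    return np.linalg.matrix_power(np.asarray(P, dtype=float), int(p))


@dataclass(frozen=True)
class KimuraChannel:
    """Cascaded Kimura channel with convenience constructors.

    Parameters
    ----------
    q : per-generation base substitution probability.
    gamma : transition/transversion shape parameter; alternatively pass
        ``epsilon`` to :meth:`from_epsilon`.
    generations : number of generations the sequence is transmitted along.
    """

    q: float
    gamma: float
    generations: int = 1

    @classmethod
    def from_epsilon(cls, q: float, epsilon: float, generations: int = 1) -> "KimuraChannel":
        return cls(q, gamma_from_epsilon(epsilon), generations)

    @property
    def matrix(self) -> np.ndarray:
        return kimura_matrix(self.q, self.gamma)

    @property
    def cascaded_matrix(self) -> np.ndarray:
        return cascade(self.matrix, self.generations)

    def mutate(self, sequence: str, rng: np.random.Generator | int | None = None) -> str:
        return mutate(sequence, self.cascaded_matrix, rng)


def mutate(
    sequence: str,
    P_p: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Sample each base of ``sequence`` independently from its row of ``P_p``."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if not sequence:
        return sequence
    idx = np.fromiter((_INDEX[b] for b in sequence), dtype=np.intp, count=len(sequence))
    cum = np.cumsum(np.asarray(P_p, dtype=float), axis=1)
    cum[:, -1] = 1.0
    u = gen.random(len(idx))
    out_idx = (u[:, None] > cum[idx]).sum(axis=1)
    return "".join(BASE_ORDER[i] for i in out_idx)
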