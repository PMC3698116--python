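"""Monte-Carlo evaluation: bit-error probability and empirical mutual
information of the codecs across generations of the mutation channel.

Each experiment draws fresh uniform random messages, embeds them, passes
the carrier through the cascaded Kimura channel ``Pi**p`` and decodes,
optionally through a resynchronisation code.  Reported per generation
count:

* ``Pb`` -- mismatch fraction between sent and decoded messages, with
  positions missing from the shorter vector counted as errors (length
  mismatch is desynchronisation damage).
* ``MI_per_bit`` -- plug-in mutual information of the pooled empirical
  2x2 joint distribution of (sent bit, decoded bit).
* ``MI_scaled`` -- the same in bits/base (ncDNA) or bits/codon (pcDNA),
  scaled by the run's empirical embedding rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import ncdna_codec, pcdna_codec
from .mutation_channel import cascade, kimura_matrix, mutate
from .resync_codes import (
    MarkerCodeConfig,
    WatermarkCodeConfig,
    marker_decode,
    marker_encode,
    watermark_decode,
    watermark_encode,
)
from .synthetic import SyntheticGeneSpec, generate_synthetic_cds


def bit_error_rate(sent, decoded) -> float:
    """Mismatch fraction; length difference counts as errors."""
    a = np.asarray(sent, dtype=np.uint8)
    b = np.asarray(decoded, dtype=np.uint8)
    n = min(len(a), len(b))
    total = max(len(a), len(b))
    if total == 0:
        return 0.0
    errors = int((a[:n] != b[:n]).sum()) + (total - n)
    return errors / total


def _joint_counts(sent, decoded) -> np.ndarray:
    """Pooled 2x2 counts of (sent, decoded); missing positions contribute
    error pairs."""
    a = np.asarray(sent, dtype=np.uint8)
    b = np.asarray(decoded, dtype=np.uint8)
    n = min(len(a), len(b))
    counts = np.zeros((2, 2))
    np.add.at(counts, (a[:n], b[:n]), 1)
    for bit in a[n:]:
        counts[bit, 1 - bit] += 1
    return counts


def mutual_information(counts: np.ndarray) -> float:
    """Plug-in MI (bits) of a 2x2 joint count table; 0*log0 := 0."""
    total = counts.sum()
    if total == 0:
        return 0.0
    joint = counts / total
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def mutual_information_pairs(pairs: Sequence[tuple[Sequence[int], Sequence[int]]]) -> float:
    counts = np.zeros((2, 2))
    for sent, decoded in pairs:
        counts += _joint_counts(sent, decoded)
    return mutual_information(counts)


@dataclass
class ExperimentConfig:
    codec: str = "ncdna"  # ncdna | bce | biocode_pc
    resync: str = "none"  # none | marker | watermark
    q: float = 1e-8
    gamma: float = 0.1
    generations: tuple[int, ...] = tuple(10**k for k in range(9))
    message_length: int = 10_000
    trials: int = 10
    seed: int = 0
    key: int | None = None
    marker: MarkerCodeConfig = field(default_factory=MarkerCodeConfig)
    watermark: WatermarkCodeConfig = field(default_factory=WatermarkCodeConfig)
    #: host gene for the pcDNA codecs (generated if omitted)
    host_codons: tuple[str, ...] | None = None
    host_n_codons: int = 400

    def __post_init__(self):
        if self.codec not in ("ncdna", "bce", "biocode_pc"):
            raise ValueError(f"unknown codec {self.codec!r}")
        if self.resync not in ("none", "marker", "watermark"):
            raise ValueError(f"unknown resync {self.resync!r}")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if list(self.generations) != sorted(self.generations):
            raise ValueError("generations must be sorted ascending")


@dataclass
class EvalRecord:
    generations: int
    Pb: float
    Pb_ci: float
    MI_per_bit: float
    MI_scaled: float
    embedding_rate: float  # empirical bits/base or bits/codon
    trials: int


def _host(cfg: ExperimentConfig):
    if cfg.host_codons is not None:
        return list(cfg.host_codons)
    spec = SyntheticGeneSpec(n_codons=cfg.host_n_codons, seed=cfg.seed % (2**31))
    return generate_synthetic_cds(spec)


def run_experiment(cfg: ExperimentConfig) -> list[EvalRecord]:
    """Run the Monte-Carlo pipeline over the configured generation grid."""
    host = _host(cfg) if cfg.codec != "ncdna" else None
    records = []
    for gi, p in enumerate(cfg.generations):
        P_p = cascade(kimura_matrix(cfg.q, cfg.gamma), p)
        counts = np.zeros((2, 2))
        pbs = []
        carrier_units = 0
        bits_embedded = 0
        for trial in range(cfg.trials):
            rng = np.random.default_rng([cfg.seed % (2**31), gi, trial])
            m = rng.integers(0, 2, size=cfg.message_length, dtype=np.uint8)
            if cfg.resync == "marker":
                inner = marker_encode(m, cfg.marker)
            elif cfg.resync == "watermark":
                inner = watermark_encode(m, cfg.watermark)
            else:
                inner = m
            if cfg.codec == "ncdna":
                enc = ncdna_codec.encode(inner, None, key=cfg.key)
                y = enc.sequence
                z = mutate(y, P_p, rng)
                raw, _ = ncdna_codec.decode(z, key=cfg.key)
                carrier_units += len(y)
            else:
                encode = (
                    pcdna_codec.bce_encode
                    if cfg.codec == "bce"
                    else pcdna_codec.biocode_pc_encode
                )
                enc = encode(inner, host, cfg.key)
                z = mutate("".join(enc.codons), P_p, rng)
                z_codons = [z[i : i + 3] for i in range(0, len(z), 3)]
                if cfg.codec == "bce":
                    raw = pcdna_codec.bce_decode(z_codons, cfg.key)
                else:
                    raw, _ = pcdna_codec.biocode_pc_decode(z_codons, cfg.key)
                carrier_units += len(host)
            # payload accounting: message bits per carrier unit (resync
            # overhead is not payload); a host too short for the full
            # message simply embeds a prefix, which is what gets compared
            if enc.bits_embedded < len(inner):
                if cfg.resync != "none":
                    raise ValueError(
                        "message (plus resync overhead) exceeds host capacity; "
                        "reduce message_length or enlarge the host"
                    )
                m_sent = m[: enc.bits_embedded]
            else:
                m_sent = m
            bits_embedded += len(m_sent)
            if cfg.resync == "marker":
                decoded = marker_decode(raw, cfg.marker, len(m_sent))
            elif cfg.resync == "watermark":
                decoded = watermark_decode(raw, len(m_sent), cfg.watermark)
            else:
                decoded = raw[: len(m_sent)]
            pbs.append(bit_error_rate(m_sent, decoded))
            counts += _joint_counts(m_sent, decoded)
        pbs = np.asarray(pbs)
        mi = mutual_information(counts)
        rate = bits_embedded / carrier_units if carrier_units else 0.0
        ci = (
            1.96 * pbs.std(ddof=1) / np.sqrt(cfg.trials) if cfg.trials > 1 else float("nan")
        )
        records.append(
            EvalRecord(p, float(pbs.mean()), float(ci), mi, mi * rate, rate, cfg.trials)
        )
    return records
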