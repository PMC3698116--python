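"""pcDNA codecs: static BCE and the dynamic codon-count preserving codec."""

from collections import Counter

import numpy as np
import pytest

from biocode import pcdna_codec as pc
from biocode.genetic_code import translate
from biocode.synthetic import SyntheticGeneSpec, generate_synthetic_cds


def test_bce_forced_codons_carry_no_bits():
    res = pc.bce_encode([1, 0, 1], ["ATG"])
    assert res.codons == ["ATG"] and res.bits_embedded == 0
    res = pc.bce_encode([1, 0, 1], ["TGG"])  # Trp
    assert res.codons == ["TGG"] and res.bits_embedded == 0


def test_bce_glycine_example():
    res = pc.bce_encode([0, 1, 1], ["GGA"])
    assert res.codons == ["GGC"]  # Gly family {00,01,10,11} -> 01 -> GGC
    assert res.bits_embedded == 2


def test_bce_decode_examples():
    assert list(pc.bce_decode(["GGC"])) == [0, 1]
    assert list(pc.bce_decode(["TGG"])) == []


def test_bce_roundtrip(rng, small_cds):
    m = rng.integers(0, 2, size=150, dtype=np.uint8)
    res = pc.bce_encode(m, small_cds)
    back = pc.bce_decode(res.codons)
    n = res.bits_embedded
    assert np.array_equal(back[:n], m[:n])
    assert translate(res.codons) == translate(small_cds)


def test_init_state_restriction():
    state = pc.init_state(["GGA", "GGC", "GGG"])
    assert state.families["Gly"] == ("GGA", "GGC", "GGG")
    assert state.books["Gly"].codewords == ("0", "10", "11")
    solo = pc.init_state(["ATG"])
    assert solo.families["Met"] == ("ATG",)
    assert solo.counts == Counter({"ATG": 1})
    assert solo.families["Gly"] == ()


def test_init_state_full_code_reproduces_static_tables():
    all64 = [c for fam in pc.SYNONYMOUS.values() for c in fam]
    state = pc.init_state(all64)
    for aa, fam in pc.SYNONYMOUS.items():
        assert state.families[aa] == fam
        assert state.books[aa].codewords == pc._static_books(None)[aa].codewords


def test_dynamic_hand_trace():
    """Gly budget {GGA:1, GGC:1}: first position consumes a bit, second is
    forced by the exhausted table and consumes none."""
    host = ["GGA", "GGC"]
    res = pc.biocode_pc_encode([0, 1, 1, 0], host)
    assert res.codons == ["GGA", "GGC"]
    assert res.bits_embedded == 1  # one bit at the first position only
    res2 = pc.biocode_pc_encode([1, 0, 0, 1], host)
    assert res2.codons == ["GGC", "GGA"]
    bits, flags = pc.biocode_pc_decode(res2.codons)
    assert list(bits) == [1] and flags == []


def test_count_preservation_and_roundtrip(rng, small_cds):
    for trial in range(20):
        m = rng.integers(0, 2, size=int(rng.integers(0, 300)), dtype=np.uint8)
        res = pc.biocode_pc_encode(m, small_cds)
        assert Counter(res.codons) == Counter(small_cds)
        assert translate(res.codons) == translate(small_cds)
        bits, flags = pc.biocode_pc_decode(res.codons)
        n = res.bits_embedded
        assert flags == []
        assert np.array_equal(bits[:n], m[:n])


def test_roundtrip_with_key(rng, small_cds):
    m = rng.integers(0, 2, size=100, dtype=np.uint8)
    res = pc.biocode_pc_encode(m, small_cds, key=5)
    assert Counter(res.codons) == Counter(small_cds)
    bits, _ = pc.biocode_pc_decode(res.codons, key=5)
    assert np.array_equal(bits[: res.bits_embedded], m[: res.bits_embedded])
    wrong, _ = pc.biocode_pc_decode(res.codons, key=6)
    assert not np.array_equal(wrong[: res.bits_embedded], m[: res.bits_embedded])


def test_singleton_only_gene_embeds_nothing():
    host = ["ATG", "TGG", "ATG"]
    res = pc.biocode_pc_encode([1, 1, 1], host)
    assert res.codons == host and res.bits_embedded == 0
    bits, flags = pc.biocode_pc_decode(host)
    assert bits.size == 0 and flags == []


def test_substitution_produces_local_flag_or_bit_damage(rng, small_cds):
    m = rng.integers(0, 2, size=200, dtype=np.uint8)
    res = pc.biocode_pc_encode(m, small_cds)
    mutated = list(res.codons)
    # synonymous substitution at the first multi-codon family position
    for i, codon in enumerate(mutated):
        fam = pc.SYNONYMOUS[pc.CODON_TO_AA[codon]]
        if len(fam) > 1:
            mutated[i] = next(c for c in fam if c != codon)
            break
    bits, flags = pc.biocode_pc_decode(mutated)
    n = min(len(bits), res.bits_embedded)
    assert (not np.array_equal(bits[:n], m[:n])) or flags


def test_encoder_never_stalls(rng):
    """Every position always finds a codon with remaining budget."""
    for seed in range(10):
        host = generate_synthetic_cds(
            SyntheticGeneSpec(n_codons=60, include_stops=True, seed=seed)
        )
        m = rng.integers(0, 2, size=500, dtype=np.uint8)
        res = pc.biocode_pc_encode(m, host)  # would raise if a table emptied
        assert len(res.codons) == 60


def test_rate_increases_with_length():
    from biocode.rate_analysis import empirical_gene_rate

    rates = []
    for n in (100, 400, 1600):
        host = generate_synthetic_cds(SyntheticGeneSpec.uniform_codons(n, seed=4))
        est = empirical_gene_rate(host, trials=8, seed=1)
        rates.append((est.bits_per_codon, est.ci_halfwidth))
    assert rates[0][0] + rates[0][1] < rates[1][0] - rates[1][1]
    assert rates[1][0] + rates[1][1] < rates[2][0] - rates[2][1]


def test_non_triplet_length_rejected():
    from biocode.genetic_code import codon_list

    with pytest.raises(ValueError):
        codon_list("ACGTA")
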