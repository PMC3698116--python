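# biocode-dna

Embedding binary data in DNA under strict biological constraints, with the
coding analyses needed to know how much fits and how long it survives.

DNA is a digital medium: the four bases A, C, G, T can carry arbitrary
messages, and information placed in the genome of a living organism is
replicated from generation to generation. But a living host imposes rules.
A modified non-coding region must not acquire a start codon (ATG, or the
eukaryotic alternatives CTG/TTG) in *any* of the six reading frames — three
per strand — or the cell's machinery may try to translate it. A modified
protein-coding region must translate to exactly the same protein, and
ideally keep its codon-usage statistics untouched, since codon bias
influences translation speed and expression. This package implements two
codecs that satisfy these constraints by construction, plus the channel
model and analyses that quantify their robustness to mutation:

* **ncDNA codec** — embeds bits base-by-base using a *graduated mapping*
  keyed on the trailing dinucleotide `d = [y(i-2), y(i-1)]`. When `d ∈
  D = {AT, CT, TT, CA}` the next base is drawn from a restricted set `S_d`
  so no start codon can arise on either strand; otherwise all four bases
  are available. Steady-state rate: **1.7538 bits/base** (exactly 114/65),
  against the unconstrained 2 bits/base.
* **pcDNA codecs** — substitute codons synonymously so `aa(ȳ) = aa(x̄)`.
  The static variant (binary codon equivalency, BCE) uses one prefix-free
  codebook per amino acid and achieves **1.75 bits/codon** under uniform
  codon usage (the method-independent ceiling is 1.7819). The dynamic
  variant additionally preserves the host's exact codon histogram: each
  codon may be used only as often as it appeared, exhausted codons are
  removed and the family's codebook rebuilt, so the codon count vector of
  the output equals that of the input — a first-order steganographic
  guarantee.
* **Mutation channel** — the Kimura two-parameter model `Π(q, γ)`
  (transition/transversion-aware; `γ = 1` is Jukes–Cantor), cascaded over
  `p` generations as `Π^p`.
* **Resynchronisation** — substitutions can make the variable-length
  decoder insert or drop bits, desynchronising everything downstream.
  Marker codes (periodic pilot patterns) and simplified watermark codes
  (sparsify, XOR with a shared pseudo-random vector, realign by banded
  edit-distance) repair the bitframe.
* **Evaluation** — Monte-Carlo estimates of bit-error probability and
  empirical mutual information versus generation count.

## Worked example

```python
import numpy as np
from biocode import ncdna_codec, pcdna_codec
from biocode.io import bits_from_bytes

bits = bits_from_bytes(b"Hi")           # 0100100001101001

res = ncdna_codec.encode(bits)
print(res.sequence)                      # TACACTTTAC
back, flags = ncdna_codec.decode(res.sequence)
assert np.array_equal(back[:16], bits) and flags == []
```

The 16 message bits become the 10-base carrier `TACACTTTAC`; neither it nor
its reverse complement contains ATG, CTG or TTG anywhere, and decoding
replays the same state machine to recover the bits. Flags would mark any
base that is impossible under the replayed state — evidence of mutation.

The codon-count-preserving codec on a toy gene:

```python
host = ["GGA", "CTA", "ATG", "GGC", "CTT", "TAA"]
r = pcdna_codec.biocode_pc_encode(bits, host)
print(r.codons, r.bits_embedded)
# ['GGA', 'CTT', 'ATG', 'GGC', 'CTA', 'TAA'] 2
```

The output translates to the same protein and contains exactly the same
codon multiset as the host; only the *arrangement* within each synonymous
family carries information (here 2 bits — the first Gly and first Leu
position each carry one bit, after which every family is forced). Rates
grow with gene length and codon diversity:

```sh
$ biocode rate --ncdna
{"ncdna_bits_per_base": 1.7538461538461538}
$ biocode rate --bce
{"bce_bits_per_codon": 1.75}
```

The CLI also exposes `nc-encode/nc-decode`, `pc-encode/pc-decode`,
`mutate`, `synth` and `simulate` for file-based pipelines (FASTA carriers,
raw-binary or 0/1-text messages; true message length travels out-of-band
via `--bits`).

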