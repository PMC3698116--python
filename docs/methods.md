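# Methods

## Graduated bit↔symbol mappings

Both codecs map message bits to DNA symbols through *graduated* prefix-free
codebooks. For `μ` available symbols, `l = ⌊log₂ μ⌋`: the first
`2^(l+1) − μ` symbols get the `l`-bit strings in ascending binary order and
each remaining `l`-bit string is extended with "0" and "1" to serve the
remaining symbol pairs. A single-symbol codebook maps to the empty string,
so forced symbols carry no information. Under uniform random message bits a
length-`l` codeword is used with probability `2^−l`, giving the average
rate

    R(μ) = l·(2^(l+1) − μ)/2^l + (l+1)·2(μ − 2^l)/2^(l+1)   bits/symbol,

which equals `log₂ μ` exactly at powers of two and is kept as an exact
`Fraction` throughout the rate analyses. Tail handling: if the message
ends mid-codeword the encoder pads with zero bits; the true bit length is
carried out-of-band and the decoder truncates. A secret key is realised as
a deterministic permutation of each labelled symbol set's canonical order
(derived from the integer key and the set label), identity by default so
the published tables are reproduced.

## ncDNA codec

Eukaryotic start codons ATG/CTG/TTG, read on either strand, appear on the
forward strand as the six triplets {ATG, CTG, TTG, CAT, CAG, CAA}. All six
are prefixed by a dinucleotide in `D = {AT, CT, TT, CA}`, so the encoder
only needs to restrict the next base whenever the trailing dinucleotide is
in `D`: after AT/CT/TT the base G is banned (sets {A,T,C}, codebook
{0,10,11}); after CA only C remains (forced, zero bits); otherwise all four
bases are available (codebook {00,01,10,11}). Because every window of
three consecutive bases is checked through its first two symbols, no start
codon can appear in any of the six reading frames of the output.

Boundary conventions (ours): positions 1–2 use a virtual left context
"GG", which triggers no restriction; if a real left flank is supplied its
last two bases seed the state instead. With a right flank and a fixed
target length, the final position additionally bans bases that would
complete a start codon across the boundary; if that empties the set the
encoder raises rather than emit an unsafe base. The decoder replays the
state machine on the *received* sequence — a substitution can therefore
change downstream set sizes and shift the bitframe, which is precisely
what the resynchronisation codes address. Bases impossible under the
replayed state are flagged and contribute zero bits; correction beyond
flagging is left to outer codes.

### Steady-state rate

The encoder is a Markov chain over trailing dinucleotides. The five-class
view {AT, CT, TT, CA, other} is not Markov (transitions out of "other"
depend on the last base), so the rate is computed on the exact 16-state
chain: from state `[a,b]`, the next base is drawn from the restricted set
of `ab` with its codeword-usage probabilities, moving to `[b,y]`. The
stationary distribution (eigendecomposition, refined by a matrix-power
step and cross-checked by power iteration in the tests) weights `R(|S_d|)`:

    R_ncDNA = Σ_d π(d) · R(|S_d|) = 114/65 = 1.753846…  bits/base.

Solving the chain in exact rational arithmetic gives the same value, with
lumped stationary masses: other 48/65, AT 1/20, CT 1/13, CA 1/13, TT 3/52.
The Monte-Carlo rate of the actual encoder agrees to within sampling error
(±0.002 at 10⁶ message bits).

## pcDNA codecs

The static codec (binary codon equivalency) assigns each amino acid's full
synonymous family — canonical alphabetical order, Stp treated as a 21st
class of size 3 — a graduated codebook, and replaces each host codon with
the family member selected by the upcoming message bits. Under uniform
codon usage the rate is `Σ_a (|S_a|/64)·R(|S_a|) = 112/64 = 1.75`
bits/codon; replacing `R` with `log₂` gives the method-independent ceiling
1.7819 bits/codon.

The dynamic codec additionally preserves the exact codon histogram. At
initialisation each family is restricted to the codon types present in the
host, and a codon count vector holds each type's budget. After each
emission the budget is decremented; at zero the codon is removed and the
family's codebook rebuilt graduatedly. Feasibility is structural: per
amino acid, the remaining budget always equals the number of remaining
positions, so a codon is always available. When the message is exhausted,
remaining positions take the first remaining codon of their family — a
deterministic fill that preserves counts and that the decoder discards via
the out-of-band message length. The decoder rebuilds the same tables from
the received sequence's own histogram (equal to the encoder's when no
mutation occurred) and replays them; a codon absent from its current
family is flagged and skipped.

## Mutation channel

Single-generation substitutions follow the Kimura two-parameter model in
base order A, C, T, G: diagonal `1 − q`, transitions (A↔G, C↔T)
`(1 − 2γ/3)q`, transversions `γq/3`, with `γ = 3/(2(ε+1))` from the
transition:transversion ratio ε and `γ = 1` recovering Jukes–Cantor.
Mutations are independent across loci (real local dependence can be broken
by an interleaver), and `p` generations compose to the matrix power `Π^p`,
computed by binary exponentiation in double precision (row sums stay
within 1e−10 of 1 even at `p = 10¹⁰`, where the rows approach the uniform
stationary law). Sampling is vectorised from the cascaded rows with a
seeded generator; per-trial substreams are derived deterministically from
the experiment seed.

Simulation defaults follow realistic per-generation estimates:
`q = 10⁻⁸`, `γ = 0.1`, generation grids over decades 10⁰…10⁸. Insertions
and deletions at the DNA level are out of scope.

## Bitframe resynchronisation

Marker codes insert a pilot pattern (default "001") after every block
(default 99 bits; both configurable — no canonical values exist, the
defaults pair the classic pilot with a round block size). A pilot observed
one position early/late implies a deletion/insertion in the preceding
block, repaired by inserting a zero / deleting a bit at the block
midpoint: one desynchronisation per block is corrected, flips inside the
block are not. The expected block structure comes from the out-of-band
message length.

Watermark codes sparsify the message (bit `k` at position `⌊k/sparsity⌋`,
default sparsity 0.5), XOR with a shared pseudo-random watermark `w`, and
embed the result. The decoder realigns the received vector against `w` by
global edit-distance alignment in which `w` is the fixed frame: the output
always has `|w|` columns, received values are kept at mismatch columns,
deleted positions fall back to the watermark value. This is the
simplified alignment variant; probabilistic forward–backward decoding with
channel information is deliberately out of scope.

Alignment scoring (ours): integer costs, mismatch 1 versus gap 10, ties
toward the diagonal. The ratio matters: a spurious one-position shift
costs two gaps and only pays off by avoiding ≥ 2·gap/mismatch = 20
consecutive mismatches, a ~4⁻²⁰-per-site coincidence in random binary
data, so an indel-free channel yields the identity path; a true deletion
flips about half of all downstream comparisons and amortises its gap
within ~20 bits. Integer arithmetic keeps the dynamic programme exact —
with float costs, rounding noise in the banded prefix-scan was observed to
flip ties away from the diagonal. The band follows the straight line
between the endpoints with half-width `|Δlength| + 32`, giving
`O(|w|·band)` time.

## Performance measures

Bit-error probability is the mismatch fraction between the sent and
decoded messages; positions missing from the shorter vector count as
errors (length mismatch is desynchronisation damage). Note the usual
convention: a Kronecker-delta "Hamming similarity" would count agreements,
so the implementation counts disagreements, the only reading consistent
with a probability of bit error. Mutual information is the plug-in
estimate from the pooled empirical 2×2 joint of (sent bit, decoded bit)
across positions and trials, with `0·log 0 = 0`; it is scaled from
bits/bit to bits/base or bits/codon by the run's empirical embedding rate,
so at `p = 0` the scaled value equals the embedding rate. Messages longer
than a pcDNA host's capacity embed a prefix, and only embedded bits are
compared; resynchronisation-coded runs require the full coded stream to
fit.

## Synthetic hosts

The generator draws an amino acid per position from a configurable
composition (default uniform over the 20 amino acids, stops excluded
unless requested), then a codon from that family under a configurable
bias (default uniform). `SyntheticGeneSpec.uniform_codons` weights amino
acids by family size so all 64 codons are equally likely. This emulates
composition and codon-bias structure but not real features such as codon
autocorrelation, GC gradients, or splice/regulatory motifs — passing tests
show the codecs' combinatorial guarantees and rates, not organism-specific
performance. Where a check targets the uniform-distribution expectation
(the 1.75 bits/codon figure), the test host is an exactly balanced codon
histogram, removing composition noise from a fixed-size sample.

## Problem sizes and numerical choices

Analytic checks run at full precision (rational arithmetic where stated).
Empirical rate checks use 10⁶ message bits (ncDNA) and ~10⁵ codons (BCE);
randomized invariant sweeps use 10⁴ cases of small messages and genes;
Monte-Carlo sweeps default to a handful of trials per generation decade
with 95% normal-approximation confidence intervals, sizes chosen to keep
the full suite in the minutes range on one CPU. Stationary distributions
come from `scipy.linalg.eig` with a power-iteration consistency check;
degenerate inputs (empty messages, empty sequences, single-symbol
codebooks, `p = 0`) are exercised explicitly in the tests.

## Known limitations

* Marker decoding corrects at most one desynchronisation per block and
  never repairs flips; watermark realignment degrades once the flip rate
  approaches one half, as channel information is not used.
* No indel channel at the DNA level; no codon-pair bias preservation (with
  both primary-structure and codon-count constraints active there is
  typically no freedom left to also preserve pairs); no intron handling;
  callers supply in-frame CDS.
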