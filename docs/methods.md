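# Methods

## The model

A `ProfileSCFG` is a probabilistic model of one structured RNA family.
Its skeleton is a guide tree built deterministically from the consensus
secondary structure: leading unpaired columns become left-emitting
singles (MATL), trailing unpaired columns right-emitting singles (MATR),
a paired outermost column pair becomes a PAIR node, and a level holding
*n* helices splits into *n* − 1 bifurcations (BIF), so a cloverleaf has
two.  The in-order traversal of emitting nodes recovers the consensus
exactly, which is asserted in tests.

Consensus columns are those with gap fraction < 0.5 in the seed
alignment; a structural pair survives only if both of its columns are
consensus.  All scores are log₂ likelihood ratios ("bits") against a
background base distribution, uniform 0.25 by default so that scores are
genome-independent.  Emissions use Laplace pseudocounts (α = 1 per cell):
a single column seen once as A scores log₂((2/5)/0.25) ≈ +0.678 bits for
A; a pair seen once as G:C scores log₂((2/17)/0.0625) ≈ +0.912 bits for
G:C.  Match/delete transitions (and the pair left-only / right-only /
delete variants) are trained per node with α = 1 per option.  N and any
other ambiguity code scores zero bits (the background expectation);
ambiguity codes contribute fractionally to training counts, uniformly
over their IUPAC set, which is how NNN-masked anticodon columns train to
near-flat emissions.

**Insert runs.**  Each insert slot (after a left emission, before a right
emission, between the two sides of a bifurcation, and at the root's
flanks) carries a geometric run model: open, extend, stop.  Inserted
residues themselves score zero bits.  The run-length estimate uses a
length-calibrated prior (extension 9 : stop 1, i.e. a mean unobserved run
of ~10 nt) rather than pure Laplace: with no observed inserts, Laplace
would set the extension probability to 1/3 and charge ~1.6 bits for every
inserted nucleotide, making the 15–50 nt introns this pipeline exists to
find cost 25–80 bits and effectively banning them.  Observed insert
counts dominate the prior when present.  Motif models that must stay
compact — the bulge-helix-bulge (BHB) splice-site models — are trained
with the strict Laplace prior instead (`ext_prior=1`), because a motif
interrupted by a long insertion has not physically formed.

## Scoring

`score_sequence` runs a CYK-style maximum dynamic program over the guide
tree: `M[v, i, j]` is the best bit score of node *v* generating
`s[i:j]`, with bifurcations maximising over split points.  `local` mode
leaves residues outside the chosen span unpenalised; `global` parses the
whole sequence.  Three companion tables (`T5`, `T3`, `T53`) let a prefix,
suffix, or both of the consensus columns (in emission order) be deleted
at zero penalty, consulted only for parses anchored at a sequence
boundary — the model of genes truncated by a contig end.  A pair whose
partner column falls in the truncated region emits its surviving residue
with the pair's marginal score and no transition charge.

Every parse decomposes exactly: the primary-sequence score re-scores the
identical parse with each pair emission replaced by the sum of its two
marginal single scores; the secondary-structure score is the remainder
(the covariation surplus), and `score = primary + secondary` to 1e-9 by
construction.  Traceback is deterministic — fewest inserted residues
first, then a fixed option order, non-truncated before truncated — so
repeated runs are byte-identical.

The kernel is written with numba; an independent reference scorer
(direct recursion over the generative grammar with explicit insert-length
and split-point loops) lives in the test suite and agrees with the
kernel exactly on thousands of random tiny-model/short-sequence pairs in
all four mode × truncation combinations.

## Search

First pass: the model is marginalised to a structure-free linear profile
(pair columns released to their marginals) and swept over both strands
with a vectorised glocal Viterbi — local in the sequence, global in the
profile.  Ends scoring ≥ 10 bits seed candidate windows, extended by a
60-nt flank each side and merged when overlapping on the same strand.
The first and last window of every sequence are always rescored
structurally regardless of the first pass, because a boundary-truncated
gene can fall below the structure-free cutoff yet clear the reporting
threshold once truncation is allowed.  The first-pass score tracks the
primary-sequence component, so genes whose evidence is mostly structural
(e.g. heavily intron-penalised weak genes) can be missed by the default
two-pass search; the exhaustive sliding-window mode (`--max`, 200-nt
windows with 150-nt overlap) trades time for that sensitivity.

Second pass: each window is scored with the full structural model
(truncation allowed only at true sequence ends); hits at or above the
20-bit reporting threshold are emitted with exact coordinates, and the
window remainders are rescanned so merged windows can yield several
genes.  Overlapping same-strand hits across models keep the top scorer
(ties: lexicographic model name, then leftmost).

Reported scores and the anticodon come from the *mature* tRNA: introns
removed, re-parsed globally.  The scan model's anticodon columns are
NNN-masked, so when isotype-specific models are available the anticodon
is read off the best-scoring one, whose anchored loop positions the three
columns much more reliably; the observed residues are reported, so a
mutated anticodon still reads as mutated (this is what makes the IPD flag
meaningful).

## Introns

Canonical introns appear as an insert run attached between the consensus
column one position 3′ of the anticodon and its successor (positions
37/38); because a splice-boundary base can mimic a neighbouring consensus
column, runs attached one region to either side also count, and runs
below 8 nt are ignored.  Noncanonical (archaeal) introns are searched
iteratively: the candidate is extended with 60-nt flanks, scanned with
the two BHB models, and each acceptable motif hit (≥ 10 bits, span within
10 nt of the motif's consensus length) is tentatively spliced; the splice
is accepted only if the mature-tRNA score strictly improves.  Iteration
continues (≤ 3 rounds) because closely spaced introns hide one another's
motifs, and stops if the mature length would drop below 70 nt.  The BHB
acceptance threshold (10 bits), minimum intron length (8 nt) and span
slack (10 nt) are this package's own operating points, validated in tests
(fixture introns pass; random sequence and disrupted motifs do not).

## Classification and filtering

Anticodon → isotype decoding reverses the codon through the standard (or
vertebrate-mitochondrial) genetic code; the tables ship as packaged JSON.
CAU is three-way ambiguous and resolved by the top subtype model among
{iMet/fMet, Met, Ile2}; UCA maps to SeC; stop-decoders are labelled Sup.
The 15 eukaryotic disallowed anticodons are the 8 unused A34 anticodons
plus the 7 G34 anticodons spared by inosine wobble in four-codon boxes.

The high-confidence filter runs pseudogene (overall < 55 and primary < 10
or secondary < 5) → secondary (top isotype score < 70, overall < 50 or
secondary < 10) → tertiary (per anticodon with > 40 predictions: threshold
starts at 71 bits, rises one bit at a time to at most 95, removing
lower-scoring hits) → consistency (IPD or a disallowed anticodon excludes
a prediction from the high-confidence set but it is still reported with
its flags).  Every comparison is strict `<`, so boundary values survive.
The filter targets eukaryotic predictions and warns on other domains.

## Synthetic data

The fixture generator emulates the statistical structure the method
exploits without any real sequence: families within a domain share ~82%
of a master cloverleaf consensus (76 columns; D-armless, 9/4- and
8/5-fold selenocysteine variants for the special architectures), stems
vary compensatorily at 8% per pair, loops at 8% per base, anticodon
columns are invariant within a family, and rare gaps (2%) appear in
loops.  Eight nuclear families (including the three CAU classes and
SeC), the 22 vertebrate mitochondrial classes and two BHB intron
families are built this way (400 / 150 / 150 rows).  The implanted
genome is 100 kb of fifth-order Markov background carrying ≥ 50 sampled
genes: plain, canonical-intron (13–17 nt), one- and two-BHB-intron,
boundary-truncated, and anticodon-mutated (IPD) cases, each recorded in a
truth table; the mitochondrial genome is 16.6 kb with one implant per
class.  What passing these tests does *not* show: performance on real
genomes, whose tRNA families carry modified-base-driven biases,
pseudogene gradients and repeat structure the generator does not imitate;
the fixtures establish algorithmic correctness and calibration, not
field sensitivity.

Markov training uses (order+1)-mer counts with pseudocount 1, skipping
N-containing windows; generation is sequential and deterministic under a
seed, per-sequence rather than concatenated to avoid artificial junction
contexts.

## Numerical and design notes

- −∞ is represented as −1e30 to keep additions NaN-free; equality checks
  in traceback use 1e-6 bits, score assertions 1e-9.
- Local-mode span ties resolve to the lexicographically smallest (i, j);
  variant preference is plain before truncated.
- Model files store bit scores to three decimals and round-trip
  byte-identically; pair marginals are recomputed from the quantised
  table on load.
- Problem sizes in the acceptance suite are scaled analogues chosen to
  exercise every code path at desk scale: 50 random tiny models × 200
  short sequences for the enumeration equivalence, a 100 kb implant
  genome, 10 Mb of false-positive background, 200 samples per isotype
  for the concordance rate, and 4 virtual mitochondrial genomes.
- Known limitations: no E-values (bit thresholds only); truncation is
  boundary-anchored and zero-penalty rather than probabilistic; the
  first pass is primary-sequence-only (see Search); circular genomes are
  scanned linearly, so a gene spanning the origin is missed unless the
  caller rotates the sequence.
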