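# Methods

## Model

A PLS-class PPR protein with ℓ annotated motifs defines the pair sequence
S(6,1′): m = ℓ − 1 ordered triples (aa6, aa1′, motif type), where triple t
pairs residue 6 of motif t with residue 1 of motif t+1 and carries the type
of motif t (the repeat whose helix contacts the base).  Binding-site
prediction is semi-global alignment of S(6,1′) (length m) to an RNA R
(length n ≥ m) under a seven-state pair HMM:

| state | consumes | meaning |
|---|---|---|
| `start`, `end` | — | silent boundary states |
| `M` | 1 pair + 1 base | a pair–nucleotide contact |
| `D1` | 1 base | unaligned 5′ flank (before the first contact) |
| `D2` | 1 base | unaligned 3′ flank (after the last contact) |
| `X` | 1 base | internal gap on the protein side (a contact on both sides) |
| `Y` | 1 pair | gap on the RNA side |

Legal transitions: `start→{M,D1}`, `D1→{D1,M}`, `M→{M,X,Y,D2,end}`,
`X→{X,M}`, `Y→{Y,M}`, `D2→{D2,end}`.  This structure alone encodes the
semantic constraints (D1 only before the first match, D2 only after the
last, X flanked by matches); the brute-force oracle in the test suite
enumerates exactly the walks this graph admits.

**Transitions.**  Rows out of `M`, `X` and `Y` are estimated from a corpus
of recorded binding events as (F(α,β) + γ) / Σ_β (F(α,β) + γ) over the
legal successors, where F counts observed consecutive state pairs
(including the silent `start→·` and `·→end` transitions).  Rows out of
`start`, `D1` and `D2` are realized per alignment problem with the flank
exit probability q = 1/((n−m)/2) — a uniform prior over the expected flank
length — clamped into (0, 1]; q = 1 (n − m ≤ 2) means no room for a flank.
Since PLS proteins bind contiguously, real corpora contain no `X`/`Y`
steps; the two states exist for forward compatibility with gapped repeat
families, and with γ = 0 they are provably unreachable.

**Emissions.**  `M` emits from a 400 × 4 × 3 table A over (amino-acid pair,
nucleotide, motif type), estimated as (G + η) / Σ (G + η) with the sum over
*all* 4800 cells — global rather than per-row normalization, so a pair seen
rarely but consistently still scores high for its preferred base.  Gap
states emit uniformly (Q = 1/4 per base for `D1`/`D2`/`X`, O = 1/400 per
pair for `Y`), so alignments are discriminated by their contacts, never by
their gaps.

**Pseudocounts.**  Defaults γ = 1 per legal transition and η = 0.01 per
emission cell.  η is deliberately small: with 4800 cells, a per-cell value
of 1 would contribute 4800 virtual observations and swamp a corpus of a few
hundred real contacts, while 0.01 (48 virtual observations) regularizes
empty cells without distorting observed ones.  Both are recorded in the
model file and are free parameters of `train_model`.

## Decoding and numerics

All computation is in natural-log space (products of hundreds of
probabilities underflow in linear space).  Two kinds of zeros are treated
differently:

- a **zero-probability transition** (e.g. T(M,X) after γ = 0 training on a
  contiguous corpus) is log −∞ and prunes its paths — the hard exclusion of
  `X`/`Y` for PLS proteins;
- a **zero-probability emission cell** (η = 0 and unseen) contributes a
  finite floor of −10⁹, so decoding through it stays defined but such a
  path can never outrank one that avoids it.  Pairs containing
  non-standard residues (X, B, Z) at positions 6/1′ are retained and emit
  the uniform cell value 1/4800 — neutral rather than fatal.

The w-best decoder stores, per DP cell, its w best partial scores with
backpointers; ties are broken deterministically (predecessor state order
M < X < Y < D1 < D2, then smaller coordinates, then rank).  Backpointer
chains are distinct state paths by construction, so the final list is
duplicate-free.  A reported alignment must contain at least one `M` step; a
matchless path (all flank) is meaningless and not decodable under the
transition structure.  Final scores include the terminal `M→end` or
`D2→end` transition.  Scores are accumulated in a fixed left-to-right
association so the decoder agrees bit-for-bit with sequential path
enumeration — the equivalence tests assert exact equality, not approximate.

**Normalized score.**  The sum of the (transition + emission) log terms of
every step entering `M` or `X`, minus the flank-entry term log T(D1,M),
divided by the number of `M` and `X` steps.  The entry term is cancelled
algebraically (not numerically), so the normalized score of a given core
alignment is bit-identical regardless of transcript length or flank
placement — the property that makes scores comparable across transcripts
and usable as a single null distribution.  For a gapless placement this
reduces to ((m−1)·log T(M,M) + Σ log A) / m, which the sliding
`scan_contiguous` evaluates in vectorized form.

## Statistics

The null model for a pair sequence is the set of normalized scores of
every contiguous gapless placement across a transcript database (target
transcripts included by default; a flag excludes them).  Gapped alignments
are excluded from the null: the reported alignments are overwhelmingly
gapless, and a placement-based null is exactly enumerable.  The scores are
fitted by moments (sample mean, n−1 standard deviation) and a prediction's
p-value is the upper tail of N(μ, σ) at its score — the fitted normal
tracks the empirical 5% tail on synthetic databases to within ±2 points,
which the test suite checks.  p-values are floored at the smallest positive
double and never reported as 0.  BH adjustment treats all p-values reported
in one invocation as a single family (per-event p-values in leave-one-out
mode; the reported hits in scan mode).

Decoy databases are per-transcript permutations (preserving length and
base composition) from a seeded generator recorded in the output header.
The false positive rate of a score is the fraction of decoy placements
scoring at least as high.  ROC/AUC is the rank statistic (probability a
random positive p-value is smaller than a random negative one, ties at ½)
with raw — not adjusted — p-values on both sides, since the pooled
negatives come from many different families.

## Synthetic data: what it emulates and what it does not

The generators realize the published recognition code: six P/S-scope pairs
(T+D→G, S+N→A, T+N→A, N+D→U, N+N→C, N+S→C) and two L-scope rules (P at
position 6 → U; N at 1′ with I/L/P/T/M at 6 → adenine — the literature
reports "A or U", and the generator fixes A to keep recovery tests sharp).
Preferences are deterministic; stochasticity enters only through the
fraction of uncoded pairs (`frac_specific`) and the uniform-random filler.
Generated corpora are gapless D1…M^m…D2 events with random flanks
(defaults: 8–16 pairs, 80% coded, flanks 0–30 nt) — the shape of curated
binding diagrams for PLS editing factors.  Transcript backgrounds are
i.i.d. uniform by default, with a composition knob (real organellar
transcripts are AU-rich).

Consequences: passing benchmarks on this data shows the *machinery* is
correct — training recovers the generating code, the decoder is exact, the
planted site is retrieved with calibrated significance.  It does not show
that real binding events are as cleanly coded (real corpora have weaker,
context-dependent preferences and far fewer events), nor that real
transcript composition or repeat annotation noise is handled — benchmark
numbers on synthetic data (AUC ≈ 1, decoy FPR ≈ 0) are best cases, and
real-data performance will be lower.  Running against a real corpus and
transcriptome requires only the documented TSV/FASTA inputs.

## Problem sizes in the shipped benchmarks

The planted-site benchmark uses 50 replicates of: a 200-event training
corpus, a fully coded 12-pair query, and 20 transcripts of 500 nt with one
planted cognate site; a hit must be the top-ranked placement with
BH-adjusted p < 0.01 to count.  The leave-one-out benchmark uses a
30-event corpus and a shared 15 × 400-nt database; its ROC pools ≈ 1.8×10⁵
background placements as negatives.  The decoder-exactness tests cover all
shapes n ≤ 8, m ≤ 3 with over a hundred random parameterizations.  These
sizes give stable statistics while keeping the whole suite fast on a
single CPU.

## Design choices where the design was open

- **Pair order** is (aa6, aa1′) everywhere, matching the recognition-code
  table convention (6 before 1′).
- **The motif type of a pair** is that of the position-6 motif, following
  the structural assignment of the contacted base to that repeat.
- **Scanner fallback**: motif annotation is primarily table-driven (any
  external annotator); the built-in scanner matches a degenerate 35-residue
  P-type consensus by fractional identity (threshold 0.4, ≈ 9 SD above the
  random-sequence mean) and therefore cannot detect length-variant L/S
  repeats — it is a convenience, not a replacement for a profile annotator.
- **Edit-site anchoring**: the window helper reports whether an alignment's
  last contact sits exactly 4 bases upstream of the edit position, the
  documented geometry of PLS editing factors.
- **Model persistence** stores counts plus pseudocount settings and
  recomputes the probability tables deterministically on load, which keeps
  files small and the round trip bit-identical.
- **Direct D1→D2 paths are impossible** (no such transition), so every
  reported alignment contains at least one contact.

## Known limitations

- Trained on PLS-class events only; P-class proteins (pure 35-aa tandem
  arrays, no editing role) would need their own corpus and likely a
  different gap structure.
- The normal null is an approximation; extreme tails (p ≲ 10⁻⁸) are
  extrapolations of the fit, not empirical frequencies.
- The scanner-mode annotator detects canonical-length repeats only.
- No reverse-strand scanning, no RNA secondary structure, no
  posterior/forward–backward decoding.
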