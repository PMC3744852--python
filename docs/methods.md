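# Methods

## The junction model

A copy-number variant allele is modelled as the reference with one junction:
`REF[1..a] . REF[b..N]` (1-based inclusive everywhere in this package).
With `a < b` this deletes bases `a+1..b-1`; with `a >= b` it repeats bases
`b..a` immediately after `a` (a tandem duplication).  A sequencing read of
length `L` that crosses the junction with `x` bases on the 5' side reads
`REF[a-x+1..a] . REF[b..b+L-x-1]`.  A local aligner maps such a read by its
longer half: `x > L/2` yields a matched-then-clipped alignment (`MS`,
CIGAR `xM(L-x)S`, POS `a-x+1`), `x < L/2` a clipped-then-matched one (`SM`).
The matched part of an MS read therefore pins the 5' breakpoint `a` and the
matched part of an SM read pins the 3' breakpoint `b`.

Two clipped reads are accepted as evidence for the *same* junction only when
they overlap in the polarized MS-left / SM-right orientation and their
common string contains both soft-clipped parts (`CL >= s1 + s2`).  The
breakpoints then follow from arithmetic alone:

    a = POS_ms + ref_span_ms - 1,   b = POS_sm,   dx = CL - s1 - s2,

where `ref_span` generalizes the matched length to alignments with internal
indels, and `dx` is the width of the junction repeat (microhomology).

### Repeat (homology) handling

When `REF[a+1..a+h] == REF[b..b+h-1]` the pair `(a, b)` can slide jointly by
up to `h` bases without changing the variant sequence.  Because aligners
extend the matched run maximally toward the junction, the raw arithmetic
anchors `a` at the *rightmost* equivalent position while `b` lands at the
*leftmost* one; the two raw coordinates are deliberately not a consistent
pair.  The refinement step therefore rebases to `a0 = a - dx` and, for every
shift `i` in `[0, dx]`, rebuilds the junction window from the reference,

    CSREF(i) = REF[a0 - s2 + 1 .. a0 + i] . REF[b + i .. b + CL - s2 - 1],

counts mismatches against the observed common string, and takes the argmin
set `{d}`.  The call is placed at `(a0 + min{d}, b + min{d})` with
uncertainty `dx' = max{d} - min{d}`.  On error-free reads every shift
rebuilds the identical string, so the reported pair is the leftmost
equivalent and `dx'` equals the engineered homology — both covered by
tests.  `{d}` can in principle be non-contiguous in pathological repeats
with read errors; the implementation still reports min/max and logs the gap.

### Consensus inside the common string

When the two reads disagree inside their overlap, the common string is
assembled segment-wise — the first `s2` bases from the SM read's clip, the
remainder (repeat + MS clip) from the MS read's suffix — and disagreements
are counted as mismatches.  The mismatch budget is `floor(0.08 * CL)`;
using the floor is the stricter reading of an "8% of the length" rule.  Among
admissible overlap lengths, fewest mismatches wins, ties going to the
longest overlap (more evidence).

## False-positive filters

The paired reads are fused at their common string into `MERGE`
(`|MERGE| = L1 + L2 - CL`) and compared against three equal-length
reference windows: `REFa` (at the MS read's position), `REFb` (ending at
the SM read's last matched base) and `REFab` (the junction reconstruction
`REF[p1..a] . REF[b..]`).  With `tau = 0.08 |MERGE|` a call is rejected
when `dist(MERGE, REFa) < tau`, `dist(MERGE, REFb) < tau`, or
`dist(MERGE, REFab) > tau`; inequalities are strict, so equality at the
threshold is accepted.  All distances are position-wise mismatch counts:
the compared strings are equal length by construction, and for
substitution-only errors this coincides with edit distance.  A Levenshtein
mode for indel-containing reads is a deliberate extension point, not
implemented.

Surviving calls are fingerprinted by 50 reference bases (25 ending at `a`,
25 starting at `b`); calls sharing a fingerprint are collapsed to the one
whose `MERGE` best matches `REFab`, accumulating supporting read pairs.
Fingerprints truncated by a contig edge are N-padded rather than dropped.
Finally, a call must be supported by at least two distinct read pairs.

## Failure-rate model

Among `n` junction-covering reads, calling fails when no usable MS read or
no usable SM read remains.  With the breakpoint offset uniform along the
read, a read is MS or SM with probability 1/2, and its clip is too short
with probability `q1 = (min_clip-1)/(L/2)` on the MS side and
`q2 = (min_clip+dx-1)/(L/2)` on the SM side (junction homology is absorbed
into the SM matched part, shortening that clip).  Conditioning on the
MS/SM split and applying inclusion-exclusion:

    FNR(n, L, min_clip, dx)
      = sum_{i=0}^{n} C(n,i) (1/2)^n [ q1^i + q2^(n-i) - q1^i q2^(n-i) ].

The sum is accumulated with log-space binomial coefficients; the bracket is
non-negative, so there is no cancellation.  The test suite checks the sum
against its binomial-theorem collapse
`((1+q1)/2)^n + ((1+q2)/2)^n - ((q1+q2)/2)^n` and against a read-level
Monte-Carlo verifier (3 SE on a 12-point grid at 10^6 replicates).  At the
default design point (n=20, L=100, min_clip=11, dx=10) the rate is
~8.3e-4, well below 5%.  The model deliberately ignores mapping failure of
junction reads, which in real data is the dominant loss mode; it is a lower
bound on what any clip-pairing scheme can achieve, not a forecast.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `min_clip` | 11 | bases | clips of 10 and below are routine alignment noise; collection keeps clips > 10 |
| `min_overlap` | 28 | bases | the common string merges two reads, so this acts like an aligner seed length; lowering it inflates chance pairings |
| `max_mismatch_frac` | 0.08 | fraction | mismatch tolerance inside the common string and in the merged-read filters |
| `search_window` | 2,000,000 | bases | largest POS distance across which reads are paired; bounds detectable CNV span; ~20,000 suits exome capture data |
| `min_support` | 2 | read pairs | more than one distinct supporting pair per call |
| `flank` | 1000 | bases | flank width of the depth-ratio validation statistic |
| `min_mapq` | 0 | — | no mapping-quality floor by default; exposed for noisy data |

## Read classification edge policy

Unmapped, secondary, supplementary and duplicate records are skipped.  A
read clipped at both ends takes its orientation from the larger clip; the
smaller clip is trimmed from the sequence so every downstream formula sees
exactly (matched part + one clip).  Equal clips are orientation-ambiguous
and rejected.  A dominant clip *longer* than the matched part is rejected
outright: it is the signature of an aligner anchoring the short side of a
junction read (a paired-end artifact), and there is no way to validate it;
these records are also what the simulator's misanchored-read option emits.
Dominant hard clips make a read unusable (the clipped sequence is absent).
Reads failing these rules are never salvaged via mate information.

## The simulator and what it does not emulate

The generator draws an i.i.d. random reference at a requested GC content,
locally rewrites it so each CNV's junction homology is *exact* (including
h = 0) and the implanted `(a, b)` is the canonical leftmost pair, and emits
single-end SAM records with the clip conventions above, sampling read
starts uniformly on the chosen allele (variant, reference, or a 50/50
heterozygous mix).  Junction records are emitted against the rightmost
equivalent pair, which is the only convention under which the SM record's
matched segment equals the reference at its POS — this mirrors maximal
matched-run extension by real aligners.  Per-base substitution errors are
i.i.d.; an optional fraction of misanchored records exercises the
classifier's rejection path.

Not emulated: position-dependent quality and error profiles, indel errors,
paired-end insert sizes, mapping ambiguity in genomic repeats, capture
bias.  Passing round-trip tests therefore demonstrates the correctness of
the breakpoint arithmetic, refinement, filters and bookkeeping — not
robustness to the mapping difficulties that dominate real-data losses.

## Problem sizes used in the tests

Round-trip and homology-recovery checks use 50 and 20 single-CNV datasets
on 7–8 kb contigs with 3 MS + 3 SM junction reads; oracle-equivalence runs
20 datasets on <= 5 kb contigs at 10x so the quadratic brute-force oracle
stays cheap; the failure-model cross-check uses 10^6 Monte-Carlo replicates
per grid point and 500 end-to-end replicates at n = 6 junction reads.
These sizes were chosen so the full suite completes in seconds while every
stage is still exercised end to end through real FASTA/SAM files.

## Known limitations

* Inter-chromosomal events, random insertions and zygosity inference are
  out of scope; the caller types every junction as DEL or DUP by the sign
  of `b - a` alone.
* Reads whose alignments contain internal indels participate with
  generalized `ref_span`, but the Hamming-based filters implicitly assume
  substitution-only errors within compared windows.
* The depth-ratio statistic is a validation aid, not a genotyper: it
  reports mean inside/flank coverage and returns missing when flanks are
  uncovered.
* All candidate (MS, SM) pairs within the search window are tested, which
  is quadratic per window; fine at the clip densities of real data, but a
  clip-dense pathological input would be slow.
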