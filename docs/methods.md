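# Methods notes

These notes document the models and procedures the package implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic fixtures do and do not establish
about real data.

## The minimum unique length model

For a reference `S` (a set of named sequences) and a position `p` on
sequence `s`, define

```
MUL(p) = min { L ∈ [kmin, min(kmax, |s| − p)] : occ(s[p : p+L]) = 1 }
```

with `MUL(p) = 0` when the set is empty. `occ(q)` counts exact alignments
of `q` across all sequences; by default both strands are counted, one per
(sequence, position, strand) triple. Three consequences worth spelling
out:

- **Palindromes.** A palindromic read matches the same locus once per
  strand and is therefore never unique under both-strand counting. This
  mirrors per-strand alignment reporting in exact short-read aligners; a
  `forward_only` mode is available where the distinction matters
  (bisulfite tracks use it).
- **Ambiguous bases.** Any window containing a non-A/C/G/T base has
  `occ = 0` and can never become unique. Soft-masked lowercase is folded to
  uppercase rather than excluded.
- **Monotonicity.** Extending a read can only lose occurrences, and a read
  always matches at its own position, so `occ` is non-increasing in `L`
  with `occ ≥ 1`; once unique, always unique (while the read fits). The
  test suite audits this rather than assuming it: at every nonzero value
  `m`, the count at `m` is 1 and at `m − 1` is ≥ 2.

**Length range.** Defaults `kmin = 20`, `kmax = 255`. The upper bound is
the largest value a one-byte track can store; the lower bound reflects
that sequencing reads shorter than 20 nt are rare. Two-byte tracks
(little-endian) extend the range to 65535 for long-read applications.

**Search strategy.** Per position the implementation brackets instead of
scanning: probe the longest fitting length (failure ⇒ 0), probe `kmin`
(success ⇒ `kmin`), then ascend in steps of 25 until uniqueness appears
between a known-non-unique `k_low` and a known-unique `k_high`, and scan
that bracket linearly. The step size is a pure performance knob (default
25 balances probe counts at typical read lengths); the output is proven
identical to the brute-force definition for every step size, and to an
independent per-length tabulation oracle on randomized genomes.

**Occurrence queries.** The "index" is a set of uppercased sequences
queried by C-speed substring scans with early termination (uniqueness
probes only need to distinguish 0/1/≥2). At the scales this package
targets (fixtures to tens of kilobases) scans beat building a suffix
array; the structure is deliberately replaceable since all consumers go
through `count_occurrences`/`find_occurrences`.

## Binary track format

One file per sequence, `position i` at byte offset `i × width`,
little-endian for width 2; file size is exactly `length × width`. The
binary payload is not self-describing, so a JSON sidecar stores the
sequence name, length, `kmin`/`kmax`, mode, width and build label, and
queries use it to reject read lengths below `kmin`. Read lengths above
`kmax` are capped with a warning rather than rejected: a stored 0 is
ambiguous between "needs more than kmax" and "never unique", and the
capped answer is the only one the track can honestly give.

**Proportion-unique denominators.** Whether trailing positions that cannot
host a full read belong in the denominator is a genuine convention choice.
Both are exposed; the default `fitting` counts only start positions from
which a whole read fits inside the region (clipped to the sequence),
matching how reads are physically generated from a transcript. `all`
divides by every position and is the convention under which the proportion
is provably non-decreasing in read length.

## Bisulfite tracks

Full conversion is modelled on the reference: C→T for the forward strand,
G→A (= revcomp ∘ C→T ∘ revcomp) for the reverse. Because the converted
strands are no longer reverse complements, each strand gets its own track.
A position is unique at `L` iff its converted read (a) occurs exactly
once, forward orientation, in its own strand's converted genome, and
(b) occurs zero times in the other strand's converted genome. For (b) the
orientation convention is not forced by the procedure it models (the
second-pass mapping allows either orientation); the default checks both
orientations — the conservative choice — with `crosscheck_orientation=
"forward"` available.

A consequence worth knowing: a genome with neither C nor G converts to
itself on both strands, so rule (b) removes every read and the track is
all zero. More generally, conversion only merges k-mers, so bisulfite
uniqueness can never exceed plain forward-only genome uniqueness at any
position — the direction asserted by the degradation tests.

## Transcriptome tracks

Spliced transcript sequences (exons concatenated, reverse-complemented for
minus-strand transcripts) are indexed *together with* the genome, so
junction-spanning reads are first-class. Every occurrence of a read is
collapsed to genomic coordinates — leftmost aligned base to one past the
rightmost, introns not subtracted, since only start/end identity matters —
and genomically identical footprints from different sources are
deduplicated. Uniqueness is then:

- **gene level**: all footprints share a start *or* share an end (one
  locus, any isoform);
- **transcript level, coordinate rule** (default): exactly one distinct
  start *and* one distinct end;
- **transcript level, single-source rule**: additionally at most one
  distinct source transcript.

The two transcript rules differ exactly for reads whose hits in several
isoforms collapse to identical genomic coordinates (e.g. a read inside an
exon shared with identical boundaries). Which of the two a given analysis
wants depends on whether "identifies one transcript" is read
coordinate-wise or annotation-wise; both are implemented and tested, the
coordinate rule is the default. Transcript-level uniqueness implies
gene-level uniqueness under either rule, and the hierarchy (gene-level MUL
≤ transcript-level MUL positionwise; transcript-level unique set ⊆
gene-level unique set) is asserted over randomized fixtures.

Because the engine enumerates *all* occurrences, no cap on alignments per
read is needed; the per-transcript overlap count (`count_overlaps`) is
kept as a diagnostic of how many alignments a within-annotation read can
have (overlaps + 1 genomic hit).

## Paired-end effective lengths

Fragment lengths are drawn from Normal(mean, sd); defaults mean 250 nt,
sd 25 nt, 5 draws per start position. Draws are rounded to the nearest
integer; fragments with length < 1 or extending past the transcript are
discarded and do not enter the denominator. The insert window passed to
pairing is mean ± 3 sd (175–325 at the defaults), covering 99.7% of the
distribution. Each surviving fragment's mates (first `L` bases; reverse
complement of the last `L`) are located like any other read; candidate
pairings must sit on one target in forward–reverse orientation with the
implied span inside the insert window and strictly longer than the read
(completely overlapping mates are discarded, so fragments no longer than
the read length count as non-mappable rather than raising). Candidate
spans are collapsed to genomic coordinates, deduplicated, and judged by
the gene-level rule. The per-transcript table reports
`effective_length = spliced_length × unique / total` per read length, with
one fragment set shared across read lengths.

Randomness is drawn from a stream keyed by (seed, crc32(transcript id),
position), so results are independent of iteration order, chunking, and
transcript set composition. Transcripts too short to fit any fragment
yield proportion 0 with a warning — the estimate is undefined and 0 is the
conservative report.

## Quantification

Reads are assigned to a gene when their 5′-most aligned base (reference
start for forward reads, `reference_end − 1` for reverse) falls in the
gene's exon union — the same anchor the MUL definition uses for read
starts. The depth denominator counts every uniquely mapped read in the
file, assigned or not. Exonic bases covered by two or more distinct gene
ids can be removed from all of them (`rmnameoverlap`, default on) so
ambiguous exons neither attract reads nor inflate lengths; a gene whose
model empties out is dropped with a warning. Genes with effective length 0
are reported as unquantifiable rather than given an infinite RPKM.

For fixed counts, `norm_rpkm / raw_rpkm = raw_length / effective_length =
1/u` holds algebraically; the end-to-end tests assert it to machine
precision and additionally check *parameter recovery*: with reads placed
uniformly at a planted depth and filtered by uniqueness, the corrected
RPKM matches the planted expression within 3 binomial standard errors of
the kept-read count.

## Synthetic fixtures: what they do and do not show

The generator emits i.i.d. A/C/G/T chromosomes with exact-copy planted
repeat families, annotations with known shared/private exon structure or
paralog duplications, and uniform unique-only read sets — all pure
functions of a seed, with ground truth emitted alongside. Problem sizes
used throughout the tests and the acceptance script (kilobase-scale
chromosomes, `kmax ≤ 64`, thousands of reads or fragments) were chosen so
the whole suite runs comfortably on a laptop while still mixing unique,
repeat-shadowed and edge positions.

What passing these tests shows: the implementation computes the MUL
definition exactly; the format round-trips; the uniqueness hierarchies and
degradation directions hold; the RPKM correction mechanism is exact and
recovers planted truth. What they do not show: behaviour on real genomes —
real repeats are inexact and nested, GC content is not uniform, real
annotations contain overlapping genes on both strands at rates the
fixtures only sample, and real libraries have non-Gaussian inserts and
sequencing errors (errors are ignored here by design: uniqueness files
model exact matching, and unique-best-alignment filtering upstream plays
that role for real data). Genome-scale magnitudes (storage, fraction of
transcripts above a mappability threshold, counts of genes whose RPKM
shifts two-fold) depend on those properties and are not claimed by any
test in this package.

## Known limitations

- No mismatch-tolerant uniqueness: a deliberately excluded variant —
  requiring positions to be unique *and* distant from the rest of the
  genome is overly conservative for unique-best-alignment pipelines.
- No genome-wide paired-end MUL files: a per-position minimum does not
  exist when uniqueness depends on a random fragment length; only
  per-transcript tables are produced.
- The occurrence engine is exact-match and in-memory; chromosome-scale
  inputs work but are slow in pure Python. The module boundary
  (`genome_index`) is the intended replacement point for an FM-index.
- BED12 carries no gene id; the record name doubles as gene and transcript
  id, so isoform grouping across BED12 records requires refFlat input.
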