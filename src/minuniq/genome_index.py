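"""Exact-match occurrence queries over a set of named DNA sequences.

This is the uniqueness oracle underlying every mappability computation in
the package: a read (substring) is "uniquely mappable" when it has exactly
one exact alignment across the indexed sequences, counting both strands by
default.  Matching mirrors an exact short-read aligner run with unique-only
reporting and zero mismatches: soft-masked lowercase is folded to upper
case, and any window containing an ambiguous base (N or another IUPAC
degeneracy code) can never be matched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Occurrence",
    "OccurrenceIndex",
    "build_index",
    "count_occurrences",
    "find_occurrences",
    "revcomp",
    "read_fasta",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Full IUPAC nucleotide alphabet accepted at build time.  Only A/C/G/T can
# ever participate in a match; the rest behave like N (unmatchable).
_IUPAC = frozenset("ACGTNRYSWKMBDHV")
_UNAMBIGUOUS = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Occurrence:
    """One exact alignment of a query.

    ``position`` is the 0-based offset of the match on the forward
    representation of ``seq_name``; ``strand`` is ``"-"`` when the reverse
    complement of the query matches the forward sequence there.
    """

    seq_name: str
    position: int
    strand: str


class OccurrenceIndex:
    """Queryable substring-occurrence oracle over named sequences.

    Sequences are stored uppercased.  The "index" is deliberately plain —
    occurrence queries are answered by C-speed substring scans, which is
    exact, allocation-free and fast at the scales this package targets.
    """

    def __init__(self, sequences: Mapping[str, str] | Iterable[tuple[str, str]]):
        pairs = sequences.items() if isinstance(sequences, Mapping) else list(sequences)
        seqs: dict[str, str] = {}
        for name, seq in pairs:
            if name in seqs:
                raise ValueError(f"duplicate sequence name: {name!r}")
            upper = seq.upper()
            bad = set(upper) - _IUPAC
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains non-IUPAC character {sorted(bad)[0]!r}"
                )
            seqs[name] = upper
        if not seqs or all(len(s) == 0 for s in seqs.values()):
            raise ValueError("index requires at least one non-empty sequence")
        self.sequences: dict[str, str] = seqs
        self.total_length: int = sum(len(s) for s in seqs.values())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"OccurrenceIndex({len(self.sequences)} sequences, "
            f"{self.total_length} bp)"
        )

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def length(self, seq_name: str) -> int:
        return len(self.sequences[seq_name])


def build_index(sequences: Mapping[str, str] | Iterable[tuple[str, str]]) -> OccurrenceIndex:
    """Build an :class:`OccurrenceIndex` from named DNA strings."""
    return OccurrenceIndex(sequences)


def _scan(haystack: str, needle: str) -> Iterator[int]:
    """Yield all (overlapping) match offsets of ``needle`` in ``haystack``."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def _iter_occurrences(
    index: OccurrenceIndex, query: str, strand_mode: str
) -> Iterator[Occurrence]:
    if not query:
        raise ValueError("query must be non-empty")
    if strand_mode not in ("both", "forward_only"):
        raise ValueError(f"unknown strand_mode: {strand_mode!r}")
    q = query.upper()
    if set(q) - _UNAMBIGUOUS:
        return  # ambiguous bases never match
    rc = revcomp(q) if strand_mode == "both" else None
    for name, seq in index.sequences.items():
        hits: list[Occurrence] = []
        for pos in _scan(seq, q):
            hits.append(Occurrence(name, pos, "+"))
        if rc is not None:
            for pos in _scan(seq, rc):
                hits.append(Occurrence(name, pos, "-"))
        hits.sort()
        yield from hits


def count_occurrences(
    index: OccurrenceIndex,
    query: str,
    strand_mode: str = "both",
    limit: int | None = None,
) -> int:
    """Count exact alignments of ``query`` across the index.

    Each (sequence, position, strand) triple counts once, so a palindromic
    query matching one locus on both strands counts twice — the per-strand
    convention of exact aligners, which makes fully palindromic k-mers
    non-unique.  ``limit`` allows early exit once that many occurrences have
    been seen (uniqueness probes only need to distinguish 0 / 1 / >=2).
    """
    n = 0
    for _ in _iter_occurrences(index, query, strand_mode):
        n += 1
        if limit is not None and n >= limit:
            return n
    return n


def find_occurrences(
    index: OccurrenceIndex, query: str, strand_mode: str = "both"
) -> list[Occurrence]:
    """All exact alignments of ``query``, sorted by (seq_name, position, strand)."""
    return sorted(_iter_occurrences(index, query, strand_mode))


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly wrapped, soft-masked) FASTA file into a name->sequence dict."""
    import pyfaidx

    with pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}
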