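"""Per-position minimum unique length (MUL) computation.

The MUL of a genomic coordinate is the length of the shortest read starting
at that coordinate that aligns to exactly one location in the reference.
Storing this single number per base describes mappability for *every* read
length at once: a position is uniquely mappable at read length L iff
``0 < MUL <= L``.  Value 0 means the position is never unique within the
queried length range (or no read of at least ``kmin`` bases fits before the
sequence end).

Uniqueness is monotone for exact matching — extending a read can only lose
occurrences, and the read always matches at its own position — so the
smallest unique length is found by bracketing: probe the largest fitting
length (no uniqueness there means 0), probe ``kmin``, then ascend in fixed
steps until uniqueness appears between a known-non-unique ``k_low`` and a
known-unique ``k_high``, and finally scan that bracket linearly.  The
result is identical to evaluating every (position, length) pair directly.

Bisulfite-converted references are handled by converting reads and genome
alike (C->T for the forward strand, G->A for the reverse strand) and
requiring a read to be unique on its own converted strand while absent
from the other strand's converted genome — the two strands are no longer
reverse complements after conversion, so each gets its own MUL track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .genome_index import OccurrenceIndex, build_index, count_occurrences

__all__ = [
    "MULArray",
    "compute_mul_array",
    "convert_bisulfite",
    "compute_bisulfite_mul",
    "DEFAULT_KMIN",
    "DEFAULT_KMAX",
    "DEFAULT_STEP",
]

DEFAULT_KMIN = 20
DEFAULT_KMAX = 255
#: ascent step of the bracketing search; any positive value gives the same
#: MUL array, this default just balances probe counts at typical read lengths
DEFAULT_STEP = 25

MODES = (
    "genome",
    "bisulfite_fw",
    "bisulfite_rv",
    "transcript_gene_level",
    "transcript_level",
)


@dataclass
class MULArray:
    """Minimum-unique-length values for one sequence.

    ``values[p]`` is the smallest read length in ``[kmin, kmax]`` for which
    the read starting at p is unique, or 0 if none is.
    """

    seq_name: str
    values: np.ndarray
    kmin: int = DEFAULT_KMIN
    kmax: int = DEFAULT_KMAX
    mode: str = "genome"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.mode not in MODES:
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.kmin < 1 or self.kmax < self.kmin:
            raise ValueError(f"invalid length range [{self.kmin}, {self.kmax}]")
        v = self.values
        bad = v[(v != 0) & ((v < self.kmin) | (v > self.kmax))]
        if bad.size:
            raise ValueError(
                f"MUL value {int(bad[0])} outside {{0}} U [{self.kmin}, {self.kmax}]"
            )

    def __len__(self) -> int:
        return len(self.values)

    def unique_at(self, read_length: int) -> np.ndarray:
        """Boolean mask of positions uniquely mappable at ``read_length``."""
        return (self.values > 0) & (self.values <= read_length)


def _bracket_search(
    is_unique: Callable[[int, int], bool],
    n: int,
    kmin: int,
    kmax: int,
    step: int,
) -> np.ndarray:
    """Smallest unique length per position for a monotone uniqueness predicate."""
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    if kmax < kmin:
        raise ValueError("kmax must be >= kmin")
    if step < 1:
        raise ValueError("step must be >= 1")
    values = np.zeros(n, dtype=np.int64)
    for p in range(n):
        l_max = min(kmax, n - p)
        if l_max < kmin:
            continue  # no read of length >= kmin fits
        if not is_unique(p, l_max):
            continue  # not unique even at the longest fitting read
        if is_unique(p, kmin):
            values[p] = kmin
            continue
        k_low = kmin  # known non-unique
        k = kmin + step
        while k < l_max and not is_unique(p, k):
            k_low = k
            k += step
        k_high = min(k, l_max)  # known unique
        for length in range(k_low + 1, k_high + 1):
            if is_unique(p, length):
                values[p] = length
                break
    return values


def compute_mul_array(
    index: OccurrenceIndex,
    seq_name: str,
    kmin: int = DEFAULT_KMIN,
    kmax: int = DEFAULT_KMAX,
    strand_mode: str = "both",
    step: int = DEFAULT_STEP,
) -> MULArray:
    """Compute the genome-mode MUL array for one indexed sequence.

    ``values[p]`` is the smallest L in ``[kmin, min(kmax, len - p)]`` such
    that ``seq[p:p+L]`` occurs exactly once in the index under
    ``strand_mode``, else 0.  Windows containing ambiguous bases are never
    unique.
    """
    if seq_name not in index:
        raise KeyError(f"unknown sequence: {seq_name!r}")
    seq = index.sequences[seq_name]

    def is_unique(p: int, length: int) -> bool:
        return (
            count_occurrences(index, seq[p : p + length], strand_mode, limit=2) == 1
        )

    values = _bracket_search(is_unique, len(seq), kmin, kmax, step)
    return MULArray(seq_name, values, kmin=kmin, kmax=kmax, mode="genome")


def convert_bisulfite(sequence: str, strand: str) -> str:
    """Fully bisulfite-convert a reference sequence for one strand.

    Forward strand (``"fw"``): every C becomes T.  Reverse strand
    (``"rv"``): every G becomes A, which equals reverse-complementing,
    converting C->T, and reverse-complementing back.
    """
    if strand == "fw":
        return sequence.upper().replace("C", "T")
    if strand == "rv":
        return sequence.upper().replace("G", "A")
    raise ValueError(f"strand must be 'fw' or 'rv', got {strand!r}")


def compute_bisulfite_mul(
    genome: Mapping[str, str],
    strand: str = "fw",
    kmin: int = DEFAULT_KMIN,
    kmax: int = DEFAULT_KMAX,
    step: int = DEFAULT_STEP,
    crosscheck_orientation: str = "both",
) -> dict[str, MULArray]:
    """Per-sequence MUL arrays for a bisulfite-converted genome strand.

    A fully converted read from strand ``fw`` at position p is unique at
    length L iff it occurs exactly once, forward orientation only, in the
    fw-converted genome AND does not occur in the rv-converted genome
    (symmetrically for ``rv``).  ``crosscheck_orientation`` controls
    whether the second, exclusion check considers both orientations of the
    other-strand genome (default, conservative) or its forward orientation
    only.
    """
    if strand not in ("fw", "rv"):
        raise ValueError(f"strand must be 'fw' or 'rv', got {strand!r}")
    if crosscheck_orientation not in ("both", "forward"):
        raise ValueError(
            f"crosscheck_orientation must be 'both' or 'forward', got "
            f"{crosscheck_orientation!r}"
        )
    other = "rv" if strand == "fw" else "fw"
    own_seqs = {name: convert_bisulfite(seq, strand) for name, seq in genome.items()}
    other_seqs = {name: convert_bisulfite(seq, other) for name, seq in genome.items()}
    own_index = build_index(own_seqs)
    other_index = build_index(other_seqs)
    cross_mode = "both" if crosscheck_orientation == "both" else "forward_only"

    mode = f"bisulfite_{strand}"
    out: dict[str, MULArray] = {}
    for name, conv in own_seqs.items():

        def is_unique(p: int, length: int, conv: str = conv) -> bool:
            read = conv[p : p + length]
            if count_occurrences(own_index, read, "forward_only", limit=2) != 1:
                return False
            return count_occurrences(other_index, read, cross_mode, limit=1) == 0

        values = _bracket_search(is_unique, len(conv), kmin, kmax, step)
        out[name] = MULArray(name, values, kmin=kmin, kmax=kmax, mode=mode)
    return out
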