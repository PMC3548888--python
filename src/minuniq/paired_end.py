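"""Paired-end mappability by Gaussian fragment simulation.

A single minimum unique length per position does not exist for paired-end
data: whether a mate pair maps uniquely depends on the fragment (insert)
length, which varies within a library.  Instead, mappability is estimated
per transcript: fragment lengths are drawn from a Normal(mean, sd) at
every start position (5 draws per position by default, defaults mean 250,
sd 25), fragments whose end falls outside the transcript are discarded,
and each surviving fragment's two mates are aligned like any other read.
Valid pairings must be forward-reverse oriented on the same target with an
implied fragment span inside ``[mean - 3 sd, mean + 3 sd]`` — the bounds a
paired-end aligner would be given, covering 99.7% of the distribution.
A fragment is uniquely mapped when its candidate spans, collapsed to
genomic coordinates, identify a single locus under the gene-level rule
(shared span start or shared span end).

The per-transcript summary is an effective-length table:
``effective_length = spliced_length x unique_fragments / all_fragments``.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_index import OccurrenceIndex, find_occurrences, revcomp
from .transcriptome import CollapsedAlignment, TranscriptModel, classify_read

__all__ = [
    "FragmentConfig",
    "sample_fragment_lengths",
    "simulate_fragments",
    "pair_is_unique",
    "estimate_effective_lengths",
]


@dataclass(frozen=True)
class FragmentConfig:
    """Gaussian fragment-length model and simulation settings.

    ``insert_min``/``insert_max`` default to mean +/- 3 sd, the bounds
    passed to the pairing step; 99.7% of draws fall inside them.
    """

    mean: float = 250.0
    sd: float = 25.0
    draws_per_position: int = 5
    seed: int = 0
    insert_min: float = field(default=None)  # type: ignore[assignment]
    insert_max: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.draws_per_position < 1:
            raise ValueError("draws_per_position must be >= 1")
        if self.insert_min is None:
            object.__setattr__(self, "insert_min", self.mean - 3 * self.sd)
        if self.insert_max is None:
            object.__setattr__(self, "insert_max", self.mean + 3 * self.sd)
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min exceeds insert_max")


def _position_rng(config: FragmentConfig, transcript_id: str, position: int) -> np.random.Generator:
    # stream keyed by (seed, transcript, position): results do not depend on
    # iteration order or chunking
    tag = zlib.crc32(transcript_id.encode())
    return np.random.default_rng([config.seed, tag, position])


def sample_fragment_lengths(
    position: int, config: FragmentConfig, transcript_id: str = ""
) -> np.ndarray:
    """Raw (unrounded) Gaussian length draws for one start position."""
    rng = _position_rng(config, transcript_id, position)
    return rng.normal(config.mean, config.sd, config.draws_per_position)


def simulate_fragments(
    transcript_length: int, config: FragmentConfig, transcript_id: str = ""
) -> list[tuple[int, int]]:
    """Simulate candidate fragments as (start, length) pairs.

    For every start position, ``draws_per_position`` lengths are drawn from
    Normal(mean, sd) and rounded to the nearest integer; fragments whose
    end falls outside the transcript, or with length < 1, are discarded.
    Deterministic for a given seed.
    """
    if transcript_length < 1:
        raise ValueError("transcript_length must be >= 1")
    fragments: list[tuple[int, int]] = []
    for p in range(transcript_length):
        for raw in sample_fragment_lengths(p, config, transcript_id):
            length = int(np.rint(raw))
            if length >= 1 and p + length <= transcript_length:
                fragments.append((p, length))
    return fragments


def _candidate_spans(
    index: OccurrenceIndex,
    mate1: str,
    mate2: str,
    read_length: int,
    config: FragmentConfig,
    models: Mapping[str, TranscriptModel] | None,
) -> list[CollapsedAlignment]:
    occ1 = find_occurrences(index, mate1, "both")
    occ2 = find_occurrences(index, mate2, "both")
    spans: list[CollapsedAlignment] = []
    for o1 in occ1:
        for o2 in occ2:
            if o1.seq_name != o2.seq_name or o1.strand == o2.strand:
                continue
            plus, minus = (o1, o2) if o1.strand == "+" else (o2, o1)
            if plus.position > minus.position:
                continue  # mates must point toward each other
            start = plus.position
            end = minus.position + read_length
            span = end - start
            if span <= read_length:
                continue  # complete mate overlap is discarded
            if not (config.insert_min <= span <= config.insert_max):
                continue
            model = None if models is None else models.get(o1.seq_name)
            if model is None:
                spans.append(CollapsedAlignment(o1.seq_name, start, end))
            else:
                a = model.genomic_position(start)
                b = model.genomic_position(end - 1)
                lo, hi = (a, b + 1) if a <= b else (b, a + 1)
                spans.append(
                    CollapsedAlignment(model.chrom, lo, hi, source=model.transcript_id)
                )
    seen = {}
    for s in spans:
        seen.setdefault((s.chrom, s.genomic_start, s.genomic_end), s)
    return list(seen.values())


def pair_is_unique(
    index: OccurrenceIndex,
    spliced_seq: str,
    fragment: tuple[int, int],
    read_length: int,
    config: FragmentConfig,
    models: Mapping[str, TranscriptModel] | None = None,
) -> bool:
    """Whether one simulated fragment's mate pair maps uniquely.

    mate1 is the first ``read_length`` bases of the fragment on the
    spliced sequence, mate2 the reverse complement of its last
    ``read_length`` bases.  Candidate mappings are forward-reverse
    occurrence pairs on one target with span inside the insert bounds;
    after collapsing to genomic coordinates and deduplicating spans, the
    pair is unique iff the spans identify one locus (gene-level rule).
    Fragments no longer than the read are non-mappable: the mates would
    overlap completely, which aligners discard.
    """
    start, flen = fragment
    if flen <= read_length:
        return False
    if start < 0 or start + flen > len(spliced_seq):
        raise ValueError("fragment outside transcript")
    frag = spliced_seq[start : start + flen]
    mate1 = frag[:read_length]
    mate2 = revcomp(frag[-read_length:])
    spans = _candidate_spans(index, mate1, mate2, read_length, config, models)
    return classify_read(spans) in ("transcript_unique", "gene_unique")


def estimate_effective_lengths(
    index: OccurrenceIndex,
    transcripts: Mapping[str, str],
    read_lengths: Sequence[int],
    config: FragmentConfig,
    models: Mapping[str, TranscriptModel] | None = None,
) -> pd.DataFrame:
    """Per-transcript paired-end effective length table.

    One fragment set is simulated per transcript and reused across all
    requested read lengths.  Columns: transcript_id, read_length,
    fragments_total, fragments_unique, unique_proportion,
    effective_length (= spliced length x unique / total).
    ``fragments_total`` counts fragments that fit inside the transcript;
    fragments shorter than or equal to the read count as non-unique.
    """
    if not read_lengths:
        raise ValueError("read_lengths must be non-empty")
    for rl in read_lengths:
        if rl >= config.insert_max:
            raise ValueError(
                f"read_length {rl} not below insert_max {config.insert_max}"
            )
    rows = []
    for tid, seq in transcripts.items():
        fragments = simulate_fragments(len(seq), config, tid)
        total = len(fragments)
        if total == 0:
            warnings.warn(
                f"{tid}: no simulated fragment fits (length {len(seq)} vs mean "
                f"{config.mean}); reporting proportion 0"
            )
        for rl in read_lengths:
            unique = sum(
                pair_is_unique(index, seq, frag, rl, config, models)
                for frag in fragments
            )
            proportion = unique / total if total else 0.0
            rows.append(
                {
                    "transcript_id": tid,
                    "read_length": rl,
                    "fragments_total": total,
                    "fragments_unique": unique,
                    "unique_proportion": proportion,
                    "effective_length": len(seq) * proportion,
                }
            )
    return pd.DataFrame(rows)
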