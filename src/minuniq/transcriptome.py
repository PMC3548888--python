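"""Spliced-transcript mappability: sequences, coordinate maps, and
gene- vs transcript-level minimum unique lengths.

Reads from spliced mRNA must be unique in the genome *and* the
transcriptome, and exon-exon junction reads exist only on spliced
sequences.  The approach indexes the genome together with every spliced
transcript sequence, finds all occurrences of a read, converts transcript
hits back to genomic coordinates, and then asks whether the surviving
alignment set identifies one locus (gene level) or one transcript
(transcript level):

* gene level — all alignments share a genomic start OR share a genomic end
  (reads hitting several isoforms of one locus at the same genomic
  position still count as unique);
* transcript level (coordinate rule, default) — exactly one distinct
  genomic start AND one distinct end;
* transcript level (``single_source`` rule) — additionally at most one
  distinct source transcript.  The two transcript rules differ exactly for
  reads whose alignments in several isoforms collapse to identical genomic
  coordinates; both are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_index import OccurrenceIndex, build_index, find_occurrences, revcomp
from .mul_core import (
    DEFAULT_KMAX,
    DEFAULT_KMIN,
    DEFAULT_STEP,
    MULArray,
    _bracket_search,
)

__all__ = [
    "TranscriptModel",
    "CollapsedAlignment",
    "parse_annotation",
    "extract_spliced_sequence",
    "transcript_to_genomic",
    "classify_read",
    "build_combined_index",
    "compute_transcript_mul",
    "count_overlaps",
    "write_refflat",
    "write_bed12",
]


@dataclass(frozen=True)
class TranscriptModel:
    """Stranded exon structure of one transcript.

    Exons are genomic half-open ``(start, end)`` intervals, sorted by
    start and non-overlapping.  Transcript coordinate 0 is the 5' end of
    the mRNA: for strand ``-`` it maps to the *largest* genomic coordinate
    of the exon union.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(
                    f"{self.transcript_id}: empty or inverted exon ({start}, {end})"
                )
            if start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    def genomic_position(self, offset: int) -> int:
        """Genomic coordinate of transcript base ``offset`` (0-based, 5'->3')."""
        n = self.spliced_length
        if not 0 <= offset < n:
            raise IndexError(
                f"{self.transcript_id}: offset {offset} outside [0, {n})"
            )
        if self.strand == "-":
            offset = n - 1 - offset
        for start, end in self.exons:
            size = end - start
            if offset < size:
                return start + offset
            offset -= size
        raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class CollapsedAlignment:
    """A read alignment expressed in genomic coordinates.

    ``genomic_start`` is the genomic coordinate of the read's leftmost
    aligned base and ``genomic_end`` one past its rightmost, regardless of
    strand or intervening introns.  ``source`` names the transcript the
    alignment was found on, or ``"genome"``.
    """

    chrom: str
    genomic_start: int
    genomic_end: int
    source: str = "genome"

    def __post_init__(self) -> None:
        if self.genomic_start >= self.genomic_end:
            raise ValueError("alignment start must precede end")


def transcript_to_genomic(
    transcript: TranscriptModel, offset: int, length: int
) -> CollapsedAlignment:
    """Collapse a transcript-coordinate read to genomic start/end.

    The reported interval runs from the genomic coordinate of the read's
    leftmost base to one past its rightmost (start < end even for strand
    ``-``, where transcript base 0 is the rightmost genomic base).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if offset < 0 or offset + length > transcript.spliced_length:
        raise IndexError(
            f"{transcript.transcript_id}: read [{offset}, {offset + length}) "
            f"outside spliced length {transcript.spliced_length}"
        )
    a = transcript.genomic_position(offset)
    b = transcript.genomic_position(offset + length - 1)
    start, end = (a, b + 1) if a <= b else (b, a + 1)
    return CollapsedAlignment(
        transcript.chrom, start, end, source=transcript.transcript_id
    )


# ---------------------------------------------------------------------------
# annotation parsing / writing


def _parse_int_list(text: str, path, lineno: int, label: str) -> list[int]:
    try:
        return [int(x) for x in text.rstrip(",").split(",") if x != ""]
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: bad {label}: {exc}") from None


def parse_annotation(path, format: str = "refFlat") -> list[TranscriptModel]:
    """Parse transcript models from a refFlat or BED12 file.

    refFlat columns: geneName, name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds (0-based half-open).
    BED12 block coordinates are relative to chromStart.  For BED12 the
    record name serves as both transcript and gene identifier.
    """
    if format not in ("refFlat", "BED12"):
        raise ValueError(f"unknown annotation format: {format!r}")
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "refFlat":
                    if len(fields) < 11:
                        raise ValueError("fewer than 11 refFlat fields")
                    gene, name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
                    n_exons = int(fields[8])
                    starts = _parse_int_list(fields[9], path, lineno, "exonStarts")
                    ends = _parse_int_list(fields[10], path, lineno, "exonEnds")
                    if len(starts) != n_exons or len(ends) != n_exons:
                        raise ValueError(
                            f"exonCount={n_exons} but {len(starts)} starts / "
                            f"{len(ends)} ends"
                        )
                    exons = tuple(zip(starts, ends))
                else:
                    if len(fields) < 12:
                        raise ValueError("fewer than 12 BED12 fields")
                    chrom, strand = fields[0], fields[5]
                    chrom_start = int(fields[1])
                    name = gene = fields[3]
                    n_blocks = int(fields[9])
                    sizes = _parse_int_list(fields[10], path, lineno, "blockSizes")
                    offsets = _parse_int_list(fields[11], path, lineno, "blockStarts")
                    if len(sizes) != n_blocks or len(offsets) != n_blocks:
                        raise ValueError(
                            f"blockCount={n_blocks} but {len(sizes)} sizes / "
                            f"{len(offsets)} starts"
                        )
                    exons = tuple(
                        (chrom_start + off, chrom_start + off + size)
                        for off, size in zip(offsets, sizes)
                    )
                models.append(TranscriptModel(name, gene, chrom, strand, exons))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return models


def write_refflat(transcripts: Iterable[TranscriptModel], path) -> None:
    """Write transcript models as a refFlat file (CDS spans the full transcript)."""
    with open(path, "w") as fh:
        for t in transcripts:
            starts = ",".join(str(s) for s, _ in t.exons) + ","
            ends = ",".join(str(e) for _, e in t.exons) + ","
            fh.write(
                "\t".join(
                    [
                        t.gene_id,
                        t.transcript_id,
                        t.chrom,
                        t.strand,
                        str(t.tx_start),
                        str(t.tx_end),
                        str(t.tx_start),
                        str(t.tx_end),
                        str(len(t.exons)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


def write_bed12(transcripts: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            offsets = ",".join(str(s - t.tx_start) for s, _ in t.exons) + ","
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.tx_start),
                        str(t.tx_end),
                        t.transcript_id,
                        "0",
                        t.strand,
                        str(t.tx_start),
                        str(t.tx_end),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# sequences and uniqueness


def extract_spliced_sequence(
    genome: Mapping[str, str] | OccurrenceIndex, transcript: TranscriptModel
) -> str:
    """Spliced transcript sequence, reverse-complemented for strand ``-``."""
    seqs = genome.sequences if isinstance(genome, OccurrenceIndex) else genome
    if transcript.chrom not in seqs:
        raise KeyError(f"chromosome {transcript.chrom!r} not in genome")
    chrom_seq = seqs[transcript.chrom]
    for start, end in transcript.exons:
        if end > len(chrom_seq):
            raise ValueError(
                f"{transcript.transcript_id}: exon ({start}, {end}) outside "
                f"{transcript.chrom} of length {len(chrom_seq)}"
            )
    spliced = "".join(chrom_seq[s:e] for s, e in transcript.exons).upper()
    return revcomp(spliced) if transcript.strand == "-" else spliced


def classify_read(
    alignments: Sequence[CollapsedAlignment],
    transcript_rule: str = "coordinate",
) -> str:
    """Classify a read's collapsed alignment set.

    Returns the most specific of ``transcript_unique`` / ``gene_unique`` /
    ``multimapping`` / ``unmapped``.  ``transcript_unique`` implies the
    gene-level criterion.
    """
    if transcript_rule not in ("coordinate", "single_source"):
        raise ValueError(f"unknown transcript_rule: {transcript_rule!r}")
    if not alignments:
        return "unmapped"
    starts = {(a.chrom, a.genomic_start) for a in alignments}
    ends = {(a.chrom, a.genomic_end) for a in alignments}
    sources = {a.source for a in alignments if a.source != "genome"}
    if len(starts) == 1 and len(ends) == 1:
        if transcript_rule == "coordinate" or len(sources) <= 1:
            return "transcript_unique"
        return "gene_unique"
    if len(starts) == 1 or len(ends) == 1:
        return "gene_unique"
    return "multimapping"


def build_combined_index(
    genome: Mapping[str, str], transcripts: Sequence[TranscriptModel]
) -> tuple[OccurrenceIndex, dict[str, TranscriptModel]]:
    """Index the genome together with every spliced transcript sequence.

    Junction-spanning reads exist only on the transcript sequences; exonic
    reads occur both genomically and on transcripts and are merged later by
    their collapsed genomic coordinates.
    """
    sequences = dict(genome)
    models: dict[str, TranscriptModel] = {}
    for t in transcripts:
        if t.transcript_id in sequences:
            raise ValueError(
                f"transcript id {t.transcript_id!r} collides with another "
                f"sequence name"
            )
        sequences[t.transcript_id] = extract_spliced_sequence(genome, t)
        models[t.transcript_id] = t
    return build_index(sequences), models


def collapse_occurrence(occ, length: int, models: Mapping[str, TranscriptModel]) -> CollapsedAlignment:
    """Convert one index occurrence to genomic coordinates."""
    model = models.get(occ.seq_name)
    if model is None:
        return CollapsedAlignment(occ.seq_name, occ.position, occ.position + length)
    a = model.genomic_position(occ.position)
    b = model.genomic_position(occ.position + length - 1)
    start, end = (a, b + 1) if a <= b else (b, a + 1)
    return CollapsedAlignment(model.chrom, start, end, source=model.transcript_id)


def _dedupe(alignments: Iterable[CollapsedAlignment]) -> list[CollapsedAlignment]:
    seen = {}
    for a in alignments:
        key = (a.chrom, a.genomic_start, a.genomic_end, a.source)
        seen.setdefault(key, a)
    return list(seen.values())


def compute_transcript_mul(
    index: OccurrenceIndex,
    transcript: TranscriptModel,
    models: Mapping[str, TranscriptModel],
    level: str = "gene",
    kmin: int = DEFAULT_KMIN,
    kmax: int = DEFAULT_KMAX,
    step: int = DEFAULT_STEP,
    transcript_rule: str = "coordinate",
) -> MULArray:
    """MUL array in transcript coordinates at gene or transcript level.

    ``values[t]`` is the smallest L such that the read
    ``spliced[t : t+L]``, after locating *all* its occurrences across the
    combined genome+transcriptome index (both strands) and collapsing them
    to genomic coordinates, satisfies the gene-level (``level="gene"``) or
    transcript-level criterion; 0 otherwise.  Hits on other chromosomes or
    loci keep their own coordinates and so break uniqueness.
    """
    if level not in ("gene", "transcript"):
        raise ValueError(f"level must be 'gene' or 'transcript', got {level!r}")
    if transcript.transcript_id not in index:
        raise KeyError(
            f"transcript {transcript.transcript_id!r} not in combined index"
        )
    spliced = index.sequences[transcript.transcript_id]
    accepted = (
        {"transcript_unique", "gene_unique"} if level == "gene" else {"transcript_unique"}
    )

    def is_unique(p: int, length: int) -> bool:
        read = spliced[p : p + length]
        occs = find_occurrences(index, read, "both")
        collapsed = _dedupe(collapse_occurrence(o, length, models) for o in occs)
        return classify_read(collapsed, transcript_rule=transcript_rule) in accepted

    values = _bracket_search(is_unique, len(spliced), kmin, kmax, step)
    mode = "transcript_gene_level" if level == "gene" else "transcript_level"
    return MULArray(transcript.transcript_id, values, kmin=kmin, kmax=kmax, mode=mode)


def count_overlaps(transcripts: Sequence[TranscriptModel]) -> dict[str, int]:
    """Number of other annotated transcripts overlapping each transcript's exons.

    Overlap means at least one shared exonic base on the same chromosome,
    either strand.  Reported as a diagnostic: an enumerate-all-occurrences
    engine needs no cap on alignments per read, but the overlap count (plus
    one genomic hit) bounds how many alignments a within-annotation read
    can have.
    """
    counts = {t.transcript_id: 0 for t in transcripts}
    for i, a in enumerate(transcripts):
        for b in transcripts[i + 1 :]:
            if a.chrom != b.chrom:
                continue
            if any(
                s1 < e2 and s2 < e1
                for s1, e1 in a.exons
                for s2, e2 in b.exons
            ):
                counts[a.transcript_id] += 1
                counts[b.transcript_id] += 1
    return counts
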