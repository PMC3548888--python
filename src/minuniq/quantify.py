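"""Mappability-corrected RPKM expression estimation.

Multimapping reads are discarded upstream; the estimator sees only
uniquely-mapped alignments.  Discarding them deflates the read count of
any gene with non-unique sequence, so the gene-model length used for RPKM
must shrink accordingly: the *effective length* is the number of
exon-union positions uniquely mappable at the experiment's read length,
taken from a MUL track (gene-level transcriptome uniqueness superimposed
on genomic uniqueness, or plain genomic uniqueness).

    raw_rpkm  = count * 1e9 / (raw_length * total_mapped)
    norm_rpkm = count * 1e9 / (effective_length * total_mapped)

For fixed counts the correction factor norm/raw equals
raw_length / effective_length = 1 / (proportion unique) — plotting the
ratio against the unique proportion must therefore fall on y = 1/x, a
useful diagnostic for any uniqueness-compensation method.

Gene models are exon unions per gene id; bases shared between different
genes can be removed from both (``rmnameoverlap``) so ambiguous exons
neither attract reads nor inflate lengths.  Read depth is normalized
against all uniquely mapped reads in the file, assigned to a gene or not
(``allmapnorm``).
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .mulfile import MULFileSet
from .transcriptome import TranscriptModel

__all__ = [
    "GeneModel",
    "ExpressionRecord",
    "gene_models_from_transcripts",
    "count_unique_reads",
    "effective_length",
    "rpkm",
    "quantify_expression",
    "compare_raw_norm",
]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def subtract_intervals(
    intervals: Sequence[tuple[int, int]], removed: Sequence[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    """Set difference of two merged, sorted interval lists."""
    out: list[tuple[int, int]] = []
    for start, end in intervals:
        cur = start
        for rs, re in removed:
            if re <= cur or rs >= end:
                continue
            if rs > cur:
                out.append((cur, rs))
            cur = max(cur, re)
            if cur >= end:
                break
        if cur < end:
            out.append((cur, end))
    return tuple(out)


@dataclass(frozen=True)
class GeneModel:
    """Exon union of one gene: merged, disjoint half-open intervals."""

    gene_id: str
    chrom: str
    strand: str
    intervals: tuple[tuple[int, int], ...]

    @property
    def raw_length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class ExpressionRecord:
    gene_id: str
    read_count: int
    raw_length: int
    effective_length: int
    raw_rpkm: float
    norm_rpkm: float

    @property
    def ratio(self) -> float:
        """norm/raw RPKM ratio; inf when nothing is uniquely mappable."""
        if self.effective_length == 0:
            return float("inf")
        return self.raw_length / self.effective_length


def gene_models_from_transcripts(
    transcripts: Sequence[TranscriptModel], rmnameoverlap: bool = True
) -> list[GeneModel]:
    """Collapse transcripts to per-gene exon-union models.

    With ``rmnameoverlap`` (default), exonic bases covered by two or more
    distinct gene ids on a chromosome are removed from every gene's model.
    Genes whose model becomes empty are dropped with a warning.
    """
    by_gene: dict[str, dict] = {}
    for t in transcripts:
        entry = by_gene.setdefault(
            t.gene_id, {"chrom": t.chrom, "strand": t.strand, "exons": []}
        )
        if entry["chrom"] != t.chrom:
            raise ValueError(f"gene {t.gene_id!r} spans multiple chromosomes")
        entry["exons"].extend(t.exons)
    unions = {
        gid: merge_intervals(e["exons"]) for gid, e in by_gene.items()
    }
    if rmnameoverlap:
        shared_by_chrom: dict[str, tuple[tuple[int, int], ...]] = {}
        chroms = {e["chrom"] for e in by_gene.values()}
        for chrom in chroms:
            events: list[tuple[int, int]] = []
            for gid, entry in by_gene.items():
                if entry["chrom"] != chrom:
                    continue
                for s, e in unions[gid]:
                    events.append((s, 1))
                    events.append((e, -1))
            events.sort()
            shared: list[tuple[int, int]] = []
            depth = 0
            open_at = None
            for pos, delta in events:
                depth += delta
                if depth >= 2 and open_at is None:
                    open_at = pos
                elif depth < 2 and open_at is not None:
                    if pos > open_at:
                        shared.append((open_at, pos))
                    open_at = None
            shared_by_chrom[chrom] = merge_intervals(shared)
    models = []
    for gid, entry in by_gene.items():
        intervals = unions[gid]
        if rmnameoverlap:
            intervals = subtract_intervals(
                intervals, shared_by_chrom.get(entry["chrom"], ())
            )
        if not intervals:
            warnings.warn(
                f"gene {gid!r} has no exonic bases left after removing "
                f"inter-gene shared exons; dropped"
            )
            continue
        models.append(GeneModel(gid, entry["chrom"], entry["strand"], intervals))
    return models


class _GeneLookup:
    """Position -> gene ids, by binary search over per-chromosome intervals."""

    def __init__(self, gene_models: Sequence[GeneModel]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[str]]] = {}
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for g in gene_models:
            for s, e in g.intervals:
                per_chrom.setdefault(g.chrom, []).append((s, e, g.gene_id))
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            starts = [s for s, _, _ in ivals]
            ends = [e for _, e, _ in ivals]
            gids = [g for _, _, g in ivals]
            max_len = max(e - s for s, e, _ in ivals)
            self._by_chrom[chrom] = (starts, ends, gids, max_len)

    def genes_at(self, chrom: str, pos: int) -> list[str]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, gids, max_len = entry
        i = bisect.bisect_right(starts, pos)
        hits = []
        # intervals of different genes may overlap (rmnameoverlap off); any
        # interval covering pos starts within max_len of it
        j = i - 1
        while j >= 0 and starts[j] > pos - max_len:
            if ends[j] > pos:
                hits.append(gids[j])
            j -= 1
        return hits


def _iter_sam(path):
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for i, rec in enumerate(sam.fetch(until_eof=True), 1):
            if rec.is_unmapped:
                yield i, None
                continue
            pos5 = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
            yield i, (rec.reference_name, pos5)


def _iter_bed(path):
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{i}: BED6 record needs 6 fields")
            chrom, start, end, strand = fields[0], int(fields[1]), int(fields[2]), fields[5]
            pos5 = start if strand == "+" else end - 1
            yield i, (chrom, pos5)


def count_unique_reads(
    path,
    gene_models: Sequence[GeneModel],
    format: str = "sam",
) -> tuple[dict[str, int], int, int]:
    """Count uniquely-mapped reads per gene.

    A read is assigned to a gene when its 5'-most aligned base lies inside
    the gene's exon union — the same anchor the MUL definition uses for
    read starts.  Returns ``(counts, total_mapped, skipped_unmapped)``;
    ``total_mapped`` counts every mapped read whether assigned or not, the
    denominator for depth normalization.
    """
    if format not in ("sam", "bed"):
        raise ValueError(f"format must be 'sam' or 'bed', got {format!r}")
    lookup = _GeneLookup(gene_models)
    counts = {g.gene_id: 0 for g in gene_models}
    total = 0
    skipped = 0
    records = _iter_sam(path) if format == "sam" else _iter_bed(path)
    for _, rec in records:
        if rec is None:
            skipped += 1
            continue
        total += 1
        for gid in lookup.genes_at(*rec):
            counts[gid] += 1
    return counts, total, skipped


def effective_length(
    gene_model: GeneModel, mul_files: MULFileSet, read_length: int
) -> int:
    """Number of exon-union positions uniquely mappable at ``read_length``."""
    if read_length > mul_files.kmax:
        warnings.warn(
            f"read_length {read_length} exceeds stored kmax={mul_files.kmax}; "
            f"effective length computed at {mul_files.kmax}"
        )
        read_length = mul_files.kmax
    if read_length < mul_files.kmin:
        raise ValueError(
            f"read_length {read_length} below stored kmin={mul_files.kmin}"
        )
    track = mul_files.array(gene_model.chrom).values
    n = 0
    for start, end in gene_model.intervals:
        window = track[start:end]
        n += int(((window > 0) & (window <= read_length)).sum())
    return n


def rpkm(read_count: int, length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of gene model per million mapped reads."""
    if length_nt <= 0:
        raise ValueError("length_nt must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return read_count * 1e9 / (length_nt * total_mapped)


def quantify_expression(
    alignments,
    gene_models: Sequence[GeneModel],
    mul_files: MULFileSet,
    read_length: int,
    format: str = "sam",
) -> list[ExpressionRecord]:
    """End-to-end expression table: counts, lengths, raw and corrected RPKM.

    Genes with no uniquely mappable position get ``norm_rpkm = 0`` and are
    flagged unquantifiable via ``effective_length == 0``.
    """
    counts, total, _ = count_unique_reads(alignments, gene_models, format=format)
    if total == 0:
        raise ValueError("no mapped reads; RPKM undefined")
    records = []
    for g in gene_models:
        eff = effective_length(g, mul_files, read_length)
        raw = rpkm(counts[g.gene_id], g.raw_length, total)
        norm = rpkm(counts[g.gene_id], eff, total) if eff > 0 else 0.0
        records.append(
            ExpressionRecord(g.gene_id, counts[g.gene_id], g.raw_length, eff, raw, norm)
        )
    return records


def compare_raw_norm(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    """Per-gene correction-ratio table (the y = 1/x diagnostic).

    ``ratio = raw_length / effective_length`` equals norm/raw RPKM for any
    gene with reads; ``unique_proportion`` is its reciprocal argument, so
    ratio x proportion == 1 identically.  Genes with effective length 0
    are reported with ``quantifiable = False`` and NaN ratio.
    """
    rows = []
    for r in records:
        quantifiable = r.effective_length > 0
        rows.append(
            {
                "gene_id": r.gene_id,
                "read_count": r.read_count,
                "raw_length": r.raw_length,
                "effective_length": r.effective_length,
                "unique_proportion": (
                    r.effective_length / r.raw_length if r.raw_length else float("nan")
                ),
                "raw_rpkm": r.raw_rpkm,
                "norm_rpkm": r.norm_rpkm,
                "ratio": r.ratio if quantifiable else float("nan"),
                "quantifiable": quantifiable,
            }
        )
    return pd.DataFrame(rows)
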