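"""Synthetic genomes, annotations and read sets with planted ground truth.

Everything the package's tests and demos consume is generated here, as a
pure function of a seed: i.i.d. A/C/G/T chromosomes with planted
exact-copy repeat families (the controlled source of non-uniqueness),
gene/transcript layouts with known shared and private exons or paralog
duplications, and uniformly-placed single-end reads over gene models at a
planted expression, filtered to uniquely mappable start positions so the
output emulates a unique-only alignment file.

Random 20-mers essentially never collide by chance at these scales, so a
background chromosome is almost everywhere uniquely mappable and every
loss of mappability is traceable to a planted repeat.  Read placements
depend only on (seed, gene), never on the read length, so regenerating at
a shorter read length re-filters the *same* placements — the in-silico
analogue of trimming a sequencing run to a shorter length.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .mulfile import MULFileSet
from .quantify import GeneModel
from .transcriptome import TranscriptModel

__all__ = [
    "RepeatFamily",
    "FixtureSpec",
    "generate_genome",
    "make_single_exon_gene",
    "make_two_isoform_locus",
    "make_paralog_pair_layout",
    "generate_reads",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class RepeatFamily:
    """One segment sequence planted verbatim at several locations."""

    length: int
    placements: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("repeat length must be >= 1")
        if len(self.placements) < 2:
            raise ValueError("a repeat family needs at least 2 placements")


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic genome."""

    seed: int
    chrom_lengths: Mapping[str, int]
    repeats: tuple[RepeatFamily, ...] = ()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def generate_genome(spec: FixtureSpec) -> tuple[dict[str, str], list[dict]]:
    """Generate the genome and a ground-truth map of planted repeats.

    Returns ``(sequences, repeat_map)`` where each repeat-map entry lists
    the family's segment length and every (chrom, start) copy.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = {
        name: list(_random_seq(rng, length))
        for name, length in spec.chrom_lengths.items()
    }
    repeat_map: list[dict] = []
    for fam in spec.repeats:
        segment = _random_seq(rng, fam.length)
        for chrom, start in fam.placements:
            if chrom not in chroms:
                raise ValueError(f"repeat placed on unknown chromosome {chrom!r}")
            if start < 0 or start + fam.length > len(chroms[chrom]):
                raise ValueError(
                    f"repeat of length {fam.length} does not fit at "
                    f"{chrom}:{start} (chromosome length {len(chroms[chrom])})"
                )
            chroms[chrom][start : start + fam.length] = segment
        repeat_map.append(
            {"length": fam.length, "placements": list(fam.placements)}
        )
    return {name: "".join(seq) for name, seq in chroms.items()}, repeat_map


# ---------------------------------------------------------------------------
# annotation layouts


def make_single_exon_gene(
    gene_id: str, chrom: str, start: int, length: int, strand: str = "+"
) -> TranscriptModel:
    return TranscriptModel(gene_id, gene_id, chrom, strand, ((start, start + length),))


def make_two_isoform_locus(
    gene_id: str,
    chrom: str,
    start: int,
    shared_len: int,
    private_len: int,
    intron: int = 100,
    strand: str = "+",
) -> list[TranscriptModel]:
    """A locus with a shared first exon and one isoform-private second exon.

    Ground truth by construction: the shared exon carries no
    transcript-level uniqueness under the single-source rule, while the
    private exon does.
    """
    shared = (start, start + shared_len)
    private = (start + shared_len + intron, start + shared_len + intron + private_len)
    iso1 = TranscriptModel(f"{gene_id}.1", gene_id, chrom, strand, (shared,))
    iso2 = TranscriptModel(f"{gene_id}.2", gene_id, chrom, strand, (shared, private))
    return [iso1, iso2]


def make_paralog_pair_layout(
    base_id: str,
    chrom: str,
    copy_starts: tuple[int, int],
    copy_len: int,
    flank: int = 0,
) -> tuple[RepeatFamily, list[TranscriptModel]]:
    """A duplicated segment plus two genes over its copies.

    Each gene's exon covers one repeat copy extended by ``flank`` unique
    bases on each side, the ferritin-paralog situation: identical bodies,
    distinguishable only by flanking sequence.  Gene-level unique
    proportion is below 1 over the copies and rises with the flank.
    """
    fam = RepeatFamily(copy_len, ((chrom, copy_starts[0]), (chrom, copy_starts[1])))
    genes = [
        make_single_exon_gene(
            f"{base_id}{i+1}", chrom, start - flank, copy_len + 2 * flank
        )
        for i, start in enumerate(copy_starts)
    ]
    return fam, genes


# ---------------------------------------------------------------------------
# reads


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_reads(
    genome: Mapping[str, str],
    gene_models: Sequence[GeneModel],
    mul_files: MULFileSet,
    read_length: int,
    depth: Mapping[str, int] | int,
    seed: int,
    sam_path,
) -> pd.DataFrame:
    """Simulate a unique-only single-end alignment file plus its truth table.

    For each gene, ``depth`` read start positions are placed uniformly over
    the gene's exon-union positions; a read survives to the output iff its
    start is uniquely mappable at ``read_length`` (``0 < MUL <= L``), which
    is exactly what aligning and keeping unique hits would do.  Placements
    are drawn from a (seed, gene) stream, so re-running with a shorter
    ``read_length`` trims the same virtual reads.

    The truth table reports, per gene: reads simulated, reads surviving,
    the gene's raw and effective length and unique proportion at this read
    length.  Zero-depth genes yield zero reads.
    """
    depth_of = (lambda g: depth[g]) if isinstance(depth, Mapping) else (lambda g: depth)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": len(seq)} for name, seq in genome.items()
        ],
    }
    rows = []
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        tid_of = {name: i for i, name in enumerate(genome)}
        for g in gene_models:
            n = depth_of(g.gene_id)
            positions = np.concatenate(
                [np.arange(s, e) for s, e in g.intervals]
            )
            rng = np.random.default_rng([seed, zlib.crc32(g.gene_id.encode())])
            starts = rng.choice(positions, size=n, replace=True) if n else np.array([], dtype=int)
            track = mul_files.array(g.chrom).values
            chrom_seq = genome[g.chrom]
            kept = 0
            for j, p in enumerate(starts):
                p = int(p)
                mul = int(track[p])
                if not (0 < mul <= read_length):
                    continue
                kept += 1
                seq = chrom_seq[p : p + read_length]
                rec = pysam.AlignedSegment()
                rec.query_name = f"{g.gene_id}:{j}"
                rec.reference_id = tid_of[g.chrom]
                rec.reference_start = p
                rec.mapping_quality = 255
                rec.cigarstring = f"{len(seq)}M"
                rec.query_sequence = seq
                rec.flag = 0
                out.write(rec)
            window = track[positions]
            eff = int(((window > 0) & (window <= read_length)).sum())
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "n_simulated": n,
                    "n_kept": kept,
                    "raw_length": g.raw_length,
                    "effective_length": eff,
                    "unique_proportion": eff / g.raw_length if g.raw_length else 0.0,
                }
            )
    return pd.DataFrame(rows)
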