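"""Binary MUL track files: write, read, and query.

One binary file per sequence: position i lives at byte offset ``i * width``
(little-endian for the optional 2-byte width, which extends the storable
length range from 255 to 65535).  File size is therefore exactly
``sequence length x width`` bytes — the whole-genome storage cost of the
representation.  A JSON sidecar carries the metadata (length range, mode,
value width, build label) that the binary payload cannot describe itself;
it also lets queries reject read lengths outside the stored range.

The query surface answers the two questions users actually ask: per-position
uniqueness flags over an arbitrary region at an arbitrary read length, and
proportion-unique summaries over region sets.
"""

from __future__ import annotations

import json
import urllib.parse
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mul_core import MULArray

__all__ = [
    "write_mul_file",
    "read_mul_file",
    "MULFileSet",
    "query_region",
    "proportion_unique",
    "read_bed_regions",
]

SET_SIDECAR = "mulset.json"
FORMAT_VERSION = 1
_DTYPES = {1: np.dtype("u1"), 2: np.dtype("<u2")}


def _sanitize(name: str) -> str:
    """Reversible, filesystem-safe encoding of a sequence name."""
    return urllib.parse.quote(name, safe="")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_mul_file(
    array: MULArray,
    path,
    value_width: int = 1,
    overwrite: bool = False,
    genome_build: str = "unspecified",
) -> Path:
    """Write one MUL array as a binary file plus JSON sidecar."""
    if value_width not in _DTYPES:
        raise ValueError(f"value_width must be 1 or 2, got {value_width}")
    limit = (1 << (8 * value_width)) - 1
    if array.kmax > limit:
        raise ValueError(
            f"kmax={array.kmax} not representable in {value_width} byte(s) "
            f"(max {limit})"
        )
    if array.values.size and int(array.values.max()) > limit:
        raise ValueError(
            f"MUL value {int(array.values.max())} overflows {value_width}-byte storage"
        )
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")
    path.parent.mkdir(parents=True, exist_ok=True)
    array.values.astype(_DTYPES[value_width]).tofile(path)
    meta = {
        "format_version": FORMAT_VERSION,
        "seq_name": array.seq_name,
        "length": int(len(array)),
        "kmin": int(array.kmin),
        "kmax": int(array.kmax),
        "mode": array.mode,
        "value_width": value_width,
        "genome_build": genome_build,
        "tool": "minuniq",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")
    return path


def read_mul_file(path) -> MULArray:
    """Read a binary MUL file written by :func:`write_mul_file`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar}; MUL binaries are not self-describing — "
            f"restore the .json written alongside the track or rebuild it"
        )
    meta = json.loads(sidecar.read_text())
    width = meta["value_width"]
    expected = meta["length"] * width
    actual = path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"{path}: size {actual} bytes, sidecar implies {expected} "
            f"({meta['length']} positions x {width} byte(s))"
        )
    values = np.fromfile(path, dtype=_DTYPES[width])
    return MULArray(
        meta["seq_name"], values, kmin=meta["kmin"], kmax=meta["kmax"], mode=meta["mode"]
    )


class MULFileSet:
    """A directory of per-sequence MUL tracks sharing one metadata sidecar."""

    def __init__(self, directory, meta: dict):
        self.directory = Path(directory)
        self.meta = meta
        self._cache: dict[str, MULArray] = {}

    # -- construction -------------------------------------------------

    @classmethod
    def write(
        cls,
        arrays: Iterable[MULArray] | Mapping[str, MULArray],
        directory,
        value_width: int = 1,
        genome_build: str = "unspecified",
        overwrite: bool = False,
    ) -> "MULFileSet":
        if isinstance(arrays, Mapping):
            arrays = list(arrays.values())
        else:
            arrays = list(arrays)
        if not arrays:
            raise ValueError("no arrays to write")
        kmin = {a.kmin for a in arrays}
        kmax = {a.kmax for a in arrays}
        mode = {a.mode for a in arrays}
        if len(kmin) != 1 or len(kmax) != 1 or len(mode) != 1:
            raise ValueError("all arrays in a set must share kmin, kmax and mode")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        sequences = {}
        for a in arrays:
            fname = f"{_sanitize(a.seq_name)}.mul{value_width}"
            write_mul_file(
                a,
                directory / fname,
                value_width=value_width,
                overwrite=overwrite,
                genome_build=genome_build,
            )
            sequences[a.seq_name] = {"length": int(len(a)), "file": fname}
        meta = {
            "format_version": FORMAT_VERSION,
            "kmin": int(kmin.pop()),
            "kmax": int(kmax.pop()),
            "mode": mode.pop(),
            "value_width": value_width,
            "genome_build": genome_build,
            "tool": "minuniq",
            "sequences": sequences,
        }
        (directory / SET_SIDECAR).write_text(json.dumps(meta, indent=1) + "\n")
        return cls(directory, meta)

    @classmethod
    def open(cls, directory) -> "MULFileSet":
        directory = Path(directory)
        sidecar = directory / SET_SIDECAR
        if not sidecar.exists():
            raise FileNotFoundError(f"no {SET_SIDECAR} in {directory}")
        return cls(directory, json.loads(sidecar.read_text()))

    # -- access --------------------------------------------------------

    @property
    def kmin(self) -> int:
        return self.meta["kmin"]

    @property
    def kmax(self) -> int:
        return self.meta["kmax"]

    @property
    def mode(self) -> str:
        return self.meta["mode"]

    def seq_names(self) -> list[str]:
        return list(self.meta["sequences"])

    def seq_length(self, seq_name: str) -> int:
        return self.meta["sequences"][seq_name]["length"]

    def array(self, seq_name: str) -> MULArray:
        if seq_name not in self.meta["sequences"]:
            raise KeyError(f"no MUL track for sequence {seq_name!r}")
        if seq_name not in self._cache:
            fname = self.meta["sequences"][seq_name]["file"]
            self._cache[seq_name] = read_mul_file(self.directory / fname)
        return self._cache[seq_name]

    def query_region(self, seq_name, start, end, read_length):
        return query_region(self, seq_name, start, end, read_length)

    def proportion_unique(self, regions, read_length, denominator="fitting"):
        return proportion_unique(self, regions, read_length, denominator)


def _effective_read_length(files: MULFileSet, read_length: int) -> int:
    if read_length < files.kmin:
        raise ValueError(
            f"read_length {read_length} below stored range "
            f"[{files.kmin}, {files.kmax}]"
        )
    if read_length > files.kmax:
        warnings.warn(
            f"read_length {read_length} exceeds stored kmax={files.kmax}; "
            f"value 0 cannot distinguish 'needs > kmax' from 'never unique', "
            f"capping query at {files.kmax}",
            stacklevel=3,
        )
        return files.kmax
    return read_length


def query_region(
    files: MULFileSet, seq_name: str, start: int, end: int, read_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position MUL values and uniqueness flags over ``[start, end)``.

    Position p is uniquely mappable at ``read_length`` iff
    ``0 < value[p] <= read_length``.
    """
    length = files.seq_length(seq_name)
    if not (0 <= start < end <= length):
        raise ValueError(
            f"region [{start}, {end}) invalid for {seq_name!r} of length {length}"
        )
    read_length = _effective_read_length(files, read_length)
    values = files.array(seq_name).values[start:end]
    flags = (values > 0) & (values <= read_length)
    return values, flags


def proportion_unique(
    files: MULFileSet,
    regions: Sequence[tuple[str, int, int]],
    read_length: int,
    denominator: str = "fitting",
) -> tuple[list[float], float]:
    """Fraction of uniquely mappable positions per region, plus the pooled fraction.

    ``denominator="fitting"`` counts only start positions from which a full
    read of ``read_length`` fits inside the region (clipped to the
    sequence) — the positions a read could actually be generated from;
    ``"all"`` counts every position in the region.  The numerator is
    restricted to the same position set.  Pooled = sum of numerators / sum
    of denominators.
    """
    if not regions:
        raise ValueError("empty region list")
    if denominator not in ("fitting", "all"):
        raise ValueError(f"denominator must be 'fitting' or 'all', got {denominator!r}")
    capped = _effective_read_length(files, read_length)
    fractions: list[float] = []
    num_total = 0
    den_total = 0
    for seq_name, start, end in regions:
        values, flags = query_region(files, seq_name, start, end, capped)
        if denominator == "fitting":
            stop = min(end, files.seq_length(seq_name)) - read_length + 1 - start
            flags = flags[: max(stop, 0)]
            den = max(stop, 0)
        else:
            den = end - start
        num = int(flags.sum())
        fractions.append(num / den if den else 0.0)
        num_total += num
        den_total += den
    pooled = num_total / den_total if den_total else 0.0
    return fractions, pooled


def read_bed_regions(path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) triples from a BED3+ file."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            regions.append((fields[0], int(fields[1]), int(fields[2])))
    return regions
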