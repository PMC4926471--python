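"""File formats and genome partitioning.

Input tables use 1-based inclusive genomic coordinates, as produced by the
common per-cytosine and per-SNP summary pipelines.  Internally everything is
0-based half-open; the conversion happens only at this I/O boundary.

Supported formats
-----------------
* methylation TSV: ``chrom  pos  strand  context  meth_reads  total_reads``
* SNP TSV: ``chrom  pos  ref_base  alt_base  quality  r  concordance``
* UCSC wiggle (``fixedStep`` and ``variableStep``) carrying per-position
  methylation levels in ``[0, 1]``
* two-column chromosome-sizes text
* sample label TSV: ``sample_id  label``

Gzip-compressed inputs are accepted transparently (detected by magic bytes).
"""
from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

VALID_CONTEXTS = ("CG", "CHG", "CHH")
VALID_STRANDS = ("+", "-")

METH_COLUMNS = ("chrom", "pos", "strand", "context", "meth_reads", "total_reads")
SNP_COLUMNS = ("chrom", "pos", "ref_base", "alt_base", "quality", "r", "concordance")

DEFAULT_MIN_QUALITY = 25.0
DEFAULT_BIN_WIDTH = 2000


class FormatError(ValueError):
    """Structural problem with an input file (wrong columns, bad dialect)."""


class RecordError(ValueError):
    """A single record violates its invariants; message carries the line number."""


# ---------------------------------------------------------------------------
# atomic record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineSite:
    """One cytosine's observation: strand, context and read counts."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise RecordError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in VALID_STRANDS:
            raise RecordError(f"invalid strand {self.strand!r}")
        if self.context not in VALID_CONTEXTS:
            raise RecordError(f"invalid context {self.context!r}")
        if self.total_reads < 1:
            raise RecordError(f"total_reads must be positive, got {self.total_reads}")
        if not (0 <= self.meth_reads <= self.total_reads):
            raise RecordError(
                f"meth_reads={self.meth_reads} outside [0, total_reads="
                f"{self.total_reads}]"
            )

    @property
    def level(self) -> float:
        """Methylation level: fraction of reads observed methylated."""
        return self.meth_reads / self.total_reads


@dataclass(frozen=True)
class SnpSite:
    """One base substitution with supporting-read count and concordance."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    quality: float
    r: int
    concordance: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise RecordError(f"pos must be >= 1, got {self.pos}")
        if self.quality < 0:
            raise RecordError(f"quality must be non-negative, got {self.quality}")
        if self.r < 0:
            raise RecordError(f"r must be non-negative, got {self.r}")
        if not (0.0 <= self.concordance <= 1.0):
            raise RecordError(f"concordance {self.concordance} outside [0, 1]")

    @property
    def rn(self) -> float:
        """Normalized supporting-read count r * concordance."""
        return self.r * self.concordance


# ---------------------------------------------------------------------------
# sample containers
# ---------------------------------------------------------------------------

class MethylomeSample:
    """A collection of cytosine observations keyed by (chrom, pos, strand).

    ``has_counts`` distinguishes read-count samples (from methylation TSVs)
    from level-only tracks (from wiggle files); the latter carry a ``level``
    column directly and no read counts.
    """

    def __init__(self, sample_id: str, data: pd.DataFrame, has_counts: bool = True):
        self.sample_id = sample_id
        self.has_counts = has_counts
        data = data.reset_index(drop=True)
        if len(data):
            dup = data.duplicated(subset=["chrom", "pos", "strand"])
            if dup.any():
                i = int(np.flatnonzero(dup.to_numpy())[0])
                raise RecordError(
                    f"duplicate site key at {data.at[i, 'chrom']}:"
                    f"{data.at[i, 'pos']}{data.at[i, 'strand']}"
                )
        if has_counts and "level" not in data.columns:
            data = data.assign(level=data["meth_reads"] / data["total_reads"])
        self.data = data

    @classmethod
    def from_sites(cls, sample_id: str, sites: Iterable[CytosineSite]) -> "MethylomeSample":
        rows = [
            (s.chrom, s.pos, s.strand, s.context, s.meth_reads, s.total_reads)
            for s in sites
        ]
        df = pd.DataFrame(rows, columns=list(METH_COLUMNS))
        return cls(sample_id, df)

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def sites(self) -> Iterator[CytosineSite]:
        if not self.has_counts:
            raise ValueError("level-only sample has no read counts")
        for row in self.data.itertuples(index=False):
            yield CytosineSite(
                row.chrom, int(row.pos), row.strand, row.context,
                int(row.meth_reads), int(row.total_reads),
            )

    def equals(self, other: "MethylomeSample") -> bool:
        cols = list(METH_COLUMNS) if self.has_counts else ["chrom", "pos", "strand", "context", "level"]
        return (
            self.sample_id == other.sample_id
            and self.has_counts == other.has_counts
            and self.data[cols].equals(other.data[cols])
        )


class SnpSample:
    """A collection of SNP records keyed by (chrom, pos)."""

    def __init__(self, sample_id: str, data: pd.DataFrame):
        self.sample_id = sample_id
        data = data.reset_index(drop=True)
        if len(data):
            dup = data.duplicated(subset=["chrom", "pos"])
            if dup.any():
                i = int(np.flatnonzero(dup.to_numpy())[0])
                raise RecordError(
                    f"duplicate SNP key at {data.at[i, 'chrom']}:{data.at[i, 'pos']}"
                )
        self.data = data

    @classmethod
    def from_sites(cls, sample_id: str, sites: Iterable[SnpSite]) -> "SnpSample":
        rows = [
            (s.chrom, s.pos, s.ref_base, s.alt_base, s.quality, s.r, s.concordance)
            for s in sites
        ]
        df = pd.DataFrame(rows, columns=list(SNP_COLUMNS))
        return cls(sample_id, df)

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def sites(self) -> Iterator[SnpSite]:
        for row in self.data.itertuples(index=False):
            yield SnpSite(
                row.chrom, int(row.pos), row.ref_base, row.alt_base,
                float(row.quality), int(row.r), float(row.concordance),
            )


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _is_header(fields: list[str], expected: tuple[str, ...]) -> bool:
    return [f.strip().lower() for f in fields[: len(expected)]] == list(expected)


# ---------------------------------------------------------------------------
# methylation TSV
# ---------------------------------------------------------------------------

def read_methylation_tsv(
    path,
    context_filter: str | None = "CG",
    sample_id: str | None = None,
    lenient: bool = False,
) -> MethylomeSample:
    """Read a per-cytosine methylation TSV.

    Parameters
    ----------
    path : str or Path
        Input file (optionally gzip-compressed).
    context_filter : str or None
        Keep only rows with this methylation context (default ``"CG"``);
        ``None`` keeps all contexts.
    sample_id : str, optional
        Defaults to the file stem.
    lenient : bool
        If true, malformed rows are skipped with a warning instead of
        raising.  Strict mode is the default: reproducibility over
        convenience.
    """
    if context_filter is not None and context_filter not in VALID_CONTEXTS:
        raise ValueError(f"invalid context_filter {context_filter!r}")
    sid = sample_id or Path(path).stem.removesuffix(".tsv")
    rows: list[tuple] = []
    n_skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and _is_header(fields, METH_COLUMNS):
                continue
            try:
                if len(fields) < 6:
                    raise FormatError(
                        f"line {lineno}: expected 6 columns, got {len(fields)}"
                    )
                try:
                    site = CytosineSite(
                        fields[0], int(fields[1]), fields[2], fields[3],
                        int(fields[4]), int(fields[5]),
                    )
                except RecordError as exc:
                    raise RecordError(f"line {lineno}: {exc}") from None
                except ValueError:
                    raise FormatError(f"line {lineno}: non-numeric count field") from None
            except (FormatError, RecordError) as exc:
                if lenient:
                    n_skipped += 1
                    continue
                raise type(exc)(f"{path}: {exc}") from None
            if context_filter is None or site.context == context_filter:
                rows.append(
                    (site.chrom, site.pos, site.strand, site.context,
                     site.meth_reads, site.total_reads)
                )
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} malformed rows (lenient mode)")
    df = pd.DataFrame(rows, columns=list(METH_COLUMNS))
    return MethylomeSample(sid, df)


def write_methylation_tsv(sample: MethylomeSample, path) -> None:
    if not sample.has_counts:
        raise ValueError("cannot write a level-only sample as a count TSV")
    with open(path, "w") as fh:
        fh.write("\t".join(METH_COLUMNS) + "\n")
        for row in sample.data.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.strand}\t{row.context}\t"
                f"{row.meth_reads}\t{row.total_reads}\n"
            )


# ---------------------------------------------------------------------------
# SNP TSV
# ---------------------------------------------------------------------------

def read_snp_tsv(
    path,
    min_quality: float = DEFAULT_MIN_QUALITY,
    sample_id: str | None = None,
    lenient: bool = False,
) -> SnpSample:
    """Read a per-site SNP TSV, keeping only rows with quality >= min_quality.

    The default threshold of 25 matches the common quality cut for these
    tables.  Filtering is idempotent: re-reading an already filtered file
    returns the same records.
    """
    sid = sample_id or Path(path).stem.removesuffix(".tsv")
    rows: list[tuple] = []
    n_skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and _is_header(fields, SNP_COLUMNS):
                continue
            try:
                if len(fields) < 7:
                    raise FormatError(
                        f"line {lineno}: expected 7 columns, got {len(fields)}"
                    )
                try:
                    site = SnpSite(
                        fields[0], int(fields[1]), fields[2], fields[3],
                        float(fields[4]), int(fields[5]), float(fields[6]),
                    )
                except RecordError as exc:
                    raise RecordError(f"line {lineno}: {exc}") from None
                except ValueError:
                    raise FormatError(f"line {lineno}: non-numeric field") from None
            except (FormatError, RecordError) as exc:
                if lenient:
                    n_skipped += 1
                    continue
                raise type(exc)(f"{path}: {exc}") from None
            if site.quality >= min_quality:
                rows.append(
                    (site.chrom, site.pos, site.ref_base, site.alt_base,
                     site.quality, site.r, site.concordance)
                )
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} malformed rows (lenient mode)")
    df = pd.DataFrame(rows, columns=list(SNP_COLUMNS))
    return SnpSample(sid, df)


def write_snp_tsv(sample: SnpSample, path) -> None:
    # quality/concordance written with repr so floats round-trip exactly
    with open(path, "w") as fh:
        fh.write("\t".join(SNP_COLUMNS) + "\n")
        for row in sample.data.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.ref_base}\t{row.alt_base}\t"
                f"{row.quality!r}\t{row.r}\t{row.concordance!r}\n"
            )


# ---------------------------------------------------------------------------
# wiggle tracks
# ---------------------------------------------------------------------------

def read_wiggle(path, sample_id: str | None = None, context: str = "CG") -> MethylomeSample:
    """Read a UCSC wiggle track of per-position methylation levels.

    Both ``fixedStep`` and ``variableStep`` blocks are accepted, and may be
    mixed within one file.  Levels must lie in [0, 1].  The result is a
    level-only :class:`MethylomeSample` (``has_counts=False``); downstream
    entropy computations use the levels directly.
    """
    sid = sample_id or Path(path).stem.removesuffix(".wig")
    chroms: list[str] = []
    positions: list[int] = []
    levels: list[float] = []

    mode = None  # ("variable", chrom, span) or ("fixed", chrom, next_pos, step, span)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("variableStep"):
                attrs = _wig_attrs(line, lineno)
                mode = ("variable", attrs["chrom"], int(attrs.get("span", 1)))
                continue
            if line.startswith("fixedStep"):
                attrs = _wig_attrs(line, lineno)
                mode = (
                    "fixed", attrs["chrom"], int(attrs["start"]),
                    int(attrs.get("step", 1)), int(attrs.get("span", 1)),
                )
                continue
            if mode is None:
                raise FormatError(f"{path}: line {lineno}: data before any step header")
            if mode[0] == "variable":
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(f"{path}: line {lineno}: expected 'pos value'")
                pos, value = int(parts[0]), float(parts[1])
                _check_level(value, path, lineno)
                _, chrom, span = mode
                for off in range(span):
                    chroms.append(chrom)
                    positions.append(pos + off)
                    levels.append(value)
            else:
                value = float(line)
                _check_level(value, path, lineno)
                _, chrom, nxt, step, span = mode
                for off in range(span):
                    chroms.append(chrom)
                    positions.append(nxt + off)
                    levels.append(value)
                mode = ("fixed", chrom, nxt + step, step, span)

    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "strand": "+",
            "context": context,
            "level": levels,
        }
    )
    return MethylomeSample(sid, df, has_counts=False)


def _wig_attrs(line: str, lineno: int) -> dict:
    attrs = {}
    for token in line.split()[1:]:
        if "=" not in token:
            raise FormatError(f"line {lineno}: bad wiggle attribute {token!r}")
        key, value = token.split("=", 1)
        attrs[key] = value
    if "chrom" not in attrs:
        raise FormatError(f"line {lineno}: wiggle header lacks chrom=")
    return attrs


def _check_level(value: float, path, lineno: int) -> None:
    if not (0.0 <= value <= 1.0):
        raise RecordError(f"{path}: line {lineno}: level {value} outside [0, 1]")


# ---------------------------------------------------------------------------
# genome partition
# ---------------------------------------------------------------------------

class RegionPartition:
    """An ordered, non-overlapping partition of the genome into regions.

    Internal coordinates are 0-based half-open; ``region_ids`` render
    1-based inclusive (``chrom:start-end``).  The same partition object is
    applied to every sample so region columns are comparable across samples.
    """

    def __init__(self, regions: Iterable[tuple[str, int, int]]):
        regions = list(regions)
        if not regions:
            raise ValueError("empty partition")
        self._regions = regions
        self._index: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
        offset = 0
        current: str | None = None
        starts: list[int] = []
        ends: list[int] = []
        for chrom, start, end in regions:
            if not (0 <= start < end):
                raise ValueError(f"bad region ({chrom}, {start}, {end})")
            if chrom != current:
                if chrom in self._index:
                    raise ValueError(f"chromosome {chrom} appears in two runs")
                if current is not None:
                    self._index[current] = (
                        np.asarray(starts), np.asarray(ends), offset,
                    )
                    offset += len(starts)
                current, starts, ends = chrom, [], []
            if ends and start < ends[-1]:
                raise ValueError(f"regions overlap or are unsorted on {chrom}")
            starts.append(start)
            ends.append(end)
        self._index[current] = (np.asarray(starts), np.asarray(ends), offset)
        self.region_ids = [f"{c}:{s + 1}-{e}" for c, s, e in regions]

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self):
        return iter(self._regions)

    def __getitem__(self, i: int) -> tuple[str, int, int]:
        return self._regions[i]

    def assign(self, chrom, pos) -> np.ndarray:
        """Map 1-based positions to global region indices (-1 if unassigned)."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(pos.shape, -1, dtype=np.int64)
        for c in pd.unique(chrom):
            if c not in self._index:
                continue
            starts, ends, offset = self._index[c]
            mask = chrom == c
            p0 = pos[mask] - 1
            idx = np.searchsorted(starts, p0, side="right") - 1
            ok = (idx >= 0) & (p0 < ends[np.clip(idx, 0, len(ends) - 1)])
            res = np.where(ok, idx + offset, -1)
            out[mask] = res
        return out


def make_partition(chrom_sizes: Mapping[str, int], bin_width: int = DEFAULT_BIN_WIDTH) -> RegionPartition:
    """Partition chromosomes into fixed-width bins (last bin may be short)."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if not chrom_sizes:
        raise ValueError("empty chrom_sizes")
    regions = []
    for chrom, size in chrom_sizes.items():
        if size < 1:
            raise ValueError(f"chromosome {chrom} has non-positive size")
        for start in range(0, size, bin_width):
            regions.append((chrom, start, min(start + bin_width, size)))
    return RegionPartition(regions)


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}: expected 'chrom size' lines")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# sample labels
# ---------------------------------------------------------------------------

def read_labels_tsv(path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and [f.lower() for f in fields[:2]] == ["sample_id", "label"]:
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 'sample_id<TAB>label'")
            labels[fields[0]] = fields[1]
    return labels


def write_labels_tsv(labels: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")
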