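"""Region-level information statistics.

Two region statistics drive the whole pipeline:

* ``IR`` — information gained or lost in a region between a reference
  ("before") and a subject ("after") methylome: the sum over shared cytosine
  sites of the difference in binary Shannon entropy of the methylation level.
* ``LCR`` — the sum over a region of log2 of the normalized supporting-read
  counts of the SNPs it contains, read as the uncertainty of *not* observing
  a SNP under the Boltzmann model (see :mod:`methylinfo.boltzmann`).

Regions are further classified by the magnitude of their IR values into
low-variable (LMR), variable (VMR) and highly variable (HMR) regions.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.constants import k as BOLTZMANN_CONSTANT
from scipy.special import xlogy

from .io import MethylomeSample, RegionPartition, SnpSample

DEFAULT_T1 = 2.0
DEFAULT_T2 = 10.0
REGION_CLASSES = ("LMR", "VMR", "HMR")


def landauer_limit(temperature_k: float = 298.15) -> float:
    """Minimum energy in Joules dissipated when one bit is erased.

    At room temperature this evaluates to about 3e-21 J.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return BOLTZMANN_CONSTANT * temperature_k * math.log(2.0)


def site_entropy(p):
    """Binary Shannon entropy (bits) of a methylation level in [0, 1].

    ``0 * log2(0)`` is taken as 0 by continuity, so H(0) = H(1) = 0 and the
    maximum H(0.5) = 1 bit.  Accepts scalars or arrays.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("methylation level outside [0, 1]")
    h = -(xlogy(arr, arr) + xlogy(1.0 - arr, 1.0 - arr)) / math.log(2.0)
    h = np.clip(h, 0.0, 1.0)  # guard tiny negative rounding
    if np.isscalar(p) or arr.ndim == 0:
        return float(h)
    return h


# ---------------------------------------------------------------------------
# RegionMatrix
# ---------------------------------------------------------------------------

@dataclass
class RegionMatrix:
    """Samples x regions table of a region statistic (IR or LCR)."""

    sample_ids: list[str]
    region_ids: list[str]
    values: np.ndarray
    statistic: str = "IR"
    reference_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.region_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.region_ids)} regions"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def column(self, region_id: str) -> np.ndarray:
        return self.values[:, self.region_ids.index(region_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "RegionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return RegionMatrix(
            list(sample_ids), list(self.region_ids), self.values[idx],
            self.statistic, self.reference_id,
        )

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV with 12 significant digits (round-trip stable)."""
        with open(path, "w") as fh:
            fh.write(f"#statistic={self.statistic}\n")
            if self.reference_id is not None:
                fh.write(f"#reference={self.reference_id}\n")
            fh.write("sample_id\t" + "\t".join(self.region_ids) + "\n")
            for sid, row in zip(self.sample_ids, self.values):
                fh.write(sid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "RegionMatrix":
        statistic, reference = "IR", None
        sample_ids: list[str] = []
        rows: list[list[float]] = []
        region_ids: list[str] | None = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#statistic="):
                    statistic = line.split("=", 1)[1]
                    continue
                if line.startswith("#reference="):
                    reference = line.split("=", 1)[1]
                    continue
                if not line:
                    continue
                fields = line.split("\t")
                if region_ids is None:
                    if fields[0] != "sample_id":
                        raise ValueError(f"{path}: missing header row")
                    region_ids = fields[1:]
                    continue
                sample_ids.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
        if region_ids is None:
            raise ValueError(f"{path}: empty matrix file")
        return cls(sample_ids, region_ids, np.asarray(rows), statistic, reference)


# ---------------------------------------------------------------------------
# IR
# ---------------------------------------------------------------------------

def region_information(
    subject: MethylomeSample,
    reference: MethylomeSample,
    partition: RegionPartition,
    min_coverage: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region information gain of ``subject`` relative to ``reference``.

    For each region the statistic is ``sum_i H(ref_i) - sum_i H(subj_i)``
    over sites present in *both* samples (same chrom, pos and strand) with at
    least ``min_coverage`` total reads in both.  Sites below coverage or
    missing from either sample are excluded rather than imputed.

    Returns
    -------
    (ir, n_sites)
        ``ir`` — array of length ``len(partition)`` in bits;
        ``n_sites`` — number of shared qualifying sites per region (regions
        with 0 such sites carry IR = 0 and are thereby flagged).
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    n = len(partition)
    if subject.sample_id == reference.sample_id:
        warnings.warn("subject is the reference sample; IR is identically zero")
        return np.zeros(n), np.zeros(n, dtype=np.int64)

    cols_r = ["chrom", "pos", "strand", "level"] + (
        ["total_reads"] if reference.has_counts else []
    )
    cols_s = ["chrom", "pos", "strand", "level"] + (
        ["total_reads"] if subject.has_counts else []
    )
    merged = pd.merge(
        reference.data[cols_r], subject.data[cols_s],
        on=["chrom", "pos", "strand"], suffixes=("_ref", "_sub"),
    )
    # level-only (wiggle) samples carry no counts and bypass the coverage cut
    mask = np.ones(len(merged), dtype=bool)
    if reference.has_counts:
        mask &= merged["total_reads_ref" if subject.has_counts else "total_reads"].to_numpy() >= min_coverage
    if subject.has_counts:
        mask &= merged["total_reads_sub" if reference.has_counts else "total_reads"].to_numpy() >= min_coverage
    merged = merged[mask]

    ir = np.zeros(n)
    n_sites = np.zeros(n, dtype=np.int64)
    if len(merged):
        idx = partition.assign(merged["chrom"].to_numpy(), merged["pos"].to_numpy())
        keep = idx >= 0
        idx = idx[keep]
        h_ref = site_entropy(merged["level_ref"].to_numpy()[keep])
        h_sub = site_entropy(merged["level_sub"].to_numpy()[keep])
        np.add.at(ir, idx, h_ref - h_sub)
        np.add.at(n_sites, idx, 1)
    return ir, n_sites


def build_ir_matrix(
    samples: Mapping[str, MethylomeSample] | Sequence[MethylomeSample],
    reference: MethylomeSample,
    partition: RegionPartition,
    min_coverage: int = 1,
    include_reference: bool = False,
) -> RegionMatrix:
    """Stack per-sample IR vectors into a samples x regions matrix."""
    if isinstance(samples, Mapping):
        samples = list(samples.values())
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    if include_reference:
        sample_ids.append(reference.sample_id)
        rows.append(np.zeros(len(partition)))
    for sample in samples:
        if sample.sample_id == reference.sample_id:
            continue
        ir, _ = region_information(sample, reference, partition, min_coverage)
        sample_ids.append(sample.sample_id)
        rows.append(ir)
    return RegionMatrix(
        sample_ids, list(partition.region_ids), np.vstack(rows),
        statistic="IR", reference_id=reference.sample_id,
    )


# ---------------------------------------------------------------------------
# LCR
# ---------------------------------------------------------------------------

def region_lcr(sample: SnpSample, partition: RegionPartition) -> np.ndarray:
    """Per-region sum of log2 normalized SNP supporting-read counts.

    Sites with normalized count ``rN = r * concordance`` below 1 are dropped
    (they would contribute negative uncertainty); regions with no qualifying
    SNP get 0.
    """
    n = len(partition)
    lcr = np.zeros(n)
    if not len(sample.data):
        return lcr
    rn = (sample.data["r"] * sample.data["concordance"]).to_numpy(dtype=float)
    keep = rn >= 1.0
    if not keep.any():
        return lcr
    data = sample.data[keep]
    idx = partition.assign(data["chrom"].to_numpy(), data["pos"].to_numpy())
    inside = idx >= 0
    np.add.at(lcr, idx[inside], np.log2(rn[keep][inside]))
    return lcr


def build_lcr_matrix(
    snp_samples: Mapping[str, SnpSample] | Sequence[SnpSample],
    partition: RegionPartition,
) -> RegionMatrix:
    if isinstance(snp_samples, Mapping):
        snp_samples = list(snp_samples.values())
    sample_ids = [s.sample_id for s in snp_samples]
    rows = [region_lcr(s, partition) for s in snp_samples]
    return RegionMatrix(
        sample_ids, list(partition.region_ids), np.vstack(rows), statistic="LCR",
    )


def site_lc_values(sample: SnpSample) -> np.ndarray:
    """Per-site log2 normalized counts (LC), for sites with rN >= 1."""
    if not len(sample.data):
        return np.empty(0)
    rn = (sample.data["r"] * sample.data["concordance"]).to_numpy(dtype=float)
    return np.log2(rn[rn >= 1.0])


# ---------------------------------------------------------------------------
# HMR / VMR / LMR taxonomy
# ---------------------------------------------------------------------------

def classify_regions(
    matrix: RegionMatrix, t1: float = DEFAULT_T1, t2: float = DEFAULT_T2
) -> np.ndarray:
    """Label each region LMR / VMR / HMR by its max |value| over samples.

    ``m < t1`` -> LMR, ``t1 <= m < t2`` -> VMR, ``m >= t2`` -> HMR.  The
    taxonomy is defined for IR matrices; other statistics are allowed but
    warned about.
    """
    if not t1 < t2:
        raise ValueError("thresholds must satisfy t1 < t2")
    if matrix.statistic != "IR":
        warnings.warn(
            f"region taxonomy is defined for IR matrices, got {matrix.statistic}"
        )
    m = np.abs(matrix.values).max(axis=0)
    labels = np.where(m >= t2, "HMR", np.where(m >= t1, "VMR", "LMR"))
    return labels


def exceedance_fraction(matrix: RegionMatrix, threshold: float = 10.0) -> float:
    """Percent of sample/region cells whose |value| is >= threshold."""
    cells = matrix.values.size
    if cells == 0:
        raise ValueError("empty matrix")
    count = int((np.abs(matrix.values) >= threshold).sum())
    return 100.0 * count / cells


# ---------------------------------------------------------------------------
# heatmap export
# ---------------------------------------------------------------------------

def export_heatmap(matrix: RegionMatrix, path, cmap: str = "viridis") -> None:
    """Render the matrix as a heatmap PNG, color scale clipped to the
    observed min/max of the values."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, max(2, matrix.n_samples * 0.25)))
    vmin, vmax = float(matrix.values.min()), float(matrix.values.max())
    im = ax.imshow(matrix.values, aspect="auto", cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_yticks(range(matrix.n_samples))
    ax.set_yticklabels(matrix.sample_ids, fontsize=6)
    ax.set_xlabel("region index")
    fig.colorbar(im, ax=ax, label=matrix.statistic)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
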