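"""Synthetic methylome / SNP cohorts with known ground truth.

The generator produces exactly the table dialects of :mod:`methylinfo.io`,
so the full pipeline runs on its output unmodified.  Structure baked in:

* a bimodal (Beta-mixture) baseline methylation landscape, as in real CG
  methylomes where most sites sit near level 0 or 1;
* per-site read counts: Poisson coverage, binomial methylated reads;
* group-structured hotspot regions — a fraction of regions receive a
  group-specific methylation-level shift, giving those groups a nonzero
  expected per-region information change versus the reference;
* SNP supporting-read log-counts drawn from the Boltzmann law of
  :mod:`methylinfo.boltzmann`, with concordance back-solved from the target
  normalized count so files regenerate each LC value exactly;
* tunable coupling between the methylation-shift magnitude and the SNP
  intensity of a hotspot via an FGM-copula pair per region, so the joint
  (IR, LCR) dependence is reproducible at a chosen strength.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .boltzmann import sample_lc
from .copula import sample_fgm
from .infostats import site_entropy
from .io import (
    METH_COLUMNS,
    SNP_COLUMNS,
    MethylomeSample,
    RegionPartition,
    SnpSample,
    make_partition,
    write_chrom_sizes,
    write_labels_tsv,
    write_methylation_tsv,
    write_snp_tsv,
)
from .utils import derive_seed

CHROM = "chr1"
SITE_SPACING = 10
BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; the seed is mandatory."""

    seed: int
    n_groups: int = 3
    samples_per_group: int = 15
    n_regions: int = 500
    sites_per_region: int = 10
    hotspot_fraction: float = 0.2
    hotspot_effect: float = 0.5   # methylation-level shift magnitude
    coverage_mean: float = 20.0
    snp_rate: float = 3.0         # mean SNPs per region per sample (baseline)
    snp_boost: float = 4.0        # extra intensity factor scale in hotspots
    boltzmann_lambda: float = 0.9
    boltzmann_beta: float = 0.5
    theta: float = 0.0            # FGM coupling of shift magnitude vs SNP intensity
    baseline_low: tuple[float, float] = (0.5, 8.0)   # Beta params, low mode
    baseline_high: tuple[float, float] = (8.0, 0.5)  # Beta params, high mode
    baseline_weight_low: float = 0.5

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_groups < 1 or self.samples_per_group < 1:
            raise ValueError("need at least one group and one sample per group")
        if self.n_regions < 1 or self.sites_per_region < 1:
            raise ValueError("need at least one region and one site per region")
        if not (0.0 <= self.hotspot_fraction <= 1.0):
            raise ValueError("hotspot_fraction must be in [0, 1]")
        if not (0.0 <= self.hotspot_effect <= 1.0):
            raise ValueError("hotspot_effect must be in [0, 1]")
        if self.coverage_mean <= 0 or self.snp_rate < 0 or self.snp_boost < 0:
            raise ValueError("rates must be non-negative (coverage positive)")
        if not (0.0 < self.boltzmann_lambda <= 1.0) or self.boltzmann_beta <= 0:
            raise ValueError("boltzmann parameters out of range")
        if not (-1.0 <= self.theta <= 1.0):
            raise ValueError("theta must be in [-1, 1]")
        if not (0.0 <= self.baseline_weight_low <= 1.0):
            raise ValueError("baseline_weight_low must be in [0, 1]")

    @property
    def region_width(self) -> int:
        return SITE_SPACING * self.sites_per_region

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {CHROM: self.n_regions * self.region_width}

    def partition(self) -> RegionPartition:
        return make_partition(self.chrom_sizes, self.region_width)

    def site_positions(self) -> np.ndarray:
        """1-based positions of all simulated cytosines, region-major."""
        region = np.repeat(np.arange(self.n_regions), self.sites_per_region)
        site = np.tile(np.arange(self.sites_per_region), self.n_regions)
        return region * self.region_width + site * SITE_SPACING + 5


@dataclass
class SimulationTruth:
    """Everything needed to compute expected region statistics analytically."""

    theta: float
    boltzmann_lambda: float
    boltzmann_beta: float
    labels: dict[str, str]
    baseline_levels: np.ndarray       # (n_regions, sites_per_region)
    is_hotspot: np.ndarray            # (n_regions,) bool
    target_group: np.ndarray          # (n_regions,) int, -1 for non-hotspots
    magnitude: np.ndarray             # (n_regions,) shift magnitude
    sign: np.ndarray                  # (n_regions,) +-1
    shifted_levels: np.ndarray        # (n_regions, sites_per_region)
    fgm_u: np.ndarray                 # (n_regions,)
    fgm_v: np.ndarray                 # (n_regions,)
    snp_intensity: np.ndarray         # (n_regions,) hotspot intensity factor

    def to_json(self, path) -> None:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {
            "baseline_levels", "is_hotspot", "target_group", "magnitude",
            "sign", "shifted_levels", "fgm_u", "fgm_v", "snp_intensity",
        }
        kwargs = {
            k: (np.asarray(v) if k in arrays else v) for k, v in payload.items()
        }
        kwargs["is_hotspot"] = kwargs["is_hotspot"].astype(bool)
        return cls(**kwargs)


@dataclass
class SimulatedCohort:
    reference: MethylomeSample
    samples: dict[str, MethylomeSample]
    snp_samples: dict[str, SnpSample]
    labels: dict[str, str]
    truth: SimulationTruth
    partition: RegionPartition
    config: SimulationConfig


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _baseline_levels(config: SimulationConfig) -> np.ndarray:
    rng = np.random.default_rng(derive_seed(config.seed, "baseline"))
    n = config.n_regions * config.sites_per_region
    low = rng.uniform(size=n) < config.baseline_weight_low
    a_lo, b_lo = config.baseline_low
    a_hi, b_hi = config.baseline_high
    levels = np.where(
        low, rng.beta(a_lo, b_lo, size=n), rng.beta(a_hi, b_hi, size=n)
    )
    return levels.reshape(config.n_regions, config.sites_per_region)


def _counts_sample(
    sample_id: str, levels: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> MethylomeSample:
    flat = levels.ravel()
    coverage = np.maximum(1, rng.poisson(config.coverage_mean, size=flat.size))
    meth = rng.binomial(coverage, flat)
    df = pd.DataFrame(
        {
            "chrom": CHROM,
            "pos": config.site_positions(),
            "strand": "+",
            "context": "CG",
            "meth_reads": meth,
            "total_reads": coverage,
        },
        columns=list(METH_COLUMNS),
    )
    return MethylomeSample(sample_id, df)


def simulate_reference(config: SimulationConfig) -> MethylomeSample:
    """Reference methylome: baseline levels observed through read noise."""
    rng = np.random.default_rng(derive_seed(config.seed, "reference"))
    return _counts_sample("reference", _baseline_levels(config), config, rng)


def _plan_regions(config: SimulationConfig):
    """Hotspot placement, per-region FGM pair, shift magnitude, SNP intensity."""
    rng = np.random.default_rng(derive_seed(config.seed, "regions"))
    n = config.n_regions
    n_hot = int(round(config.hotspot_fraction * n))
    hot_idx = rng.choice(n, size=n_hot, replace=False) if n_hot else np.empty(0, int)
    is_hotspot = np.zeros(n, dtype=bool)
    is_hotspot[hot_idx] = True

    target_group = np.full(n, -1, dtype=int)
    # spread hotspots round-robin across groups so every group has signal
    target_group[np.sort(hot_idx)] = np.arange(n_hot) % config.n_groups

    u, v = sample_fgm(n, config.theta, rng)
    magnitude = np.where(is_hotspot, config.hotspot_effect * (0.5 + 0.5 * u), 0.0)
    sign = np.where(rng.uniform(size=n) < 0.5, -1.0, 1.0)
    snp_intensity = np.where(is_hotspot, 1.0 + config.snp_boost * v, 1.0)
    return is_hotspot, target_group, magnitude, sign, u, v, snp_intensity


def _random_snp_sample(
    sample_id: str,
    rates: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SnpSample:
    width = config.region_width
    rows: list[tuple] = []
    n_snps = np.minimum(rng.poisson(rates), width)
    for j in np.flatnonzero(n_snps):
        k = int(n_snps[j])
        offsets = rng.choice(width, size=k, replace=False)
        lc = sample_lc(k, config.boltzmann_lambda, config.boltzmann_beta, rng)
        rn = np.exp2(lc)  # rN >= 1 exactly when lc >= 0
        r = np.ceil(rn).astype(int)
        concordance = rn / r  # back-solved: r * concordance == rn exactly
        quality = 25.0 + rng.poisson(10.0, size=k)
        ref_idx = rng.integers(0, 4, size=k)
        alt_idx = (ref_idx + rng.integers(1, 4, size=k)) % 4
        start = j * width + 1
        for o, lcv, rr, cc, qq, ri, ai in zip(
            np.sort(offsets), lc, r, concordance, quality, ref_idx, alt_idx
        ):
            rows.append(
                (CHROM, int(start + o), BASES[ri], BASES[ai], float(qq), int(rr), float(cc))
            )
    df = pd.DataFrame(rows, columns=list(SNP_COLUMNS))
    return SnpSample(sample_id, df)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full cohort: reference, group samples, SNP tables, truth."""
    baseline = _baseline_levels(config)
    is_hotspot, target_group, magnitude, sign, u, v, snp_intensity = _plan_regions(config)

    raw_shift = baseline + (sign * magnitude)[:, None]
    shifted = np.clip(raw_shift, 0.0, 1.0)
    if np.any(raw_shift != shifted):
        warnings.warn("hotspot shifts pushed some levels outside [0, 1]; clipped")

    reference = simulate_reference(config)
    samples: dict[str, MethylomeSample] = {}
    snp_samples: dict[str, SnpSample] = {}
    labels: dict[str, str] = {}
    for g in range(config.n_groups):
        group_levels = np.where(
            (is_hotspot & (target_group == g))[:, None], shifted, baseline
        )
        group_rates = config.snp_rate * np.where(
            is_hotspot & (target_group == g), snp_intensity, 1.0
        )
        for i in range(config.samples_per_group):
            sid = f"g{g}s{i:02d}"
            rng = np.random.default_rng(derive_seed(config.seed, f"sample:{sid}"))
            samples[sid] = _counts_sample(sid, group_levels, config, rng)
            snp_samples[sid] = _random_snp_sample(sid, group_rates, config, rng)
            labels[sid] = f"G{g}"

    truth = SimulationTruth(
        theta=config.theta,
        boltzmann_lambda=config.boltzmann_lambda,
        boltzmann_beta=config.boltzmann_beta,
        labels=labels,
        baseline_levels=baseline,
        is_hotspot=is_hotspot,
        target_group=target_group,
        magnitude=magnitude,
        sign=sign,
        shifted_levels=shifted,
        fgm_u=u,
        fgm_v=v,
        snp_intensity=snp_intensity,
    )
    return SimulatedCohort(
        reference=reference,
        samples=samples,
        snp_samples=snp_samples,
        labels=labels,
        truth=truth,
        partition=config.partition(),
        config=config,
    )


def expected_ir(truth: SimulationTruth, region: int, group: int) -> float:
    """Closed-form expected information change of a region for one group:
    sum over sites of H(baseline) - H(shifted), nonzero only when the region
    is a hotspot targeting that group."""
    if not (0 <= region < len(truth.is_hotspot)):
        raise ValueError(f"region {region} outside the simulated range")
    if not truth.is_hotspot[region] or truth.target_group[region] != group:
        return 0.0
    h_before = site_entropy(truth.baseline_levels[region])
    h_after = site_entropy(truth.shifted_levels[region])
    return float(np.sum(h_before - h_after))


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write the cohort as plain-text files in the pipeline's dialects."""
    outdir = Path(outdir)
    meth_dir = outdir / "methylation"
    snp_dir = outdir / "snps"
    meth_dir.mkdir(parents=True, exist_ok=True)
    snp_dir.mkdir(parents=True, exist_ok=True)
    write_methylation_tsv(cohort.reference, meth_dir / "reference.tsv")
    for sid, sample in cohort.samples.items():
        write_methylation_tsv(sample, meth_dir / f"{sid}.tsv")
    for sid, sample in cohort.snp_samples.items():
        write_snp_tsv(sample, snp_dir / f"{sid}.tsv")
    write_labels_tsv(cohort.labels, outdir / "labels.tsv")
    write_chrom_sizes(cohort.config.chrom_sizes, outdir / "chrom_sizes.txt")
    cohort.truth.to_json(outdir / "truth.json")
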