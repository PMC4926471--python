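import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylinfo.infostats import (
    RegionMatrix,
    build_ir_matrix,
    classify_regions,
    exceedance_fraction,
    landauer_limit,
    region_information,
    region_lcr,
    site_entropy,
)
from methylinfo.io import SnpSample, SnpSite, make_partition

from conftest import make_meth_sample


def h2(p):
    """Independent binary-entropy oracle."""
    s = 0.0
    for q in (p, 1.0 - p):
        if q > 0:
            s -= q * math.log2(q)
    return s


def ir_oracle(subject, reference, partition, min_coverage=1):
    """Brute-force per-site entropy-difference sum, dict-based."""
    ref = {(s.chrom, s.pos, s.strand): s for s in reference.sites()}
    out = np.zeros(len(partition))
    for s in subject.sites():
        key = (s.chrom, s.pos, s.strand)
        if key not in ref:
            continue
        r = ref[key]
        if s.total_reads < min_coverage or r.total_reads < min_coverage:
            continue
        for i, (chrom, start, end) in enumerate(partition):
            if chrom == s.chrom and start < s.pos <= end:
                out[i] += h2(r.level) - h2(s.level)
                break
    return out


def random_toy_pair(rng, n_sites=20, chrom_size=200):
    """Two samples over a random subset of shared/unshared sites."""
    def sample(sid):
        positions = rng.choice(chrom_size, size=n_sites, replace=False) + 1
        rows = []
        for pos in sorted(positions):
            total = int(rng.integers(1, 20))
            rows.append(("chr1", int(pos), "+", "CG", int(rng.integers(0, total + 1)), total))
        return make_meth_sample(sid, rows)

    return sample("a"), sample("b")


# ---------------------------------------------------------------------------
# site entropy
# ---------------------------------------------------------------------------

def test_site_entropy_values():
    assert site_entropy(0.5) == pytest.approx(1.0)
    assert site_entropy(0.0) == 0.0
    assert site_entropy(1.0) == 0.0
    assert site_entropy(0.25) == pytest.approx(0.811278, abs=1e-6)


def test_site_entropy_domain_error():
    with pytest.raises(ValueError):
        site_entropy(-0.1)
    with pytest.raises(ValueError):
        site_entropy(1.1)


@settings(max_examples=100, deadline=None)
@given(p=st.floats(0.0, 1.0))
def test_site_entropy_properties(p):
    h = site_entropy(p)
    assert 0.0 <= h <= 1.0
    assert h == pytest.approx(site_entropy(1.0 - p), abs=1e-12)


# ---------------------------------------------------------------------------
# region information
# ---------------------------------------------------------------------------

def test_ir_zero_for_identical_sample():
    sample = make_meth_sample("a", [("chr1", 5, "+", "CG", 2, 4)])
    part = make_partition({"chr1": 10}, 10)
    with pytest.warns(UserWarning):
        ir, n = region_information(sample, sample, part)
    assert ir[0] == 0.0


def test_ir_three_sites_plus_three_bits():
    ref = make_meth_sample("ref", [
        ("chr1", 2, "+", "CG", 1, 2),
        ("chr1", 4, "+", "CG", 2, 4),
        ("chr1", 6, "+", "CG", 5, 10),
    ])
    sub = make_meth_sample("sub", [
        ("chr1", 2, "+", "CG", 0, 2),
        ("chr1", 4, "+", "CG", 4, 4),
        ("chr1", 6, "+", "CG", 0, 10),
    ])
    part = make_partition({"chr1": 10}, 10)
    ir, n = region_information(sub, ref, part)
    assert ir[0] == pytest.approx(3.0)
    assert n[0] == 3


def test_ir_information_loss_minus_one_bit():
    ref = make_meth_sample("ref", [("chr1", 2, "+", "CG", 4, 4)])
    sub = make_meth_sample("sub", [("chr1", 2, "+", "CG", 2, 4)])
    part = make_partition({"chr1": 10}, 10)
    ir, _ = region_information(sub, ref, part)
    assert ir[0] == pytest.approx(-1.0)


def test_ir_min_coverage_excludes_sites():
    ref = make_meth_sample("ref", [
        ("chr1", 2, "+", "CG", 1, 2),
        ("chr1", 4, "+", "CG", 5, 10),
    ])
    sub = make_meth_sample("sub", [
        ("chr1", 2, "+", "CG", 2, 2),
        ("chr1", 4, "+", "CG", 10, 10),
    ])
    part = make_partition({"chr1": 10}, 10)
    ir, n = region_information(sub, ref, part, min_coverage=5)
    assert n[0] == 1  # the coverage-2 site is excluded from both sums
    assert ir[0] == pytest.approx(1.0)


def test_ir_strand_is_part_of_the_key():
    ref = make_meth_sample("ref", [("chr1", 2, "+", "CG", 1, 2)])
    sub = make_meth_sample("sub", [("chr1", 2, "-", "CG", 0, 2)])
    part = make_partition({"chr1": 10}, 10)
    ir, n = region_information(sub, ref, part)
    assert n[0] == 0 and ir[0] == 0.0


def test_ir_matches_brute_force_oracle(rng):
    part = make_partition({"chr1": 200}, 37)
    for _ in range(25):
        a, b = random_toy_pair(rng)
        ir, _ = region_information(a, b, part)
        assert np.allclose(ir, ir_oracle(a, b, part), atol=1e-12)


def test_ir_antisymmetry(rng):
    part = make_partition({"chr1": 200}, 50)
    a, b = random_toy_pair(rng)
    ir_ab, _ = region_information(a, b, part)
    ir_ba, _ = region_information(b, a, part)
    assert np.allclose(ir_ab, -ir_ba, atol=1e-15)


def test_ir_subpartition_additivity(rng):
    a, b = random_toy_pair(rng)
    coarse = make_partition({"chr1": 200}, 100)
    fine = make_partition({"chr1": 200}, 20)
    ir_coarse, _ = region_information(a, b, coarse)
    ir_fine, _ = region_information(a, b, fine)
    assert ir_coarse[0] == pytest.approx(ir_fine[:5].sum(), abs=1e-12)
    assert ir_coarse[1] == pytest.approx(ir_fine[5:].sum(), abs=1e-12)


def test_ir_bounded_by_site_count(rng):
    part = make_partition({"chr1": 200}, 40)
    for _ in range(10):
        a, b = random_toy_pair(rng)
        ir, n = region_information(a, b, part)
        assert np.all(np.abs(ir) <= n + 1e-12)


def test_wiggle_sample_bypasses_coverage(tmp_path):
    import pandas as pd

    from methylinfo.io import MethylomeSample

    ref = make_meth_sample("ref", [("chr1", 2, "+", "CG", 1, 2)])
    track = MethylomeSample(
        "w",
        pd.DataFrame({"chrom": ["chr1"], "pos": [2], "strand": ["+"],
                      "context": ["CG"], "level": [1.0]}),
        has_counts=False,
    )
    part = make_partition({"chr1": 10}, 10)
    ir, n = region_information(track, ref, part, min_coverage=100)
    # reference side still fails its coverage cut at 100
    assert n[0] == 0
    ir, n = region_information(track, ref, part, min_coverage=2)
    assert n[0] == 1
    assert ir[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# LCR
# ---------------------------------------------------------------------------

def snp_sample(rows):
    return SnpSample.from_sites("s", (SnpSite("chr1", p, "A", "G", 30.0, r, c) for p, r, c in rows))


def test_lcr_empty_region():
    part = make_partition({"chr1": 10}, 10)
    empty = SnpSample("s", __import__("pandas").DataFrame(columns=["chrom", "pos", "ref_base", "alt_base", "quality", "r", "concordance"]))
    assert region_lcr(empty, part)[0] == 0.0


def test_lcr_single_snp():
    part = make_partition({"chr1": 10}, 10)
    assert region_lcr(snp_sample([(3, 8, 1.0)]), part)[0] == pytest.approx(3.0)


def test_lcr_hand_sum():
    part = make_partition({"chr1": 10}, 10)
    lcr = region_lcr(snp_sample([(3, 8, 0.5), (7, 4, 0.5)]), part)
    assert lcr[0] == pytest.approx(2.0 + 1.0)


def test_lcr_drops_subunit_rn():
    part = make_partition({"chr1": 10}, 10)
    lcr = region_lcr(snp_sample([(3, 2, 0.25)]), part)  # rN = 0.5 < 1
    assert lcr[0] == 0.0


def test_lcr_monotone_in_rn(rng):
    part = make_partition({"chr1": 100}, 100)
    rows = [(int(p), int(r), float(c)) for p, r, c in zip(
        rng.choice(100, 10, replace=False) + 1, rng.integers(1, 30, 10), rng.uniform(0.3, 1.0, 10))]
    base = region_lcr(snp_sample(rows), part)[0]
    bumped_rows = [(p, r + 5, c) for p, r, c in rows]
    assert region_lcr(snp_sample(bumped_rows), part)[0] >= base


# ---------------------------------------------------------------------------
# RegionMatrix and taxonomy
# ---------------------------------------------------------------------------

def test_region_matrix_round_trip(tmp_path, rng):
    m = RegionMatrix(
        ["a", "b"], ["r1", "r2", "r3"], rng.normal(size=(2, 3)) * 10,
        statistic="IR", reference_id="ref",
    )
    path = tmp_path / "m.tsv"
    m.to_tsv(path)
    back = RegionMatrix.from_tsv(path)
    assert back.sample_ids == m.sample_ids
    assert back.region_ids == m.region_ids
    assert back.statistic == "IR" and back.reference_id == "ref"
    back.to_tsv(tmp_path / "m2.tsv")
    assert (tmp_path / "m.tsv").read_bytes() == (tmp_path / "m2.tsv").read_bytes()


def test_reference_row_is_zero(small_cohort):
    matrix = build_ir_matrix(
        small_cohort.samples, small_cohort.reference, small_cohort.partition,
        include_reference=True,
    )
    assert matrix.sample_ids[0] == "reference"
    assert np.all(matrix.values[0] == 0.0)


def test_classify_regions_thresholds():
    m = RegionMatrix(["a"], ["r1", "r2", "r3"], [[15.0, 0.0, -5.0]])
    labels = classify_regions(m, t1=2.0, t2=10.0)
    assert list(labels) == ["HMR", "LMR", "VMR"]


def test_classify_regions_bad_thresholds():
    m = RegionMatrix(["a"], ["r1"], [[0.0]])
    with pytest.raises(ValueError):
        classify_regions(m, t1=5.0, t2=5.0)


def test_classify_regions_warns_on_non_ir():
    m = RegionMatrix(["a"], ["r1"], [[0.0]], statistic="LCR")
    with pytest.warns(UserWarning):
        classify_regions(m)


def test_exceedance_fraction_worked_example():
    # 13,370 regions x 9 samples with exactly 12,971 cells at |IR| >= 10
    n_regions, n_samples, n_hot = 13_370, 9, 12_971
    values = np.zeros((n_samples, n_regions))
    flat = values.reshape(-1)
    flat[:n_hot] = 12.0
    m = RegionMatrix([f"s{i}" for i in range(n_samples)],
                     [f"r{j}" for j in range(n_regions)], values)
    pct = exceedance_fraction(m, 10.0)
    assert pct == pytest.approx(100 * 12_971 / 120_330)
    assert round(pct) == 11


def test_heatmap_export(tmp_path, rng):
    from methylinfo.infostats import export_heatmap

    m = RegionMatrix(["a", "b"], [f"r{i}" for i in range(20)],
                     rng.normal(size=(2, 20)) * 10)
    out = tmp_path / "heat.png"
    export_heatmap(m, out)
    assert out.stat().st_size > 0


def test_landauer_limit():
    value = landauer_limit()
    # one significant figure: 3e-21 J
    assert f"{value:.0e}" == "3e-21"
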