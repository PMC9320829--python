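import itertools
import math

import numpy as np
import pytest

from antdiv.variants import (
    FilterReport,
    depth_envelope_filter,
    exclude_regions,
    filter_cascade,
    filter_sites,
    hwe_het_excess_pvalue,
    mask_genotypes,
    thin,
)

from .conftest import make_table


# ----------------------------------------------------------------------
# genotype masking
# ----------------------------------------------------------------------


@pytest.mark.parametrize(
    "gt, dp, gq, expect",
    [
        (1, 20, 29, -1),  # GQ below threshold
        (1, 8, 30, 1),    # both exactly at the inclusive boundary
        (2, 7, 45, -1),   # DP below threshold
        (0, 8, 99, 0),
    ],
)
def test_mask_genotypes_boundaries(gt, dp, gq, expect):
    t = make_table([[gt]], dp=[[dp]], gq=[[gq]])
    out, _ = mask_genotypes(t)
    assert out.gt[0, 0] == expect


def test_mask_genotypes_requires_fields():
    t = make_table([[1]])
    with pytest.raises(ValueError, match="GQ"):
        mask_genotypes(t)


# ----------------------------------------------------------------------
# site filters
# ----------------------------------------------------------------------


def test_missingness_strict_majority():
    """11/20 missing removed; 10/20 retained (strictly-more-than-half)."""
    row_keep = [0] * 10 + [-1] * 10
    row_drop = [0] * 9 + [-1] * 11
    t = make_table([row_keep, row_drop])
    out, report = filter_sites(t)
    assert out.n_sites == 1
    assert out.pos[0] == t.pos[0]
    stage = {s["stage"]: s for s in report.stages}
    assert stage["missingness"]["sites_removed"] == 1


def test_all_heterozygote_site_removed_all_homref_retained():
    t = make_table([[1] * 20, [0] * 20])
    out, _ = filter_sites(t)
    assert out.n_sites == 1
    assert (out.gt == 0).all()


def test_qual_and_biallelic_filter():
    t = make_table([[0, 1], [0, 1], [0, 1]], qual=[29.9, 30.0, 60.0])
    t.n_alt_alleles[2] = 2
    out, _ = filter_sites(t)
    assert out.n_sites == 1
    assert out.qual[0] == 30.0


def test_zero_genotyped_sites_counted_separately():
    t = make_table([[-1, -1], [0, 1]])
    out, report = filter_sites(t)
    assert out.n_sites == 1
    stage = {s["stage"]: s for s in report.stages}
    assert stage["zero_genotyped"]["sites_removed"] == 1


# ----------------------------------------------------------------------
# exact heterozygote-excess test
# ----------------------------------------------------------------------


def _slot_enumeration_pvalue(n_hom_ref, n_het, n_hom_alt):
    """Independent oracle: enumerate every placement of the alternate
    copies into the 2n gene-copy slots (individual i owns slots 2i, 2i+1)."""
    n = n_hom_ref + n_het + n_hom_alt
    m = n_het + 2 * n_hom_alt
    hits = total = 0
    for slots in itertools.combinations(range(2 * n), m):
        owners = [s // 2 for s in slots]
        het = sum(1 for i in set(owners) if owners.count(i) == 1)
        total += 1
        if het >= n_het:
            hits += 1
    return hits / total


@pytest.mark.parametrize(
    "config",
    [(4, 0, 0), (0, 4, 0), (1, 2, 1), (2, 2, 2), (3, 1, 1), (0, 2, 3)],
)
def test_hwe_pvalue_matches_slot_enumeration(config):
    assert hwe_het_excess_pvalue(*config) == pytest.approx(
        _slot_enumeration_pvalue(*config), abs=1e-12
    )


def _config_enumeration_pvalue(n, m, h_obs):
    """Second oracle (n <= 30): enumerate heterozygote counts with exact
    integer pairing multiplicities."""
    total = math.comb(2 * n, m)
    acc = 0
    for h in range(m % 2, min(m, 2 * n - m) + 1, 2):
        naa = (m - h) // 2
        naA = n - h - naa
        if naA < 0 or h < h_obs:
            continue
        acc += (
            math.factorial(n)
            // (math.factorial(naA) * math.factorial(h) * math.factorial(naa))
            * 2**h
        )
    return acc / total


@pytest.mark.parametrize("n", [10, 20, 30])
def test_hwe_pvalue_matches_enumeration_large_n(n):
    rng = np.random.default_rng(n)
    for _ in range(25):
        m = int(rng.integers(0, 2 * n + 1))
        hmax = min(m, 2 * n - m)
        h = int(rng.integers(m % 2, hmax + 1)) if hmax >= m % 2 else m % 2
        if (h - m) % 2:
            h = max(m % 2, h - 1)
        nalt = (m - h) // 2
        assert hwe_het_excess_pvalue(n - h - nalt, h, nalt) == pytest.approx(
            _config_enumeration_pvalue(n, m, h), rel=1e-12
        )


def test_hwe_monomorphic_site_p_one():
    assert hwe_het_excess_pvalue(20, 0, 0) == 1.0
    assert hwe_het_excess_pvalue(0, 0, 20) == 1.0


# ----------------------------------------------------------------------
# depth envelope
# ----------------------------------------------------------------------


def test_depth_envelope_boundaries():
    """Mean 15.6: envelope [7.8, 31.2]; DP 7 masked, DP 8 and 31 kept."""
    gt = [[1, 1, 1]]
    dp = [[7, 8, 31]]
    t = make_table(gt, dp=dp, gq=[[99, 99, 99]])
    out, _ = depth_envelope_filter(t, mean_depths=[15.6, 15.6, 15.6])
    assert out.gt[0].tolist() == [-1, 1, 1]


def test_depth_envelope_identity_when_inside():
    gt = [[0, 1], [1, 2]]
    dp = [[10, 20], [15, 30]]
    t = make_table(gt, dp=dp, gq=[[99, 99]] * 2)
    out, _ = depth_envelope_filter(t, mean_depths=[15.6, 15.6])
    np.testing.assert_array_equal(out.gt, t.gt)


def test_depth_envelope_reapplies_missingness():
    gt = [[1, 1]]
    dp = [[5, 5]]  # both out of envelope -> site all-missing -> dropped
    t = make_table(gt, dp=dp, gq=[[99, 99]])
    out, report = depth_envelope_filter(t, mean_depths=[15.6, 15.6])
    assert out.n_sites == 0
    assert report.stages[0]["genotypes_masked"] == 2


def test_depth_envelope_rejects_bad_mean():
    t = make_table([[1]], dp=[[10]], gq=[[99]])
    with pytest.raises(ValueError, match="mean depth"):
        depth_envelope_filter(t, mean_depths=[0.0])


# ----------------------------------------------------------------------
# region exclusion and thinning
# ----------------------------------------------------------------------


def test_gene_flank_closed_interval():
    import pandas as pd

    genes = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [2000]})
    t = make_table([[0, 1]] * 2, pos=[12_000, 12_001])
    out, _ = exclude_regions(t, gff=genes, flank_bp=10_000)
    assert out.pos.tolist() == [12_001]


def test_exclude_chromosome_and_unknown_warning():
    t = make_table([[0, 1]] * 4, chrom=["chr1", "chr1", "chr3", "chr3"],
                   pos=[100, 200, 100, 200])
    with pytest.warns(UserWarning, match="chrX"):
        out, _ = exclude_regions(t, exclude_chroms=["chr3", "chrX"])
    assert set(out.chrom) == {"chr1"}


def test_random_intervals_match_brute_force():
    import pandas as pd

    rng = np.random.default_rng(3)
    starts = np.sort(rng.integers(1, 100_000, size=15))
    genes = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + rng.integers(100, 5000, 15)}
    )
    pos = np.sort(rng.choice(np.arange(1, 120_000), size=300, replace=False))
    t = make_table([[0, 1]] * 300, pos=pos)
    flank = 1_500
    out, _ = exclude_regions(t, gff=genes, flank_bp=flank)
    keep_brute = [
        p for p in pos
        if not any(
            max(1, s - flank) <= p <= e + flank
            for s, e in zip(genes["start"], genes["end"])
        )
    ]
    assert out.pos.tolist() == keep_brute


def test_thin_keeps_every_kth():
    t = make_table([[0, 1]] * 1000)
    assert thin(t, 200).n_sites == 5
    np.testing.assert_array_equal(thin(t, 1).pos, t.pos)


# ----------------------------------------------------------------------
# cascade properties
# ----------------------------------------------------------------------


def _random_table(rng, n_sites=300, n_samples=8, chroms=("chr1", "chr2", "chr3")):
    gt = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    gt[rng.random(gt.shape) < 0.2] = -1
    dp = rng.poisson(15, size=gt.shape).astype(np.int32)
    gq = rng.integers(0, 100, size=gt.shape).astype(np.int32)
    chrom = np.sort(rng.choice(chroms, size=n_sites)).astype(object)
    pos = np.zeros(n_sites, dtype=np.int64)
    for c in chroms:
        k = int((chrom == c).sum())
        pos[chrom == c] = np.sort(
            rng.choice(np.arange(1, 1_000_000), size=k, replace=False)
        )
    qual = rng.uniform(10, 200, size=n_sites)
    return make_table(gt, chrom=chrom, pos=pos, qual=qual, dp=dp, gq=gq)


def test_cascade_commutes_with_chromosome_partition():
    rng = np.random.default_rng(11)
    t = _random_table(rng)
    means = np.full(t.n_samples, 15.0)
    full, _ = filter_cascade(t, mean_depths=means)
    parts = []
    for c in ("chr1", "chr2", "chr3"):
        sub = t.take_sites(t.chrom == c)
        out, _ = filter_cascade(sub, mean_depths=means)
        parts.append(out)
    merged_pos = np.concatenate([p.pos for p in parts])
    merged_gt = np.vstack([p.gt for p in parts])
    np.testing.assert_array_equal(full.pos, merged_pos)
    np.testing.assert_array_equal(full.gt, merged_gt)


def test_cascade_monotone_and_report_reconciles():
    rng = np.random.default_rng(12)
    t = _random_table(rng)
    out, report = filter_cascade(
        t, mean_depths=np.full(t.n_samples, 15.0), exclude_chroms=["chr3"]
    )
    n = t.n_sites
    for s in report.stages:
        assert s["sites_in"] == n
        assert s["sites_out"] == s["sites_in"] - s["sites_removed"]
        assert s["sites_removed"] >= 0
        n = s["sites_out"]
    assert n == out.n_sites
    assert set(map(tuple, np.c_[out.chrom, out.pos])) <= set(
        map(tuple, np.c_[t.chrom, t.pos])
    )


def test_report_rejects_negative_counts():
    r = FilterReport()
    with pytest.raises(ValueError):
        r.add("bad", 10, -1)
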