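import numpy as np
import pytest

from antdiv.coalescent import fold_joint
from antdiv.sfs import (
    Folded2DSFS,
    attach_monomorphic,
    build_folded_sfs,
    fold_counts,
    read_obs,
    resample_windows,
    write_obs,
)

from .conftest import make_table


def _data_from_counts(c1, c2, n1=4, n2=4, windows=None, pos=None):
    from antdiv.sfs import ResampledData

    c1 = np.asarray(c1, dtype=np.int64)
    k = c1.size
    return ResampledData(
        chrom=np.repeat("chr1", k).astype(object),
        pos=np.arange(1, k + 1) * 10 if pos is None else np.asarray(pos),
        window=np.zeros(k, dtype=np.int64) if windows is None else np.asarray(windows),
        c1=c1,
        c2=np.asarray(c2, dtype=np.int64),
        n1=n1,
        n2=n2,
        pop1="pol",
        pop2="aq",
        n_snps_input=k,
    )


# ----------------------------------------------------------------------
# folding
# ----------------------------------------------------------------------


def test_fold_minor_allele_examples():
    """(1,0) of 8 stays; (3,4) of 8 folds to its minor complement (1,0)."""
    data = _data_from_counts([1, 3], [0, 4])
    sfs = build_folded_sfs(data)
    assert sfs.counts[1, 0] == 2
    assert sfs.counts.sum() == 2


def test_fold_tie_rule_lexicographic():
    """Counts summing to exactly half fold to the smaller pair: (3,1) of 8
    maps to (1,3); the self-mirror (2,2) stays."""
    data = _data_from_counts([3, 2], [1, 2])
    sfs = build_folded_sfs(data)
    assert sfs.counts[1, 3] == 1
    assert sfs.counts[2, 2] == 1
    assert sfs.counts[3, 1] == 0


def test_fold_idempotent_on_random_matrices():
    rng = np.random.default_rng(4)
    for _ in range(20):
        m = rng.integers(0, 50, size=(rng.integers(2, 7), rng.integers(2, 7)))
        folded = fold_counts(m)
        np.testing.assert_array_equal(fold_counts(folded), folded)
        assert folded.sum() == m.sum()


def test_fold_joint_conserves_mass():
    rng = np.random.default_rng(5)
    m = rng.random((5, 5))
    assert fold_joint(m).sum() == pytest.approx(m.sum())


def test_population_swap_transposes():
    rng = np.random.default_rng(6)
    data = _data_from_counts(
        rng.integers(0, 5, 500), rng.integers(0, 5, 500)
    )
    a = build_folded_sfs(data)
    b = build_folded_sfs(data, swap=True)
    np.testing.assert_array_equal(b.counts, fold_counts(a.counts.T))
    np.testing.assert_array_equal(
        a.transposed().counts, b.counts
    )


def test_sfs_matches_per_site_brute_force():
    rng = np.random.default_rng(7)
    c1 = rng.integers(0, 5, 1000)
    c2 = rng.integers(0, 5, 1000)
    sfs = build_folded_sfs(_data_from_counts(c1, c2))
    brute = np.zeros((5, 5), dtype=int)
    for a, b in zip(c1, c2):
        tot = a + b
        if tot < 4 or (tot == 4 and (a, b) <= (4 - a, 4 - b)):
            brute[a, b] += 1
        else:
            brute[4 - a, 4 - b] += 1
    np.testing.assert_array_equal(sfs.counts, brute)


def test_folded_domain_validated():
    bad = np.zeros((5, 5), dtype=np.int64)
    bad[4, 4] = 3  # outside the folded domain
    with pytest.raises(ValueError, match="folded domain"):
        Folded2DSFS(counts=bad, monomorphic=0, n1=4, n2=4)


# ----------------------------------------------------------------------
# window resampling
# ----------------------------------------------------------------------


def test_dense_window_discarded():
    """SNPs at 100, 102, 103: mean gap 1.5 < 2 bp discards the window."""
    gt = np.array([[0, 1, 0, 1]] * 4, dtype=np.int8)
    t = make_table(gt, pos=[100, 102, 103, 60_000])
    data = resample_windows(t, t.samples[:2], t.samples[2:])
    assert data.n_sites == 1
    assert data.pos.tolist() == [60_000]
    assert len(data.selection["discarded_windows"]) == 1


def test_no_missing_data_is_identity():
    rng = np.random.default_rng(9)
    gt = rng.integers(0, 3, size=(50, 6)).astype(np.int8)
    t = make_table(gt, pos=np.arange(50) * 900 + 1)
    data = resample_windows(t, t.samples[:3], t.samples[3:])
    assert data.n1 == 6 and data.n2 == 6
    assert data.n_sites == 50
    np.testing.assert_array_equal(data.c1, gt[:, :3].sum(axis=1))
    np.testing.assert_array_equal(data.c2, gt[:, 3:].sum(axis=1))


def test_individual_selection_matches_brute_force():
    """Selected individuals are the argmin-missingness sets per window,
    ties broken by sample order."""
    rng = np.random.default_rng(10)
    n_sites, n_ind = 120, 8
    gt = rng.integers(0, 3, size=(n_sites, n_ind)).astype(np.int8)
    miss = rng.random((n_sites, n_ind)) < rng.uniform(0.05, 0.3, size=n_ind)
    gt[miss] = -1
    pos = np.sort(rng.choice(np.arange(1, 200_000), size=n_sites, replace=False))
    t = make_table(gt, pos=pos)
    pop1, pop2 = t.samples[:4], t.samples[4:]
    data = resample_windows(t, pop1, pop2)
    k1 = data.selection["k1"]
    for key, info in data.selection["windows"].items():
        w = int(key.rsplit(":", 1)[1])
        in_w = (pos - 1) // 50_000 == w
        m = (gt[in_w][:, :4] == -1).sum(axis=0)
        order = np.lexsort((np.arange(4), m))
        expect = sorted(pop1[i] for i in order[:k1])
        assert sorted(info["pop1"]) == expect


def test_target_k_floor_and_error():
    gt = np.array([[0, -1, -1, 0, 1, 1]] * 3, dtype=np.int8)
    t = make_table(gt)
    data = resample_windows(t, t.samples[:3], t.samples[3:])
    assert data.selection["k1"] == 2  # 3 - 2 missing, floored at 2
    with pytest.raises(ValueError, match=">= 2"):
        resample_windows(t, t.samples[:1], t.samples[3:])


def test_sites_missing_among_kept_are_dropped_and_counted():
    gt = np.array(
        [
            [0, 1, 0, 1],
            [-1, -1, 0, 1],  # pop1 keeps both individuals; site incomplete
            [0, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    t = make_table(gt)
    data = resample_windows(t, t.samples[:2], t.samples[2:])
    assert data.n_sites == 2
    assert data.selection["sites_dropped_missing"] == 1


# ----------------------------------------------------------------------
# monomorphic scaling
# ----------------------------------------------------------------------


def _sfs_with_total(total, n1=4, n2=4):
    counts = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    counts[1, 0] = total
    return Folded2DSFS(counts=counts, monomorphic=0, n1=n1, n2=n2)


def test_monomorphic_worked_example():
    """L = 10,000 with 50 of 100 SNPs kept: round(10000 * 0.5) - 50 = 4950."""
    sfs = attach_monomorphic(
        _sfs_with_total(50), n_snps_dataset=100,
        callable_counts={"a": 10_000, "b": 10_000},
    )
    assert sfs.monomorphic == 4950
    assert sfs.total_sites == 5000


def test_monomorphic_no_loss_limit():
    sfs = attach_monomorphic(
        _sfs_with_total(100), n_snps_dataset=100, callable_counts={"a": 10_000}
    )
    assert sfs.monomorphic == 10_000 - 100


def test_monomorphic_conservation_exact():
    rng = np.random.default_rng(12)
    for _ in range(10):
        s_kept = int(rng.integers(10, 400))
        s_data = s_kept + int(rng.integers(0, 200))
        L = int(rng.integers(10_000, 1_000_000))
        sfs = attach_monomorphic(
            _sfs_with_total(s_kept), n_snps_dataset=s_data,
            callable_counts={"x": L},
        )
        assert sfs.counts.sum() + sfs.monomorphic == round(L * s_kept / s_data)


def test_monomorphic_negative_is_error():
    with pytest.raises(ValueError, match="negative"):
        attach_monomorphic(
            _sfs_with_total(50), n_snps_dataset=100, callable_counts={"a": 60}
        )


# ----------------------------------------------------------------------
# .obs dialect
# ----------------------------------------------------------------------


def test_obs_round_trip(tmp_path):
    rng = np.random.default_rng(13)
    counts = fold_counts(rng.integers(0, 30, size=(5, 7)))
    sfs = Folded2DSFS(counts=counts, monomorphic=12_345, n1=4, n2=6)
    path = tmp_path / "joint.obs"
    write_obs(sfs, path)
    text = path.read_text().splitlines()
    assert text[0] == "1 observations"
    assert text[1].split()[0] == "d0_0"
    back = read_obs(path)
    assert back.n1 == 4 and back.n2 == 6
    assert back.monomorphic == 12_345 + counts[0, 0]
    expected = counts.copy()
    expected[0, 0] = 0
    np.testing.assert_array_equal(back.counts, expected)
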