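"""Heterozygosity, inbreeding and Weir-Cockerham differentiation statistics.

Per-locus observed heterozygosity is the fraction of heterozygous calls
among genotyped individuals; expected heterozygosity uses the unbiased
small-sample form ``2 p (1 - p) * n / (n - 1)`` with ``n`` the genotyped
haploid count.  The inbreeding coefficient is the ratio-of-means
estimator ``F_IS = 1 - mean(H_o) / mean(H_e)`` (stable at low-diversity
loci), with a percentile bootstrap over loci for its confidence
interval.  Pairwise F_ST is the Weir & Cockerham (1984) multi-locus
estimator from the among-population (a), among-individual (b) and
within-individual (c) variance components: ``sum(a) / sum(a + b + c)``.
Estimates may be negative and are not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable

__all__ = [
    "GroupStats",
    "heterozygosity",
    "inbreeding",
    "pairwise_fst",
    "fst_matrix",
    "wc_components",
]


@dataclass
class GroupStats:
    """Summary statistics for one group of individuals."""

    label: str
    mean_he: float
    mean_ho: float
    fis: float
    fis_ci: tuple
    n_loci: int
    n_boot: int
    ci_level: float


def _group_gt(table: VariantTable, group) -> np.ndarray:
    idx = table.sample_index(group)
    return table.gt[:, idx]


def heterozygosity(table: VariantTable, group):
    """Per-locus H_o and H_e for a group of sample names.

    Loci with fewer than 2 genotyped individuals in the group are
    skipped.  Returns ``(ho, he, used)`` arrays over the table's sites
    (``used`` marks counted loci) — means are unweighted over counted
    loci.
    """
    g = _group_gt(table, group)
    called = g != MISSING
    n_dip = called.sum(axis=1)
    used = n_dip >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ho = np.where(called, g == 1, False).sum(axis=1) / np.maximum(n_dip, 1)
        alt = np.where(called, g, 0).sum(axis=1)
        n_hap = 2 * n_dip
        p = alt / np.maximum(n_hap, 1)
        he = 2.0 * p * (1.0 - p) * n_hap / np.maximum(n_hap - 1, 1)
    ho = np.where(used, ho, np.nan)
    he = np.where(used, he, np.nan)
    return ho, he, used


def inbreeding(
    table: VariantTable,
    group,
    label: str = "",
    n_boot: int = 10_000,
    level: float = 0.95,
    rng_seed: int = 0,
) -> GroupStats:
    """F_IS with a percentile bootstrap-over-loci confidence interval."""
    ho, he, used = heterozygosity(table, group)
    ho, he = ho[used], he[used]
    n_loci = ho.size
    if n_loci < 2:
        raise ValueError("need at least 2 counted loci")
    mean_he = float(he.mean())
    mean_ho = float(ho.mean())
    if mean_he == 0:
        raise ValueError("mean expected heterozygosity is 0; F_IS undefined")
    fis = 1.0 - mean_ho / mean_he
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, n_loci, size=(n_boot, n_loci))
    bho = ho[idx].mean(axis=1)
    bhe = he[idx].mean(axis=1)
    ok = bhe > 0
    reps = 1.0 - bho[ok] / bhe[ok]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(reps, [100 * alpha, 100 * (1 - alpha)])
    return GroupStats(
        label=label,
        mean_he=mean_he,
        mean_ho=mean_ho,
        fis=fis,
        fis_ci=(float(lo), float(hi)),
        n_loci=n_loci,
        n_boot=n_boot,
        ci_level=level,
    )


def wc_components(p: np.ndarray, h: np.ndarray, n: np.ndarray):
    """Weir-Cockerham (1984) variance components per locus, 2+ populations.

    Parameters are per-locus arrays stacked population-wise:
    ``p[k, l]`` alternate-allele frequency, ``h[k, l]`` heterozygote
    frequency and ``n[k, l]`` diploid sample size for population ``k``
    at locus ``l``.  Returns ``(a, b, c)`` arrays over loci.
    """
    r = p.shape[0]
    nsum = n.sum(axis=0)
    nbar = nsum / r
    pbar = (n * p).sum(axis=0) / nsum
    hbar = (n * h).sum(axis=0) / nsum
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(table: VariantTable, group_a, group_b) -> float:
    """Multi-locus Weir-Cockerham F_ST between two groups.

    Loci with fewer than 2 genotyped individuals in either group are
    skipped.  The estimate is ``sum(a) / sum(a + b + c)`` over counted
    loci and may be slightly negative.
    """
    ga = _group_gt(table, group_a)
    gb = _group_gt(table, group_b)
    stats = []
    for g in (ga, gb):
        called = g != MISSING
        nd = called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        het = np.where(called, g == 1, False).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = alt / np.maximum(2 * nd, 1)
            h = het / np.maximum(nd, 1)
        stats.append((p, h, nd))
    (pa, ha, na), (pb, hb, nb) = stats
    used = (na >= 2) & (nb >= 2)
    if not used.any():
        raise ValueError("no loci with >= 2 genotyped individuals in both groups")
    p = np.stack([pa[used], pb[used]]).astype(np.float64)
    h = np.stack([ha[used], hb[used]]).astype(np.float64)
    n = np.stack([na[used], nb[used]]).astype(np.float64)
    a, b, c = wc_components(p, h, n)
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("all counted loci are monomorphic; F_ST undefined")
    return float(a.sum() / denom)


def fst_matrix(table: VariantTable, groups: dict) -> pd.DataFrame:
    """Symmetric pairwise multi-locus F_ST matrix over named groups."""
    labels = list(groups)
    out = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            v = pairwise_fst(table, groups[la], groups[lb])
            out.loc[la, lb] = v
            out.loc[lb, la] = v
    return out
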