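"""Folded joint 2D minor-allele frequency spectra with window resampling.

Demographic fitting needs a complete-data (no missing genotypes) joint
SFS.  Missing data are removed by *downsampling individuals in 50-kb
windows*: for each population a target individual count ``k_p`` is
fixed dataset-wide (population size minus the maximum per-site count of
missing genotypes in that population, floored at 2); in every
non-overlapping 50-kb window the ``k_p`` individuals with the least
missing data at that window's SNPs are kept; windows whose mean
inter-SNP distance is below 2 bp are discarded (dense clusters are
likely alignment artifacts); sites still missing a genotype among the
kept individuals are dropped and counted.

Folding uses the pooled (global) minor allele: per site the allele with
``c1 + c2 <= (n1 + n2) / 2`` total copies indexes entry ``(c1, c2)``;
exact ties are assigned to the lexicographically smaller member of the
mirror pair.  The monomorphic-site count is attached by scaling the
mean per-individual callable-site count by the fraction of SNPs that
survived resampling:

    monomorphic = round(L_callable * S_kept / S_dataset) - S_kept

which makes total spectrum mass equal the scaled sequence length by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import fold_joint
from .variants import MISSING, VariantTable

__all__ = [
    "Folded2DSFS",
    "ResampledData",
    "resample_windows",
    "build_folded_sfs",
    "fold_counts",
    "attach_monomorphic",
    "write_obs",
    "read_obs",
]


@dataclass
class Folded2DSFS:
    """Joint folded minor-allele-frequency counts for two populations.

    ``counts[i, j]``: SNPs whose pooled minor allele has ``i`` copies in
    population 1 and ``j`` in population 2 (haploid sizes ``n1``, ``n2``);
    entry (0, 0) holds sites monomorphic *within the downsampled
    individuals*.  The genome-wide monomorphic-site count is the separate
    ``monomorphic`` scalar.
    """

    counts: np.ndarray
    monomorphic: int
    n1: int
    n2: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError("counts shape does not match haploid sample sizes")
        if (self.counts < 0).any() or self.monomorphic < 0:
            raise ValueError("negative counts")
        folded = fold_counts(self.counts)
        if not np.array_equal(folded, self.counts):
            raise ValueError("counts contain entries outside the folded domain")

    @property
    def n_snps(self) -> int:
        """Polymorphic entries (excludes the in-sample-monomorphic cell)."""
        total = int(self.counts.sum()) - int(self.counts[0, 0])
        return total

    @property
    def total_sites(self) -> int:
        return int(self.counts.sum()) + int(self.monomorphic)

    def transposed(self) -> "Folded2DSFS":
        return Folded2DSFS(
            counts=fold_counts(self.counts.T.copy()),
            monomorphic=self.monomorphic,
            n1=self.n2,
            n2=self.n1,
            provenance=dict(self.provenance, transposed=True),
        )

    def signature(self) -> tuple:
        """Provenance key used to refuse cross-dataset model comparisons."""
        return (self.n1, self.n2, int(self.counts.sum()), int(self.monomorphic))

    # -- I/O ------------------------------------------------------------

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.counts,
            index=[f"p1_{i}" for i in range(self.n1 + 1)],
            columns=[f"p2_{j}" for j in range(self.n2 + 1)],
        )
        with open(path, "w") as fh:
            fh.write(f"# monomorphic\t{self.monomorphic}\n")
            df.to_csv(fh, sep="\t")
        side = str(path) + ".provenance.json"
        with open(side, "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


def fold_counts(counts: np.ndarray) -> np.ndarray:
    """Integer folding of a joint count matrix (idempotent)."""
    return np.rint(fold_joint(counts.astype(np.float64))).astype(np.int64)


# ----------------------------------------------------------------------
# window resampling
# ----------------------------------------------------------------------


@dataclass
class ResampledData:
    """Complete-data per-site allele counts after window downsampling.

    Individual identity varies across windows, so the object stores per
    site the alternate-allele copy count among the kept individuals of
    each population, plus the fixed haploid sizes.
    """

    chrom: np.ndarray
    pos: np.ndarray
    window: np.ndarray  # integer id, dense over used windows
    c1: np.ndarray
    c2: np.ndarray
    n1: int
    n2: int
    pop1: str
    pop2: str
    n_snps_input: int
    selection: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.pos.shape[0]

    @property
    def n_windows(self) -> int:
        return len(np.unique(self.window))


def _target_k(gt_pop: np.ndarray, label: str) -> int:
    n_ind = gt_pop.shape[1]
    if n_ind < 2:
        raise ValueError(
            f"population {label!r} has {n_ind} individuals; need >= 2 "
            "(apply stricter upstream filtering or add samples)"
        )
    max_miss = int((gt_pop == MISSING).sum(axis=1).max(initial=0))
    return max(2, n_ind - max_miss)


def _resample_complete(table, g1, g2, pop1, pop2, window_bp, min_gap_bp):
    """Vectorised fast path when the table has no missing genotypes:
    every individual is kept and only the dense-window discard applies."""
    order = np.lexsort((table.pos, table.chrom.astype(str)))
    chrom = table.chrom[order]
    pos = table.pos[order]
    codes, _ = pd.factorize(chrom)
    wkey = codes.astype(np.int64) * (2**40) + (pos - 1) // window_bp
    uniq, win_idx, counts = np.unique(wkey, return_inverse=True, return_counts=True)
    # mean inter-SNP gap per window (windows with < 2 SNPs are kept)
    boundaries = np.searchsorted(np.sort(wkey), uniq)
    sort_by_win = np.argsort(wkey, kind="stable")
    pos_sorted = pos[sort_by_win]
    gaps = np.diff(pos_sorted).astype(float)
    keep_win = np.ones(uniq.size, dtype=bool)
    for w in np.flatnonzero(counts >= 2):
        s = boundaries[w]
        g = gaps[s : s + counts[w] - 1]
        if g.mean() < min_gap_bp:
            keep_win[w] = False
    site_keep = keep_win[win_idx]
    sel = order[site_keep]
    dense_win = np.cumsum(keep_win) - 1
    discarded = [("window", int(u)) for u in uniq[~keep_win]]
    return ResampledData(
        chrom=table.chrom[sel],
        pos=table.pos[sel],
        window=dense_win[win_idx[site_keep]],
        c1=g1[order][site_keep].sum(axis=1).astype(np.int64),
        c2=g2[order][site_keep].sum(axis=1).astype(np.int64),
        n1=g1.shape[1] * 2,
        n2=g2.shape[1] * 2,
        pop1=pop1,
        pop2=pop2,
        n_snps_input=table.n_sites,
        selection={
            "k1": g1.shape[1],
            "k2": g2.shape[1],
            "windows": {},
            "complete_data_fast_path": True,
            "discarded_windows": discarded,
            "sites_dropped_missing": 0,
            "window_bp": window_bp,
            "min_gap_bp": min_gap_bp,
        },
    )


def resample_windows(
    table: VariantTable,
    pop1_samples,
    pop2_samples,
    pop1: str = "pop1",
    pop2: str = "pop2",
    window_bp: int = 50_000,
    min_gap_bp: float = 2.0,
) -> ResampledData:
    """Downsample individuals per 50-kb window to obtain complete data.

    Windows are non-overlapping, anchored at position 1 of each
    chromosome, half-open ``[start, start + window_bp)``.  Ties in the
    per-window missingness ranking are broken by sample order within the
    population.
    """
    idx1 = table.sample_index(pop1_samples)
    idx2 = table.sample_index(pop2_samples)
    g1 = table.gt[:, idx1]
    g2 = table.gt[:, idx2]
    k1 = _target_k(g1, pop1)
    k2 = _target_k(g2, pop2)

    if not ((g1 == MISSING).any() or (g2 == MISSING).any()):
        return _resample_complete(
            table, g1, g2, pop1, pop2, window_bp, min_gap_bp
        )

    chroms, poss, wins, c1s, c2s = [], [], [], [], []
    sel_log = {}
    discarded = []
    dropped_sites = 0
    wid = 0
    order = np.lexsort((table.pos, table.chrom.astype(str)))
    chrom_sorted = table.chrom[order]
    for chrom in pd.unique(chrom_sorted):
        sub = order[chrom_sorted == chrom]
        pos = table.pos[sub]
        wstart = (pos - 1) // window_bp
        for w in np.unique(wstart):
            in_w = sub[wstart == w]
            wpos = table.pos[in_w]
            if wpos.size >= 2 and float(np.diff(wpos).mean()) < min_gap_bp:
                discarded.append((str(chrom), int(w)))
                continue
            kept_cols = []
            counts = []
            ok = np.ones(wpos.size, dtype=bool)
            for g, k, samp_idx in ((g1, k1, idx1), (g2, k2, idx2)):
                miss = (g[in_w] == MISSING).sum(axis=0)
                sel = np.argsort(miss, kind="stable")[:k]
                sel.sort()
                kept_cols.append(sel)
                sub_g = g[in_w][:, sel]
                ok &= ~(sub_g == MISSING).any(axis=1)
                counts.append(sub_g)
            dropped_sites += int((~ok).sum())
            if not ok.any():
                sel1, sel2 = kept_cols
                sel_log[f"{chrom}:{int(w)}"] = {
                    "pop1": [table.samples[idx1[i]] for i in sel1],
                    "pop2": [table.samples[idx2[i]] for i in sel2],
                    "n_sites": 0,
                }
                wid += 1
                continue
            c1 = np.where(counts[0][ok] != MISSING, counts[0][ok], 0).sum(axis=1)
            c2 = np.where(counts[1][ok] != MISSING, counts[1][ok], 0).sum(axis=1)
            chroms.append(np.repeat(chrom, int(ok.sum())))
            poss.append(wpos[ok])
            wins.append(np.full(int(ok.sum()), wid, dtype=np.int64))
            c1s.append(c1)
            c2s.append(c2)
            sel1, sel2 = kept_cols
            sel_log[f"{chrom}:{int(w)}"] = {
                "pop1": [table.samples[idx1[i]] for i in sel1],
                "pop2": [table.samples[idx2[i]] for i in sel2],
                "n_sites": int(ok.sum()),
            }
            wid += 1

    if chroms:
        chrom_arr = np.concatenate(chroms)
        pos_arr = np.concatenate(poss)
        win_arr = np.concatenate(wins)
        c1_arr = np.concatenate(c1s).astype(np.int64)
        c2_arr = np.concatenate(c2s).astype(np.int64)
    else:
        chrom_arr = np.array([], dtype=object)
        pos_arr = np.array([], dtype=np.int64)
        win_arr = np.array([], dtype=np.int64)
        c1_arr = np.array([], dtype=np.int64)
        c2_arr = np.array([], dtype=np.int64)
    return ResampledData(
        chrom=chrom_arr,
        pos=pos_arr,
        window=win_arr,
        c1=c1_arr,
        c2=c2_arr,
        n1=2 * k1,
        n2=2 * k2,
        pop1=pop1,
        pop2=pop2,
        n_snps_input=table.n_sites,
        selection={
            "k1": k1,
            "k2": k2,
            "windows": sel_log,
            "discarded_windows": discarded,
            "sites_dropped_missing": dropped_sites,
            "window_bp": window_bp,
            "min_gap_bp": min_gap_bp,
        },
    )


# ----------------------------------------------------------------------
# spectrum construction
# ----------------------------------------------------------------------


def build_folded_sfs(data: ResampledData, swap: bool = False) -> Folded2DSFS:
    """Fold per-site allele counts into the joint MAF spectrum.

    ``swap=True`` builds the (pop2, pop1) spectrum, which equals the
    transpose of the unswapped one.
    """
    if swap:
        c1, c2, n1, n2 = data.c2, data.c1, data.n2, data.n1
    else:
        c1, c2, n1, n2 = data.c1, data.c2, data.n1, data.n2
    unfolded = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    np.add.at(unfolded, (c1, c2), 1)
    counts = fold_counts(unfolded)
    return Folded2DSFS(
        counts=counts,
        monomorphic=0,
        n1=n1,
        n2=n2,
        provenance={
            "pop1": data.pop2 if swap else data.pop1,
            "pop2": data.pop1 if swap else data.pop2,
            "n_snps_input": data.n_snps_input,
            "n_snps_kept": data.n_sites,
            "n_windows": data.n_windows,
            "selection": data.selection,
            "fold": "pooled minor allele; ties to lexicographically smaller pair",
        },
    )


def attach_monomorphic(
    sfs: Folded2DSFS,
    n_snps_dataset: int,
    callable_counts,
    retained_individuals=None,
) -> Folded2DSFS:
    """Scale callable-site counts into a monomorphic count for the SFS.

    ``callable_counts`` maps individual id -> callable sites (mosdepth
    style); the mean over ``retained_individuals`` (default: all ids in
    the mapping) is scaled by the fraction of dataset SNPs surviving
    resampling, and the surviving SNPs are subtracted.
    """
    if retained_individuals is None:
        retained_individuals = list(callable_counts)
    vals = np.array([callable_counts[i] for i in retained_individuals], dtype=float)
    l_callable = float(vals.mean())
    s_kept = int(sfs.counts.sum())
    mono = int(round(l_callable * s_kept / n_snps_dataset)) - s_kept
    if mono < 0:
        raise ValueError(
            "negative monomorphic count: callable length inconsistent with "
            "SNP totals"
        )
    return Folded2DSFS(
        counts=sfs.counts.copy(),
        monomorphic=mono,
        n1=sfs.n1,
        n2=sfs.n2,
        provenance=dict(
            sfs.provenance,
            L_callable=l_callable,
            S_dataset=int(n_snps_dataset),
            S_kept=s_kept,
            monomorphic_formula="round(L * S_kept / S_dataset) - S_kept",
        ),
    )


# ----------------------------------------------------------------------
# fastsimcoal2-style .obs dialect
# ----------------------------------------------------------------------


def write_obs(sfs: Folded2DSFS, path) -> None:
    """Write the joint MAF spectrum in the 2D ``.obs`` text dialect.

    Rows are labelled ``d1_j`` (population 2), columns ``d0_i``
    (population 1); the [0, 0] cell carries the monomorphic count on
    top of the in-sample-monomorphic entry.
    """
    mat = sfs.counts.T.astype(np.int64).copy()
    mat[0, 0] += sfs.monomorphic
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        fh.write("\t" + "\t".join(f"d0_{i}" for i in range(sfs.n1 + 1)) + "\n")
        for j in range(sfs.n2 + 1):
            fh.write(f"d1_{j}\t" + "\t".join(str(int(x)) for x in mat[j]) + "\n")


def read_obs(path) -> Folded2DSFS:
    """Read the dialect written by :func:`write_obs`.

    The [0, 0] cell is interpreted as the monomorphic count (the
    in-sample-monomorphic split is not recoverable from the file).
    """
    with open(path) as fh:
        header = fh.readline()
        if "observations" not in header:
            raise ValueError("not an .obs file")
        cols = fh.readline().split()
        n1 = len(cols) - 1
        rows = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            rows.append([int(x) for x in parts[1:]])
    mat = np.array(rows, dtype=np.int64).T
    mono = int(mat[0, 0])
    mat[0, 0] = 0
    return Folded2DSFS(
        counts=mat,
        monomorphic=mono,
        n1=n1,
        n2=mat.shape[1] - 1,
        provenance={"source": str(path)},
    )
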