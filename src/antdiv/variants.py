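"""Post-calling SNP filter cascade on a sites-by-individuals genotype table.

The cascade mirrors the filtering applied to the wood-ant resequencing
call set: keep biallelic SNPs with site quality >= 30, mask individual
genotypes with genotype quality < 30 or depth < 8, drop sites missing in
more than half of the samples, drop sites with a pooled-sample
heterozygote excess (one-sided exact Hardy-Weinberg test, p < 0.01,
deliberately pooling across groups to create a Wahlund effect so that
paralog-collapse artifacts stand out), mask genotypes outside the
per-individual depth envelope [mean/2, 2*mean], and exclude whole
chromosomes (the supergene-carrying "chromosome 3") and gene-proximal
regions (gene features +/- 10 kb) when an annotation is supplied.

Stage order is fixed: biallelic+QUAL -> GQ/DP masking -> missingness ->
heterozygote excess -> depth envelope (missingness re-applied) -> region
exclusion.  Every stage only removes sites or masks genotypes; allele
coding is never altered.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantTable",
    "FilterReport",
    "mask_genotypes",
    "filter_sites",
    "depth_envelope_filter",
    "exclude_regions",
    "thin",
    "filter_cascade",
    "hwe_het_excess_pvalue",
    "read_gff_genes",
]

MISSING = -1


@dataclass
class VariantTable:
    """Biallelic-SNP genotype matrix with per-genotype depth and quality.

    ``gt`` holds alternate-allele dosages (0, 1, 2) with -1 for missing;
    one row per site, one column per individual.  Positions are 1-based
    and strictly increasing within a chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    gt: np.ndarray
    samples: list
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None
    n_alt_alleles: np.ndarray | None = None  # >1 marks non-biallelic records

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.qual = np.asarray(self.qual, dtype=np.float64)
        if self.n_alt_alleles is None:
            self.n_alt_alleles = np.ones(self.n_sites, dtype=np.int64)
        for chrom in pd.unique(self.chrom):
            p = self.pos[self.chrom == chrom]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on {chrom}"
                )

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def sample_index(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[n] for n in names], dtype=np.int64)

    def take_sites(self, mask_or_index) -> "VariantTable":
        idx = np.asarray(mask_or_index)
        return VariantTable(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            qual=self.qual[idx],
            gt=self.gt[idx],
            samples=list(self.samples),
            dp=None if self.dp is None else self.dp[idx],
            gq=None if self.gq is None else self.gq[idx],
            n_alt_alleles=self.n_alt_alleles[idx],
        )

    def copy(self) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            qual=self.qual.copy(),
            gt=self.gt.copy(),
            samples=list(self.samples),
            dp=None if self.dp is None else self.dp.copy(),
            gq=None if self.gq is None else self.gq.copy(),
            n_alt_alleles=self.n_alt_alleles.copy(),
        )

    def missing_counts(self) -> np.ndarray:
        """Number of missing genotypes per site."""
        return (self.gt == MISSING).sum(axis=1)

    # -- VCF I/O --------------------------------------------------------

    @classmethod
    def from_vcf(cls, path) -> "VariantTable":
        """Read a VCFv4.x file (uncompressed or bgzipped) via cyvcf2."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        chroms, poss, refs, alts, quals, gts, dps, gqs, nalts = (
            [], [], [], [], [], [], [], [], [],
        )
        has_dp = has_gq = True
        for v in vcf:
            chroms.append(v.CHROM)
            poss.append(v.POS)
            refs.append(v.REF)
            alts.append(v.ALT[0] if v.ALT else ".")
            quals.append(np.nan if v.QUAL is None else v.QUAL)
            nalts.append(len(v.ALT))
            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
            g = v.gt_types.astype(np.int8)
            g[g == 3] = MISSING
            gts.append(g)
            try:
                dp = v.format("DP")
            except KeyError:
                dp = None
            if dp is None:
                has_dp = False
            else:
                dps.append(dp[:, 0])
            try:
                gq = v.format("GQ")
            except KeyError:
                gq = None
            if gq is None:
                has_gq = False
            else:
                gqs.append(gq[:, 0])
        vcf.close()
        return cls(
            chrom=np.array(chroms, dtype=object),
            pos=np.array(poss, dtype=np.int64),
            ref=np.array(refs, dtype=object),
            alt=np.array(alts, dtype=object),
            qual=np.array(quals, dtype=np.float64),
            gt=np.array(gts, dtype=np.int8) if gts else np.zeros((0, len(samples)), np.int8),
            samples=samples,
            dp=np.array(dps, dtype=np.int32) if has_dp and dps else None,
            gq=np.array(gqs, dtype=np.int32) if has_gq and gqs else None,
            n_alt_alleles=np.array(nalts, dtype=np.int64),
        )

    def to_vcf(self, path) -> None:
        """Write as plain-text VCFv4.2 with FORMAT GT:DP:GQ."""
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=antdiv\n")
            for chrom in pd.unique(self.chrom):
                maxpos = int(self.pos[self.chrom == chrom].max()) if self.n_sites else 0
                fh.write(f"##contig=<ID={chrom},length={maxpos + 1}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for i in range(self.n_sites):
                cells = []
                for s in range(self.n_samples):
                    g = gt_str[int(self.gt[i, s])]
                    dp = int(self.dp[i, s]) if self.dp is not None else "."
                    gq = int(self.gq[i, s]) if self.gq is not None else "."
                    cells.append(f"{g}:{dp}:{gq}")
                q = self.qual[i]
                fh.write(
                    f"{self.chrom[i]}\t{self.pos[i]}\t.\t{self.ref[i]}\t"
                    f"{self.alt[i]}\t{'.' if np.isnan(q) else f'{q:g}'}\t.\t.\t"
                    "GT:DP:GQ\t" + "\t".join(cells) + "\n"
                )


@dataclass
class FilterReport:
    """Per-stage accounting of sites removed and genotypes masked."""

    stages: list = field(default_factory=list)

    def add(self, stage: str, sites_in: int, sites_removed: int,
            genotypes_masked: int = 0) -> None:
        if sites_removed < 0 or genotypes_masked < 0:
            raise ValueError("negative filter counts")
        self.stages.append(
            {
                "stage": stage,
                "sites_in": int(sites_in),
                "sites_removed": int(sites_removed),
                "sites_out": int(sites_in - sites_removed),
                "genotypes_masked": int(genotypes_masked),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:
        lines = ["stage\tsites_in\tremoved\tsites_out\tgenotypes_masked"]
        for s in self.stages:
            lines.append(
                f"{s['stage']}\t{s['sites_in']}\t{s['sites_removed']}\t"
                f"{s['sites_out']}\t{s['genotypes_masked']}"
            )
        return "\n".join(lines)


# ----------------------------------------------------------------------
# Hardy-Weinberg heterozygote-excess exact test
# ----------------------------------------------------------------------


@functools.lru_cache(maxsize=100_000)
def _het_excess_tail(n: int, m: int, h_obs: int) -> float:
    """P(N_het >= h_obs | n diploids, m alt copies) under random pairing.

    All ``C(2n, m)`` placements of the ``m`` alternate copies into the
    ``2n`` gene-copy slots are equally likely; the number of placements
    producing exactly ``h`` heterozygotes is ``n! / (nAA! h! naa!) * 2^h``
    with ``naa = (m - h) / 2``.  Exact integer arithmetic throughout.
    """
    total = math.comb(2 * n, m)
    acc = 0
    # valid h range: same parity as m, h <= min(m, 2n - m)
    hmax = min(m, 2 * n - m)
    h0 = max(h_obs, 0)
    if (h0 % 2) != (m % 2):
        h0 += 1
    for h in range(h0, hmax + 1, 2):
        naa = (m - h) // 2
        nAA = n - h - naa
        if nAA < 0:
            continue
        acc += math.factorial(n) // (
            math.factorial(nAA) * math.factorial(h) * math.factorial(naa)
        ) * (1 << h)
    return acc / total


def hwe_het_excess_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-sided exact heterozygote-excess p-value at a biallelic site.

    Conditions on the observed allele counts; returns
    ``P(N_het >= observed)`` under Hardy-Weinberg proportions.
    A monomorphic site has p = 1.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped individuals")
    m = n_het + 2 * n_hom_alt
    return _het_excess_tail(n, m, n_het)


# ----------------------------------------------------------------------
# filter stages
# ----------------------------------------------------------------------


def mask_genotypes(
    table: VariantTable, gq_min: int = 30, dp_min: int = 8
) -> tuple[VariantTable, int]:
    """Mask genotypes with GQ < ``gq_min`` or DP < ``dp_min`` to missing.

    Site-level data are untouched.  Returns the new table and the number
    of genotypes newly masked.
    """
    if table.gq is None:
        raise ValueError("genotype-quality (GQ) field absent from table")
    if table.dp is None:
        raise ValueError("depth (DP) field absent from table")
    out = table.copy()
    bad = (out.gq < gq_min) | (out.dp < dp_min)
    newly = int((bad & (out.gt != MISSING)).sum())
    out.gt[bad] = MISSING
    return out, newly


def filter_sites(
    table: VariantTable,
    qual_min: float = 30.0,
    max_missing_fraction: float = 0.5,
    alpha_hwe: float = 0.01,
    report: FilterReport | None = None,
) -> tuple[VariantTable, FilterReport]:
    """Site-level filters: biallelic + QUAL, missingness, heterozygote excess.

    Missingness is strict: a site is removed when missing genotypes occur
    in *strictly more* than ``max_missing_fraction`` of the samples
    (10/20 missing is retained).  The heterozygote-excess test pools all
    genotyped individuals at the site.
    """
    report = report or FilterReport()
    n_ind = table.n_samples

    keep = (table.n_alt_alleles == 1) & (table.qual >= qual_min)
    report.add("biallelic_qual", table.n_sites, int((~keep).sum()))
    table = table.take_sites(keep)

    miss = table.missing_counts()
    empty = miss == n_ind
    report.add("zero_genotyped", table.n_sites, int(empty.sum()))
    table = table.take_sites(~empty)

    miss = table.missing_counts()
    keep = miss <= max_missing_fraction * n_ind
    report.add("missingness", table.n_sites, int((~keep).sum()))
    table = table.take_sites(keep)

    hom_ref = (table.gt == 0).sum(axis=1)
    het = (table.gt == 1).sum(axis=1)
    hom_alt = (table.gt == 2).sum(axis=1)
    pvals = np.array(
        [
            hwe_het_excess_pvalue(int(a), int(h), int(b))
            for a, h, b in zip(hom_ref, het, hom_alt)
        ]
    )
    keep = pvals >= alpha_hwe
    report.add("het_excess", table.n_sites, int((~keep).sum()))
    table = table.take_sites(keep)
    return table, report


def depth_envelope_filter(
    table: VariantTable,
    mean_depths: np.ndarray | None = None,
    max_missing_fraction: float = 0.5,
    report: FilterReport | None = None,
) -> tuple[VariantTable, FilterReport]:
    """Mask genotypes outside the individual depth envelope [mean/2, 2*mean].

    ``mean_depths`` may be supplied per individual; otherwise each
    individual's mean depth is computed over genotyped calls in the
    table.  The missingness rule is then re-applied to the masked table.
    """
    if table.dp is None:
        raise ValueError("depth (DP) field absent from table")
    report = report or FilterReport()
    if mean_depths is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_depths = np.nanmean(
                np.where(table.gt != MISSING, table.dp, np.nan), axis=0
            )
    mean_depths = np.asarray(mean_depths, dtype=np.float64)
    if (mean_depths <= 0).any():
        raise ValueError("non-positive mean depth")
    out = table.copy()
    lo = 0.5 * mean_depths
    hi = 2.0 * mean_depths
    bad = (out.dp < lo[None, :]) | (out.dp > hi[None, :])
    newly = int((bad & (out.gt != MISSING)).sum())
    out.gt[bad] = MISSING
    miss = out.missing_counts()
    keep = miss <= max_missing_fraction * out.n_samples
    report.add("depth_envelope", out.n_sites, int((~keep).sum()), newly)
    return out.take_sites(keep), report


def read_gff_genes(path) -> pd.DataFrame:
    """Parse gene features from a GFF3 file into (chrom, start, end)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            if parts[2] == "gene":
                rows.append((parts[0], int(parts[3]), int(parts[4])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    ms, me = [], []
    for s, e in zip(starts, ends):
        if ms and s <= me[-1] + 1:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.array(ms), np.array(me)


def exclude_regions(
    table: VariantTable,
    exclude_chroms=(),
    gff: pd.DataFrame | str | None = None,
    flank_bp: int = 10_000,
    report: FilterReport | None = None,
) -> tuple[VariantTable, FilterReport]:
    """Drop sites on excluded chromosomes and near annotated genes.

    When a gene annotation is given, a site is removed if it lies inside
    any gene feature extended by ``flank_bp`` on both sides (closed
    interval, ends included).
    """
    report = report or FilterReport()
    present = set(pd.unique(table.chrom))
    for c in exclude_chroms:
        if c not in present:
            warnings.warn(f"chromosome {c!r} in exclusion list not found in table")
    keep = ~np.isin(table.chrom, list(exclude_chroms))
    report.add("exclude_chromosomes", table.n_sites, int((~keep).sum()))
    table = table.take_sites(keep)

    if gff is not None:
        genes = read_gff_genes(gff) if not isinstance(gff, pd.DataFrame) else gff
        drop = np.zeros(table.n_sites, dtype=bool)
        for chrom, grp in genes.groupby("chrom"):
            on = table.chrom == chrom
            if not on.any():
                continue
            starts = np.maximum(grp["start"].to_numpy() - flank_bp, 1)
            ends = grp["end"].to_numpy() + flank_bp
            ms, me = _merge_intervals(starts, ends)
            pos = table.pos[on]
            j = np.searchsorted(ms, pos, side="right") - 1
            inside = (j >= 0) & (pos <= me[np.clip(j, 0, len(me) - 1)])
            drop[np.flatnonzero(on)[inside]] = True
        report.add("gene_proximity", table.n_sites, int(drop.sum()))
        table = table.take_sites(~drop)
    return table, report


def thin(table: VariantTable, step: int = 200) -> VariantTable:
    """Keep SNPs at 1-based ordinal positions 1, 1+step, 1+2*step, ...

    Ordinals run in genome order (table order: chromosome blocks,
    positions increasing within each).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    return table.take_sites(np.arange(0, table.n_sites, step))


def filter_cascade(
    table: VariantTable,
    qual_min: float = 30.0,
    gq_min: int = 30,
    dp_min: int = 8,
    max_missing_fraction: float = 0.5,
    alpha_hwe: float = 0.01,
    mean_depths: np.ndarray | None = None,
    exclude_chroms=(),
    gff=None,
    flank_bp: int = 10_000,
    thin_step: int | None = None,
) -> tuple[VariantTable, FilterReport]:
    """Run the full fixed-order filter cascade and return table + report."""
    report = FilterReport()
    keep = (table.n_alt_alleles == 1) & (table.qual >= qual_min)
    report.add("biallelic_qual", table.n_sites, int((~keep).sum()))
    table = table.take_sites(keep)

    table, masked = mask_genotypes(table, gq_min=gq_min, dp_min=dp_min)
    report.add("gq_dp_mask", table.n_sites, 0, masked)

    miss = table.missing_counts()
    empty = miss == table.n_samples
    report.add("zero_genotyped", table.n_sites, int(empty.sum()))
    table = table.take_sites(~empty)

    miss = table.missing_counts()
    keep = miss <= max_missing_fraction * table.n_samples
    report.add("missingness", table.n_sites, int((~keep).sum()))
    table = table.take_sites(keep)

    hom_ref = (table.gt == 0).sum(axis=1)
    het = (table.gt == 1).sum(axis=1)
    hom_alt = (table.gt == 2).sum(axis=1)
    pvals = np.array(
        [
            hwe_het_excess_pvalue(int(a), int(h), int(b))
            for a, h, b in zip(hom_ref, het, hom_alt)
        ]
    )
    keep = pvals >= alpha_hwe
    report.add("het_excess", table.n_sites, int((~keep).sum()))
    table = table.take_sites(keep)

    table, report = depth_envelope_filter(
        table, mean_depths=mean_depths,
        max_missing_fraction=max_missing_fraction, report=report,
    )
    table, report = exclude_regions(
        table, exclude_chroms=exclude_chroms, gff=gff, flank_bp=flank_bp,
        report=report,
    )
    if thin_step is not None and thin_step > 1:
        n_in = table.n_sites
        table = thin(table, thin_step)
        report.add("thin", n_in, n_in - table.n_sites)
    return table, report
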