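"""Study-shaped synthetic data: VCF + metadata + callable-site counts.

The generator emulates the shape of the wood-ant resequencing call set
so that every downstream stage (filtering, summary statistics, SFS
construction, inference, bootstrap) is testable without any download:
20 diploid workers (10 per species spread over 6 sampling locations),
genome-wide biallelic SNPs at ~15.6x mean depth with ~15.5% missing
genotypes per site, plus a configurable fraction of all-heterozygote
artifact sites mimicking collapsed paralogs.

Local linkage is modelled at the resolution the analysis actually uses:
one coalescent genealogy per 50-kb window, shared by all SNPs in the
window.  Diploid genotypes pair consecutive haploid lineages within an
individual; per-genotype depth is Poisson around a lognormal-dispersed
individual mean, genotype quality is a depth-correlated integer score,
and missingness is imposed genotype-wise with per-individual rates
jittered around the target (so "individuals with less missing data" is
a meaningful ordering for the window-resampling stage).

Callable-site counts are derived from the simulated tree lengths:
``C = round(S / (mu * mean tree length))`` is the implied number of
callable sites carrying ``S`` SNPs at mutation rate ``mu``, jittered
per individual; this keeps the SNP-to-callable ratio consistent with
the mutation rate used by the inference stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import MU
from .demography import DemographicModel
from .variants import MISSING, VariantTable

__all__ = ["StudyDesign", "SyntheticDataset", "generate_dataset", "generate_gff"]

#: Sampling layout mirroring the study: (location, species, n individuals).
DEFAULT_LOCATIONS = [
    ("EastSwitzerland", "polyctena", 3),
    ("WestSwitzerland", "polyctena", 3),
    ("Finland", "polyctena", 4),
    ("EastSwitzerland", "aquilonia", 3),
    ("Scotland", "aquilonia", 3),
    ("Finland", "aquilonia", 4),
]

DEFAULT_CHROMOSOMES = [("chr1", 15_000_000), ("chr2", 15_000_000), ("chr3", 15_000_000)]


@dataclass
class StudyDesign:
    """Shape of the emulated data set.

    Defaults reproduce the study conditions: 10 + 10 individuals over 6
    locations, mean individual depth 15.6x, 15.49% missing genotypes
    per site, 50-kb linkage windows, and a three-chromosome layout so
    the chromosome-exclusion filter is exercisable.
    """

    locations: list = field(default_factory=lambda: list(DEFAULT_LOCATIONS))
    chromosomes: list = field(default_factory=lambda: list(DEFAULT_CHROMOSOMES))
    excluded_chromosome: str = "chr3"
    missing_fraction: float = 0.1549
    depth_mean: float = 15.6
    depth_log_sd: float = 0.10  # lognormal dispersion of individual means
    gq_mean: float = 60.0
    gq_sd: float = 18.0
    qual_low_fraction: float = 0.01  # sites emitted with QUAL < 30
    artifact_fraction: float = 0.005  # all-heterozygote paralog-like sites
    window_bp: int = 50_000

    def __post_init__(self):
        for _, _, n in self.locations:
            if n < 1:
                raise ValueError("each location needs >= 1 individual")
        for frac in (self.missing_fraction, self.artifact_fraction,
                     self.qual_low_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if len(self.chromosomes) < 2:
            raise ValueError(
                "need >= 2 chromosomes so the exclusion filter is exercisable"
            )

    @property
    def species(self) -> list:
        seen = []
        for _, sp, _ in self.locations:
            if sp not in seen:
                seen.append(sp)
        return seen

    def individuals(self) -> pd.DataFrame:
        """Sample metadata: id, species, location, population, nest."""
        rows = []
        for loc, sp, n in self.locations:
            for i in range(n):
                rows.append(
                    {
                        "id": f"{sp[:3]}_{loc}_{i + 1}",
                        "species": sp,
                        "location": loc,
                        "population": f"{loc}_pop",
                        "nest": f"{loc}_nest{i + 1}",
                    }
                )
        return pd.DataFrame(rows)

    def counts_per_species(self) -> dict:
        out: dict = {}
        for _, sp, n in self.locations:
            out[sp] = out.get(sp, 0) + n
        return out


@dataclass
class SyntheticDataset:
    """Generator output: genotype table, metadata, callable counts, truth."""

    table: VariantTable
    metadata: pd.DataFrame
    callable_counts: dict
    truth: dict

    def write(self, prefix) -> dict:
        """Write VCF, metadata TSV and callable-counts TSV; returns paths."""
        paths = {
            "vcf": f"{prefix}.vcf",
            "metadata": f"{prefix}.samples.tsv",
            "callable": f"{prefix}.callable.tsv",
        }
        self.table.to_vcf(paths["vcf"])
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        pd.Series(self.callable_counts, name="callable_sites").rename_axis(
            "id"
        ).to_csv(paths["callable"], sep="\t")
        return paths


def _window_layout(design: StudyDesign):
    wins = []
    for chrom, length in design.chromosomes:
        n_w = max(1, length // design.window_bp)
        for w in range(int(n_w)):
            start = w * design.window_bp + 1
            end = min(start + design.window_bp - 1, length)
            wins.append((chrom, start, end))
    return wins


def generate_dataset(
    design: StudyDesign,
    model: DemographicModel,
    n_sites: int,
    rng_seed: int,
    mu: float = MU,
) -> SyntheticDataset:
    """Simulate a study-shaped biallelic-SNP dataset under ``model``.

    The model's sampled demes are matched, in order, to the species of
    ``design``; each species' haploid sample size must equal twice its
    individual count.  Deterministic given ``rng_seed``.
    """
    meta = design.individuals()
    species = design.species
    counts = design.counts_per_species()
    sampled = [d for d, n in zip(model.deme_ids, model.sample_sizes()) if n > 0]
    sizes = [n for n in model.sample_sizes() if n > 0]
    if len(sampled) != len(species) or any(
        sizes[i] != 2 * counts[sp] for i, sp in enumerate(species)
    ):
        raise ValueError(
            f"model haploid sample sizes {sizes} do not match twice the design "
            f"individual counts {[counts[s] for s in species]}"
        )
    windows = _window_layout(design)
    n_windows = len(windows)
    if n_sites < n_windows:
        raise ValueError(
            f"n_sites = {n_sites} is less than the number of windows "
            f"({n_windows}); increase n_sites or shrink the chromosome layout"
        )
    rng = np.random.default_rng(rng_seed)
    n_ind = len(meta)
    n_hap = 2 * n_ind

    # leaf -> individual map: consecutive haploid pairs within a species
    ind_order = []
    for sp in species:
        ind_order.extend(meta.index[meta["species"] == sp].tolist())
    leaf_ind = np.repeat(np.array(ind_order), 2)

    gseed = np.random.SeedSequence(rng.integers(0, 2**31)).generate_state(n_windows)
    from .coalescent import Genealogy, NonCoalescingError, _genealogy_kernel

    enc = model.encode()

    # one genealogy per window; a window's chance of carrying a SNP is
    # proportional to physical length x total tree length (length-biased,
    # matching the infinite-sites expectation E[A_e] / E[L])
    tree_lengths = np.empty(n_windows)
    for w in range(n_windows):
        parent, node_time, leaf_deme, err = _genealogy_kernel(
            *enc, int(gseed[w] % (2**31))
        )
        if err:
            raise NonCoalescingError(
                "model cannot coalesce the sample; check joins/migration"
            )
        tree_lengths[w] = (
            node_time[parent[parent >= 0]] - node_time[parent >= 0]
        ).sum()
    lengths = np.array([e - s + 1 for _, s, e in windows], dtype=float)
    weights = lengths * tree_lengths
    sites_per_window = rng.multinomial(n_sites, weights / weights.sum())

    chroms, poss, gts = [], [], []
    for w, (chrom, start, end) in enumerate(windows):
        wlen = end - start + 1
        s_w = min(int(sites_per_window[w]), wlen)
        if s_w == 0:
            continue
        parent, node_time, leaf_deme, _err = _genealogy_kernel(
            *enc, int(gseed[w] % (2**31))
        )
        gen = Genealogy(parent=parent, node_time=node_time, leaf_deme=leaf_deme)
        bl = gen.branch_lengths()
        desc = gen.descendant_matrix()
        branch = rng.choice(gen.n_nodes, size=s_w, p=bl / bl.sum())
        hap = desc[branch]  # (s_w, n_hap): derived-state per leaf
        gt = np.zeros((s_w, n_ind), dtype=np.int8)
        for leaf in range(hap.shape[1]):
            gt[:, leaf_ind[leaf]] += hap[:, leaf]
        # distinct positions without materialising the whole window
        if s_w > wlen // 3:
            pos = np.sort(
                rng.choice(np.arange(start, end + 1), size=s_w, replace=False)
            )
        else:
            cand = np.unique(rng.integers(start, end + 1, size=2 * s_w + 8))
            while cand.size < s_w:
                cand = np.unique(
                    np.concatenate([cand, rng.integers(start, end + 1, size=2 * s_w)])
                )
            pos = np.sort(rng.choice(cand, size=s_w, replace=False))
        chroms.append(np.repeat(chrom, pos.size))
        poss.append(pos)
        gts.append(gt)

    chrom = np.concatenate(chroms).astype(object)
    pos = np.concatenate(poss)
    gt = np.vstack(gts)
    n_out = gt.shape[0]

    # artifact sites: every genotyped call heterozygous
    n_art = int(round(design.artifact_fraction * n_out))
    art_idx = rng.choice(n_out, size=n_art, replace=False) if n_art else np.array([], int)
    gt[art_idx] = 1

    # depth and genotype quality
    ind_mean_dp = design.depth_mean * np.exp(
        rng.normal(0.0, design.depth_log_sd, size=n_ind)
        - design.depth_log_sd**2 / 2
    )
    dp = rng.poisson(ind_mean_dp[None, :], size=(n_out, n_ind)).astype(np.int32)
    gq = np.clip(
        np.rint(
            rng.normal(design.gq_mean, design.gq_sd, size=(n_out, n_ind))
            + 1.5 * (dp - design.depth_mean)
        ),
        0,
        99,
    ).astype(np.int32)

    # genotype-wise missingness, per-individual rates jittered around target
    gt_complete = gt.copy()  # post-artifact, pre-missingness matrix
    if design.missing_fraction > 0:
        jitter = rng.uniform(0.6, 1.4, size=n_ind)
        rates = design.missing_fraction * jitter / jitter.mean()
        mask = rng.random((n_out, n_ind)) < rates[None, :]
        gt = np.where(mask, np.int8(MISSING), gt)

    qual = 30.0 + rng.exponential(300.0, size=n_out)
    n_low = int(round(design.qual_low_fraction * n_out))
    if n_low:
        low_idx = rng.choice(n_out, size=n_low, replace=False)
        qual[low_idx] = rng.uniform(10.0, 30.0, size=n_low)

    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = rng.choice(bases, size=n_out)
    shift = rng.integers(1, 4, size=n_out)
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]

    table = VariantTable(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=qual,
        gt=gt,
        samples=meta["id"].tolist(),
        dp=dp,
        gq=gq,
    )

    implied_callable = n_out / (mu * tree_lengths.mean())
    call_jitter = rng.uniform(0.995, 1.0, size=n_ind)
    callable_counts = {
        meta["id"].iloc[i]: int(round(implied_callable * call_jitter[i]))
        for i in range(n_ind)
    }
    truth = {
        "model": model.to_dict(),
        "n_sites": n_out,
        "implied_callable": implied_callable,
        "polymorphic_fraction": n_out / implied_callable,
        "artifact_sites": np.sort(art_idx),
        "mean_tree_length": float(tree_lengths.mean()),
        "complete_gt": gt_complete,
        "rng_seed": rng_seed,
    }
    return SyntheticDataset(
        table=table, metadata=meta, callable_counts=callable_counts, truth=truth
    )


def generate_gff(
    design: StudyDesign, gene_density: float, rng_seed: int, path=None
) -> pd.DataFrame:
    """Random non-overlapping gene features covering ~``gene_density``
    of each chromosome; optionally written as GFF3."""
    if not 0.0 <= gene_density <= 1.0:
        raise ValueError("gene density must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    rows = []
    if gene_density > 0:
        for chrom, length in design.chromosomes:
            if gene_density >= 1.0:
                rows.append((chrom, 1, length))
                continue
            covered = 0
            cursor = 1
            target = gene_density * length
            while covered < target and cursor < length:
                gap = int(rng.exponential(
                    max(1.0, (length - target) / max(1.0, target / 5000.0))
                )) + 1
                glen = int(rng.uniform(2000, 8000))
                start = cursor + gap
                end = min(start + glen - 1, length)
                if start >= length:
                    break
                rows.append((chrom, start, end))
                covered += end - start + 1
                cursor = end + 1
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if path is not None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for k, (chrom, start, end) in enumerate(genes.itertuples(index=False)):
                fh.write(
                    f"{chrom}\tantdiv\tgene\t{start}\t{end}\t.\t+\t.\t"
                    f"ID=gene{k + 1}\n"
                )
    return genes
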