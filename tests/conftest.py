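import numpy as np
import pytest

from antdiv.demography import DemographicModel, Join, Resize
from antdiv.simulate import StudyDesign, generate_dataset
from antdiv.variants import VariantTable


def make_table(gt, chrom=None, pos=None, qual=None, dp=None, gq=None, samples=None):
    """Hand-built VariantTable from a genotype matrix (-1 = missing)."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    if chrom is None:
        chrom = np.repeat("chr1", n_sites).astype(object)
    else:
        chrom = np.asarray(chrom, dtype=object)
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if qual is None:
        qual = np.full(n_sites, 60.0)
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return VariantTable(
        chrom=chrom,
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.repeat("A", n_sites).astype(object),
        alt=np.repeat("T", n_sites).astype(object),
        qual=np.asarray(qual, dtype=np.float64),
        gt=gt,
        samples=list(samples),
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        gq=None if gq is None else np.asarray(gq, dtype=np.int32),
    )


@pytest.fixture(scope="session")
def two_pop_model():
    """Two demes of 2000 haploids splitting 3000 generations ago."""
    return DemographicModel(
        demes=[("pol", 2000.0), ("aq", 2000.0)],
        events=[Join(3000.0, "aq", "pol"), Resize(3000.0, "pol", 4000.0)],
        sample_config={"pol": 4, "aq": 4},
    )


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(
        locations=[("LocA", "polyctena", 2), ("LocB", "aquilonia", 2)],
        chromosomes=[("chr1", 400_000), ("chr2", 400_000), ("chr3", 200_000)],
        missing_fraction=0.12,
        artifact_fraction=0.01,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design, two_pop_model):
    """Shared 4-individual synthetic dataset (4000 SNPs, 20 windows)."""
    return generate_dataset(small_design, two_pop_model, 4000, rng_seed=20_240)


@pytest.fixture()
def pop_lists(small_dataset):
    meta = small_dataset.metadata
    pol = meta.loc[meta.species == "polyctena", "id"].tolist()
    aq = meta.loc[meta.species == "aquilonia", "id"].tolist()
    return pol, aq
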