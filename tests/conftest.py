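import numpy as np
import pytest

from bsamap.simcross import CrossConfig, simulate_experiment
from bsamap.snpindex import ScanConfig, compute_records, screen_parental_snps
from bsamap.variant_io import GeneModel, VariantSite

#: Composition means from the published table: group -> component -> (mean, sd).
COMPOSITION_TABLE = {
    "Nip": {"starch": (86.66, 0.74), "amylose": (20.43, 0.15),
            "amylopectin": (66.23, 0.81), "protein": (9.31, 0.05)},
    "Olr": {"starch": (77.55, 1.21), "amylose": (19.50, 0.38),
            "amylopectin": (58.05, 0.83), "protein": (14.13, 0.07)},
    "F3-normal": {"starch": (88.32, 0.13), "amylose": (17.96, 0.09),
                  "amylopectin": (70.36, 0.20), "protein": (7.56, 0.05)},
    "F3-Olr": {"starch": (75.71, 1.53), "amylose": (15.95, 0.04),
               "amylopectin": (59.76, 1.49), "protein": (14.90, 0.03)},
}


@pytest.fixture(scope="session")
def small_experiment():
    """One seeded bulk-sequencing simulation: 2 chromosomes, 1 causal SNP."""
    config = CrossConfig(
        chrom_lengths={"chr1": 25_000_000, "chr2": 25_000_000},
        n_markers=400,
        causal_locus=("chr1", 12_500_000),
        n_f2=800,
        bulk_size=152,
        mean_depth=50,
        seed=11,
    )
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def small_records(small_experiment):
    sc = ScanConfig()
    kept = screen_parental_snps(small_experiment.sites, sc)
    return compute_records(kept)


def make_site(chrom="chr1", pos=100, ref="G", alt="A", **counts):
    """VariantSite shorthand: make_site(MO=(1, 9), PN=(12, 0), ...)."""
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt, counts=dict(counts))


@pytest.fixture
def plus_gene():
    """Single-exon plus-strand model with GGC (Gly) at CDS positions 79-81.

    CDS spans genomic 101-280 (180 nt, 60 codons); codon 27 occupies
    genomic 179-181.
    """
    return GeneModel(gene_id="toy_plus", chrom="chr1", strand="+", cds=[(101, 280)])


@pytest.fixture
def plus_gene_seq(rng_seq):
    seq = rng_seq(300)
    # ATG start, GGC codon 27, no premature stops needed for codon tests
    seq = seq[:100] + "ATG" + seq[103:]
    seq = seq[:178] + "GGC" + seq[181:]
    return {"chr1": seq}


@pytest.fixture
def rng_seq():
    rng = np.random.default_rng(7)

    def _make(n, alphabet="ACGT"):
        return "".join(rng.choice(list(alphabet), size=n))

    return _make
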