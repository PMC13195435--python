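import numpy as np
import pytest

from skypurge.core import MISSING, GenotypeMatrix


def build_gm(dosage, pos=None, chrom=None, samples=None, pops=None,
             ref=None, alt=None, qual=None, multiallelic=None,
             contig_lengths=None):
    """Construct a GenotypeMatrix from a (sites x samples) dosage array with
    sensible defaults for everything else."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    pos = np.asarray(pos if pos is not None else np.arange(1, n_sites + 1) * 100,
                     dtype=np.int64)
    chrom = np.asarray(chrom if chrom is not None else ["Chr1"] * n_sites,
                       dtype=object)
    samples = list(samples) if samples is not None else [f"s{i}" for i in range(n_samples)]
    if pops is None:
        pops = {s: "P1" for s in samples}
    elif not isinstance(pops, dict):
        pops = dict(zip(samples, pops))
    ref = np.asarray(ref if ref is not None else ["A"] * n_sites, dtype=object)
    alt = alt if alt is not None else [("T",)] * n_sites
    qual = np.asarray(qual if qual is not None else [100.0] * n_sites, dtype=float)
    multiallelic = np.asarray(
        multiallelic if multiallelic is not None else [False] * n_sites, dtype=bool)
    return GenotypeMatrix(chrom=chrom, pos=pos, ref=ref, alt=list(alt),
                          qual=qual, multiallelic=multiallelic, dosage=dosage,
                          samples=samples, pop_of=pops,
                          contig_lengths=contig_lengths)


@pytest.fixture
def gm_factory():
    return build_gm


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    from skypurge.synthetic_data import SynthConfig, simulate_cohort

    return simulate_cohort(SynthConfig(seed=42, n_snps=4_000))
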