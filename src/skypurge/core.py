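"""Core containers shared across the pipeline.

The central object is :class:`GenotypeMatrix`, an array-backed table of
biallelic (or flagged multiallelic) variant sites by samples, with dosages
coded as the number of non-reference alleles and ``MISSING`` (= -1) for
uncalled genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Sentinel dosage for an uncalled / partially called genotype.
MISSING: int = -1


class VariantSite(NamedTuple):
    """A single variant record (view into a :class:`GenotypeMatrix` row)."""

    chrom: str
    pos: int            # 1-based
    ref: str
    alt: tuple[str, ...]
    qual: float
    multiallelic: bool


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites dosage matrix with population labels.

    Attributes
    ----------
    chrom, pos, ref, qual
        Per-site arrays, sorted by (chrom, pos).
    alt
        Per-site tuple of alternate alleles; dosages count the first one.
    multiallelic
        Per-site flag; such sites are retained by the reader and removed
        by the biallelic filter.
    dosage
        ``(n_sites, n_samples)`` int8 array of non-reference allele counts
        in {0, 1, 2} with :data:`MISSING` for uncalled genotypes.
    samples
        Ordered sample identifiers.
    pop_of
        Sample -> population label mapping (every sample must be present).
    dp, gq
        Optional per-genotype depth / genotype-quality arrays with the
        same shape as ``dosage`` (-1 where absent).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: list
    qual: np.ndarray
    multiallelic: np.ndarray
    dosage: np.ndarray
    samples: list
    pop_of: dict
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None
    contig_lengths: dict | None = None

    def __post_init__(self) -> None:
        n_sites = len(self.pos)
        if self.dosage.shape != (n_sites, len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{n_sites} sites x {len(self.samples)} samples"
            )
        missing_pop = [s for s in self.samples if s not in self.pop_of]
        if missing_pop:
            raise ValueError(f"samples without a population label: {missing_pop}")
        if np.any(self.pos < 1):
            raise ValueError("positions must be 1-based (>= 1)")

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list:
        seen: dict = {}
        for s in self.samples:
            seen.setdefault(self.pop_of[s], None)
        return list(seen)

    def site(self, i: int) -> VariantSite:
        return VariantSite(
            str(self.chrom[i]), int(self.pos[i]), str(self.ref[i]),
            tuple(self.alt[i]), float(self.qual[i]), bool(self.multiallelic[i]),
        )

    def sample_indices(self, pop: str) -> np.ndarray:
        """Column indices of samples belonging to ``pop``."""
        idx = np.array(
            [j for j, s in enumerate(self.samples) if self.pop_of[s] == pop],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"unknown population label: {pop!r}")
        return idx

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order kept)."""
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=[self.alt[i] for i in np.atleast_1d(index)],
            qual=self.qual[index],
            multiallelic=self.multiallelic[index],
            dosage=self.dosage[index],
            dp=None if self.dp is None else self.dp[index],
            gq=None if self.gq is None else self.gq[index],
        )

    def called_mask(self) -> np.ndarray:
        return self.dosage != MISSING

    def alt_frequency(self) -> np.ndarray:
        """Per-site alternate allele frequency over called genotypes (NaN if none)."""
        called = self.called_mask()
        n_alleles = 2 * called.sum(axis=1)
        alt_count = np.where(called, self.dosage, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt_count / np.maximum(n_alleles, 1), np.nan)

    def chrom_lengths(self) -> dict:
        """Chromosome lengths from the VCF header when known, otherwise the
        last observed site per chromosome."""
        out: dict = {}
        for c in pd.unique(self.chrom):
            c = str(c)
            if self.contig_lengths and c in self.contig_lengths:
                out[c] = int(self.contig_lengths[c])
            else:
                out[c] = int(self.pos[self.chrom == c].max())
        return out


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list
    values: np.ndarray
    kind: str = "generic"  # geographic | genetic | environmental | generic

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "generic") -> "DistanceMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float), kind)


def sort_sites(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Return a copy sorted by (chrom, pos)."""
    order = np.lexsort((gm.pos, gm.chrom))
    return gm.take_sites(order)


def population_allele_frequencies(gm: GenotypeMatrix,
                                  pops: Sequence[str] | None = None) -> pd.DataFrame:
    """Alternate/derived allele frequency per population (rows) and site
    (columns, labelled ``chrom:pos``), over called genotypes."""
    pops = list(pops) if pops is not None else gm.populations
    cols = [f"{c}:{p}" for c, p in zip(gm.chrom, gm.pos)]
    rows = []
    for pop in pops:
        dos = gm.dosage[:, gm.sample_indices(pop)]
        called = dos != MISSING
        n = 2 * called.sum(axis=1)
        alt = np.where(called, dos, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows.append(np.where(n > 0, alt / np.maximum(n, 1), np.nan))
    return pd.DataFrame(rows, index=pops, columns=cols)
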