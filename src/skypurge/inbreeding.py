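"""Per-individual heterozygosity, F_IS, runs of homozygosity and F_ROH.

ROH follow the PLINK-style definition used for plant resequencing panels:
maximal stretches of homozygous calls with no heterozygous call inside,
kept when they span more than ``min_len`` bp and contain at least
``min_snps`` homozygous SNPs. Missing calls neither break a run nor count
toward the SNP minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

__all__ = [
    "ROHSegment", "per_individual_het_fis", "detect_roh", "detect_roh_all",
    "classify_and_froh", "DEFAULT_GENOME_LENGTH",
]

#: Reference genome length (bp) used as the F_ROH denominator by default.
DEFAULT_GENOME_LENGTH: int = 786_920_000

SHORT_LONG_BOUNDARY: int = 100_000  # short: 1-100 kb (inclusive), long: > 100 kb


@dataclass(frozen=True)
class ROHSegment:
    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def length_class(self) -> str:
        return "short" if self.length <= SHORT_LONG_BOUNDARY else "long"


def per_individual_het_fis(gm: GenotypeMatrix) -> pd.DataFrame:
    """Observed vs expected homozygosity per individual.

    Expected homozygosity at a site is 1 - 2p(1-p) with p the sample-wide
    alternate frequency over called genotypes (method-of-moments, no
    small-sample correction). F_IS = (O_hom - E_hom) / (N - E_hom).
    """
    if gm.n_samples < 2:
        raise ValueError("need >= 2 samples to estimate allele frequencies")
    p = gm.alt_frequency()
    e_hom_site = 1 - 2 * p * (1 - p)
    called = gm.called_mask()
    is_hom = called & (gm.dosage != 1)
    n_sites = called.sum(axis=0)
    o_hom = is_hom.sum(axis=0)
    e_hom = np.where(called, e_hom_site[:, None], 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(n_sites > 0, (n_sites - o_hom) / np.maximum(n_sites, 1), np.nan)
        denom = n_sites - e_hom
        f_is = np.where(np.abs(denom) > 1e-12, (o_hom - e_hom) / np.where(denom == 0, 1, denom), np.nan)
    f_is = np.where(n_sites > 0, f_is, np.nan)
    return pd.DataFrame({
        "sample": gm.samples,
        "population": [gm.pop_of[s] for s in gm.samples],
        "n_sites": n_sites,
        "o_hom": o_hom,
        "e_hom": e_hom,
        "het_rate": het_rate,
        "f_is": f_is,
    })


def _roh_one_chrom(sample: str, chrom: str, pos: np.ndarray, dos: np.ndarray,
                   min_len: int, min_snps: int) -> list:
    """Scan one chromosome of one individual.

    Runs are delimited by heterozygous calls; homozygous calls accumulate,
    missing calls are transparent. Segment coordinates span the first to the
    last homozygous SNP of the run.
    """
    segments = []
    het_idx = np.flatnonzero(dos == 1)
    lo = np.concatenate(([0], het_idx + 1))          # run start indices
    hi = np.concatenate((het_idx, [len(dos)]))       # run end (exclusive)
    hom_idx = np.flatnonzero((dos != MISSING) & (dos != 1))
    first = np.searchsorted(hom_idx, lo, side="left")
    last = np.searchsorted(hom_idx, hi, side="left")
    n_hom = last - first
    for k in np.flatnonzero(n_hom >= min_snps):
        run = hom_idx[first[k]:last[k]]
        start, end = int(pos[run[0]]), int(pos[run[-1]])
        if end - start + 1 > min_len:
            segments.append(ROHSegment(sample, chrom, start, end, int(n_hom[k])))
    return segments


def detect_roh(gm: GenotypeMatrix, sample: str, min_len: int = 1_000,
               min_snps: int = 50) -> list:
    """Runs of homozygosity for one individual (span strictly > min_len bp,
    at least min_snps homozygous SNPs, zero heterozygous calls inside)."""
    if sample not in gm.samples:
        raise KeyError(f"unknown sample: {sample!r}")
    j = gm.samples.index(sample)
    segments = []
    for c in pd.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        segments.extend(
            _roh_one_chrom(sample, str(c), gm.pos[idx], gm.dosage[idx, j],
                           min_len, min_snps)
        )
    return segments


def detect_roh_all(gm: GenotypeMatrix, min_len: int = 1_000,
                   min_snps: int = 50) -> list:
    """ROH for every sample in the matrix."""
    segments = []
    chrom_idx = [(str(c), np.flatnonzero(gm.chrom == c)) for c in pd.unique(gm.chrom)]
    for j, sample in enumerate(gm.samples):
        for c, idx in chrom_idx:
            segments.extend(
                _roh_one_chrom(sample, c, gm.pos[idx], gm.dosage[idx, j],
                               min_len, min_snps)
            )
    return segments


def classify_and_froh(segments: list, samples: list,
                      genome_length_bp: int = DEFAULT_GENOME_LENGTH
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Short/long totals and F_ROH per sample.

    Returns (per-segment table, per-sample table with short/long bp totals
    and f_roh = total ROH bp / genome length).
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    seg_rows = [
        (s.sample, s.chrom, s.start, s.end, s.length, s.n_snps, s.length_class)
        for s in segments
    ]
    seg_df = pd.DataFrame(
        seg_rows,
        columns=["sample", "chrom", "start", "end", "length", "n_snps", "class"],
    )
    per_sample = []
    for sample in samples:
        if len(seg_df):
            sub = seg_df[seg_df["sample"] == sample]
            short_bp = int(sub.loc[sub["class"] == "short", "length"].sum())
            long_bp = int(sub.loc[sub["class"] == "long", "length"].sum())
        else:
            short_bp = long_bp = 0
        total = short_bp + long_bp
        per_sample.append((sample, short_bp, long_bp, total,
                           total / genome_length_bp))
    froh_df = pd.DataFrame(
        per_sample,
        columns=["sample", "short_bp", "long_bp", "total_roh_bp", "f_roh"],
    )
    return seg_df, froh_df
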