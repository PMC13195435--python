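"""Windowed diversity and differentiation statistics.

Implements nucleotide diversity (pi), Tajima's D and the Weir & Cockerham
(1984) Fst estimator in a 100-kb / 10-kb sliding-window frame, private
allele counts, LD-decay curves, and Mantel tests for isolation by
distance/environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .core import MISSING, DistanceMatrix, GenotypeMatrix
from .genotype_io import genotype_r2

__all__ = [
    "WindowSpec", "make_windows",
    "windowed_pi", "windowed_tajimas_d", "windowed_fst",
    "genomewide_fst", "pairwise_fst_matrix",
    "private_allele_counts", "ld_decay_curve", "mantel_test",
    "great_circle_matrix", "linearized_fst_matrix", "environment_distance_matrix",
]

EULER_GAMMA = float(np.euler_gamma)


@dataclass
class WindowSpec:
    """Sliding-window frame anchored at position 1 on each chromosome."""

    size: int = 100_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if self.size < 1 or self.step < 1:
            raise ValueError("window size and step must be positive")


def make_windows(chrom_lengths: dict, spec: WindowSpec | None = None) -> pd.DataFrame:
    """Tile each chromosome with windows of ``spec.size`` advanced by
    ``spec.step``; the terminal window is truncated to the chromosome end."""
    spec = spec or WindowSpec()
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 1
        while start <= length:
            rows.append((chrom, start, min(start + spec.size - 1, length)))
            if start + spec.size - 1 >= length:
                break
            start += spec.step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def _pop_site_arrays(gm: GenotypeMatrix, pop: str):
    """Called allele count n, alt count, per-site pi for one population."""
    cols = gm.sample_indices(pop)
    dos = gm.dosage[:, cols]
    called = dos != MISSING
    n = 2 * called.sum(axis=1)
    alt = np.where(called, dos, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        # unbiased per-site heterozygosity: (n/(n-1)) * 2 p (1-p)
        pi = np.where(n > 1, n / np.maximum(n - 1, 1) * 2 * p * (1 - p), 0.0)
    pi = np.where(np.isnan(pi), 0.0, pi)
    return n, alt, p, pi


def _window_slices(gm: GenotypeMatrix, windows: pd.DataFrame):
    """For each window row yield (chrom-local site index range) using
    searchsorted on the sorted positions of that chromosome."""
    by_chrom = {}
    for c in pd.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        by_chrom[str(c)] = (idx, gm.pos[idx])
    for row in windows.itertuples(index=False):
        idx_pos = by_chrom.get(str(row.chrom))
        if idx_pos is None:
            yield row, np.array([], dtype=int)
            continue
        idx, pos = idx_pos
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="right")
        yield row, idx[lo:hi]


def windowed_pi(gm: GenotypeMatrix, pop: str, windows: pd.DataFrame) -> pd.DataFrame:
    """Per-window nucleotide diversity: sum of per-site unbiased pi over
    variant sites divided by the window span in bp."""
    n, _, _, pi = _pop_site_arrays(gm, pop)
    rows = []
    for w, sites in _window_slices(gm, windows):
        span = w.end - w.start + 1
        with_data = sites[n[sites] > 1]
        val = float(pi[with_data].sum()) / span
        rows.append((w.chrom, w.start, w.end, "pi", pop, val, len(with_data)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "stat",
                                       "pop", "value", "n_variants"])


def _tajima_constants(n: float):
    """Tajima (1989) a1..e2 constants, continued to non-integer n via
    digamma/trigamma (exact at integers)."""
    a1 = digamma(n) + EULER_GAMMA               # sum_{i<n} 1/i
    a2 = np.pi ** 2 / 6 - polygamma(1, n)        # sum_{i<n} 1/i^2
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajimas_d_from_counts(theta_pi: float, S: int, n: float) -> float:
    """Tajima's D from summed pairwise diversity, segregating-site count and
    (possibly harmonic-mean) sample size in alleles; NaN when undefined."""
    if S == 0 or n <= 2:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    theta_w = S / a1
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((theta_pi - theta_w) / np.sqrt(var))


def windowed_tajimas_d(gm: GenotypeMatrix, pop: str, windows: pd.DataFrame) -> pd.DataFrame:
    """Per-window Tajima's D; the constants use the harmonic mean of
    per-site called allele counts over the window's segregating sites."""
    n, _, p, pi = _pop_site_arrays(gm, pop)
    seg = (n > 2) & (p > 0) & (p < 1)
    rows = []
    for w, sites in _window_slices(gm, windows):
        seg_sites = sites[seg[sites]]
        S = len(seg_sites)
        if S == 0:
            d = float("nan")
        else:
            n_harm = S / np.sum(1.0 / n[seg_sites])
            d = tajimas_d_from_counts(float(pi[seg_sites].sum()), S, n_harm)
        rows.append((w.chrom, w.start, w.end, "tajimas_d", pop, d, S))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "stat",
                                       "pop", "value", "n_variants"])


def _wc_components(gm: GenotypeMatrix, popA: str, popB: str):
    """Per-site Weir & Cockerham (1984) variance components a, b, c for two
    populations. Sites where either population has no called genotypes get
    NaN components."""
    comps = []
    for pop in (popA, popB):
        cols = gm.sample_indices(pop)
        dos = gm.dosage[:, cols]
        called = dos != MISSING
        n_i = called.sum(axis=1).astype(float)            # diploids
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(called, dos, 0).sum(axis=1) / np.maximum(2 * n_i, 1)
            h_i = np.where(called, dos == 1, False).sum(axis=1) / np.maximum(n_i, 1)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    valid = (n1 > 0) & (n2 > 0) & (n1 + n2 > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    # monomorphic-overall sites contribute zero to both sums
    mono = valid & ((pbar <= 0) | (pbar >= 1))
    for arr in (a, b, c):
        arr[mono] = 0.0
    return a, b, c


def windowed_fst(gm: GenotypeMatrix, popA: str, popB: str,
                 windows: pd.DataFrame) -> pd.DataFrame:
    """Weir-Cockerham theta per window as ratio of summed components."""
    a, b, c = _wc_components(gm, popA, popB)
    ok = ~np.isnan(a)
    rows = []
    pair = f"{popA}:{popB}"
    for w, sites in _window_slices(gm, windows):
        s = sites[ok[sites]]
        denom = float((a[s] + b[s] + c[s]).sum())
        val = float(a[s].sum()) / denom if (len(s) and denom != 0) else float("nan")
        rows.append((w.chrom, w.start, w.end, "fst", pair, val, len(s)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "stat",
                                       "pop", "value", "n_variants"])


def genomewide_fst(gm: GenotypeMatrix, popA: str, popB: str) -> dict:
    """Genome-wide Weir-Cockerham theta, both as ratio-of-sums over all
    sites (primary) and as the mean of per-site ratios."""
    a, b, c = _wc_components(gm, popA, popB)
    ok = ~np.isnan(a)
    denom = (a[ok] + b[ok] + c[ok])
    total = denom.sum()
    ratio_of_sums = float(a[ok].sum() / total) if total != 0 else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = a[ok] / denom
    per_site = per_site[np.isfinite(per_site)]
    return {
        "ratio_of_sums": ratio_of_sums,
        "mean_of_ratios": float(per_site.mean()) if per_site.size else float("nan"),
    }


def pairwise_fst_matrix(gm: GenotypeMatrix, pops: list | None = None) -> DistanceMatrix:
    """Full population-pair matrix of genome-wide (ratio-of-sums) Fst."""
    pops = pops or gm.populations
    k = len(pops)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            v = genomewide_fst(gm, pops[i], pops[j])["ratio_of_sums"]
            m[i, j] = m[j, i] = v
    return DistanceMatrix(list(pops), m, kind="genetic")


def private_allele_counts(gm: GenotypeMatrix, pops: list | None = None) -> pd.Series:
    """Count alleles (ref or alt) observed in exactly one population."""
    pops = pops or gm.populations
    if len(pops) < 2:
        raise ValueError("private alleles need >= 2 populations")
    ref_seen = np.zeros((len(pops), gm.n_sites), dtype=bool)
    alt_seen = np.zeros((len(pops), gm.n_sites), dtype=bool)
    for k, pop in enumerate(pops):
        dos = gm.dosage[:, gm.sample_indices(pop)]
        called = dos != MISSING
        alt_seen[k] = np.any(called & (dos > 0), axis=1)
        ref_seen[k] = np.any(called & (dos < 2), axis=1)
    counts = {}
    for k, pop in enumerate(pops):
        others = np.ones(len(pops), dtype=bool)
        others[k] = False
        priv_alt = alt_seen[k] & ~alt_seen[others].any(axis=0)
        priv_ref = ref_seen[k] & ~ref_seen[others].any(axis=0)
        counts[pop] = int(priv_alt.sum() + priv_ref.sum())
    return pd.Series(counts, name="private_alleles")


def ld_decay_curve(gm: GenotypeMatrix, max_dist: int = 300_000,
                   bin_size: int = 5_000, query_level: float = 0.2,
                   sample_cols: np.ndarray | None = None) -> tuple[pd.DataFrame, float]:
    """Mean r2 per physical-distance bin for all intra-chromosome SNP pairs
    within ``max_dist``; also returns the first bin midpoint where the
    3-bin-smoothed curve falls below ``query_level`` (NaN if never)."""
    dos = gm.dosage if sample_cols is None else gm.dosage[:, sample_cols]
    sums = np.zeros(int(np.ceil(max_dist / bin_size)))
    cnts = np.zeros_like(sums, dtype=int)
    for c in pd.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[idx]
        for ai in range(len(idx)):
            hi = np.searchsorted(pos, pos[ai] + max_dist, side="right")
            for bi in range(ai + 1, hi):
                d = pos[bi] - pos[ai]
                if d == 0:
                    continue
                r2 = genotype_r2(dos[idx[ai]], dos[idx[bi]])
                if np.isnan(r2):
                    continue
                k = min(int(d // bin_size), len(sums) - 1)
                sums[k] += r2
                cnts[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    mid = (np.arange(len(sums)) + 0.5) * bin_size
    table = pd.DataFrame({"bin_bp": mid.astype(int), "mean_r2": mean_r2,
                          "n_pairs": cnts})
    # 3-bin moving average over defined bins
    defined = table.dropna(subset=["mean_r2"])
    decay_at = float("nan")
    if len(defined):
        sm = defined["mean_r2"].rolling(3, center=True, min_periods=1).mean()
        below = defined["bin_bp"][sm < query_level]
        if len(below):
            decay_at = float(below.iloc[0])
    return table, decay_at


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
                seed: int | None = None) -> tuple[float, float]:
    """Mantel correlation of two distance matrices with a one-sided
    (greater) permutation p-value, permuting the label order of ``d2``.

    p = (1 + #{permuted r >= observed r}) / (n_perm + 1).
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels and order")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    iu = np.triu_indices(len(d1.labels), k=1)
    x = d1.values[iu]

    def corr_with(mat: np.ndarray) -> float:
        y = mat[iu]
        if x.std() == 0 or y.std() == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr_with(d2.values)
    if np.isnan(r_obs):
        return float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    k = 0
    n = len(d1.labels)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(d2.values[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            k += 1
    return r_obs, (1 + k) / (n_perm + 1)


# ---------------------------------------------------------------------------
# distance-matrix constructors for IBD / IBE
# ---------------------------------------------------------------------------

def great_circle_matrix(coords: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances in km from a table indexed by
    population with columns lon, lat (degrees)."""
    labels = list(coords.index)
    lon = np.radians(coords["lon"].to_numpy(float))
    lat = np.radians(coords["lat"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, (d + d.T) / 2, kind="geographic")


def linearized_fst_matrix(fst: DistanceMatrix) -> DistanceMatrix:
    """Rousset linearization Fst / (1 - Fst), clipping Fst below at 0."""
    f = np.clip(fst.values, 0.0, 0.999999)
    return DistanceMatrix(fst.labels, f / (1 - f), kind="genetic")


def environment_distance_matrix(env: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance on z-scored environmental variables (rows are
    populations, columns are variables)."""
    z = (env - env.mean()) / env.std(ddof=0).replace(0, 1)
    v = z.to_numpy(float)
    d = np.sqrt(((v[:, None, :] - v[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(env.index), d, kind="environmental")
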