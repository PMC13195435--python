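"""Joint Fst x ln(pi-ratio) outlier windows and candidate gene overlap.

Windows in the upper tail (default top 5%) of both the between-population
Fst distribution and the log diversity ratio ln(pi_contrast / pi_focal)
are called sweep candidates; the upper ratio tail marks diversity loss in
the focal population.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .annotation import GeneModel, load_gff3

__all__ = [
    "ln_pi_ratio", "joint_outlier_windows", "merge_candidate_regions",
    "annotate_candidate_genes",
]

_WINDOW_KEY = ["chrom", "start", "end"]


def ln_pi_ratio(pi_contrast: pd.DataFrame, pi_focal: pd.DataFrame) -> pd.DataFrame:
    """Per-window ln(pi_contrast / pi_focal); windows where either pi is
    zero or undefined are dropped (logged in the ``n_dropped`` attr)."""
    a = pi_contrast.set_index(_WINDOW_KEY)["value"]
    b = pi_focal.set_index(_WINDOW_KEY)["value"]
    if not a.index.equals(b.index):
        raise ValueError("pi tables are on different window frames")
    ok = (a > 0) & (b > 0) & a.notna() & b.notna()
    out = pd.DataFrame({
        "value": np.log(a[ok] / b[ok]),
        "stat": "ln_pi_ratio",
    }).reset_index()
    out.attrs["n_dropped"] = int((~ok).sum())
    return out


def joint_outlier_windows(fst: pd.DataFrame, ratio: pd.DataFrame,
                          q: float = 0.95) -> pd.DataFrame:
    """Windows in the top (1-q) tail of both statistics.

    Thresholds are empirical ``q``-quantiles over windows where both
    statistics are defined; candidates satisfy value >= threshold for both
    (ties all included). Threshold values are recorded in ``attrs``.
    """
    f = fst.set_index(_WINDOW_KEY)["value"].rename("fst")
    r = ratio.set_index(_WINDOW_KEY)["value"].rename("ln_pi_ratio")
    df = pd.concat([f, r], axis=1, join="inner").dropna()
    if len(df) < 20:
        warnings.warn(f"only {len(df)} windows; quantile thresholds are unstable")
    fst_thr = float(np.quantile(df["fst"], q)) if len(df) else float("nan")
    ratio_thr = float(np.quantile(df["ln_pi_ratio"], q)) if len(df) else float("nan")
    out = df.reset_index()
    out["in_top_fst"] = out["fst"] >= fst_thr
    out["in_top_ratio"] = out["ln_pi_ratio"] >= ratio_thr
    out["candidate"] = out["in_top_fst"] & out["in_top_ratio"]
    out.attrs["fst_threshold"] = fst_thr
    out.attrs["ratio_threshold"] = ratio_thr
    out.attrs["q"] = q
    return out


def merge_candidate_regions(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent candidate windows into regions
    (chrom, start, end, n_windows)."""
    cand = windows[windows["candidate"]].sort_values(["chrom", "start"])
    regions = []
    for _, row in cand.iterrows():
        if regions and regions[-1][0] == row["chrom"] and row["start"] <= regions[-1][2] + 1:
            regions[-1][2] = max(regions[-1][2], int(row["end"]))
            regions[-1][3] += 1
        else:
            regions.append([row["chrom"], int(row["start"]), int(row["end"]), 1])
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows"])


def annotate_candidate_genes(regions: pd.DataFrame, gff) -> pd.DataFrame:
    """Genes overlapping any merged candidate region by >= 1 bp; each gene
    is reported once with the list of regions it touches."""
    genes = gff if isinstance(gff, list) else load_gff3(gff)
    rows: dict = {}
    for gene in genes:
        sub = regions[regions["chrom"].astype(str) == gene.chrom]
        hits = sub[(sub["start"] <= gene.end) & (sub["end"] >= gene.start)]
        if len(hits):
            rows[gene.gene_id] = {
                "gene": gene.gene_id,
                "chrom": gene.chrom,
                "start": gene.start,
                "end": gene.end,
                "regions": [f"{r.chrom}:{r.start}-{r.end}"
                            for r in hits.itertuples(index=False)],
            }
    return pd.DataFrame(list(rows.values()),
                        columns=["gene", "chrom", "start", "end", "regions"])
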