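"""Derived-allele genetic load: polarization, DEL/TOL split, load ratios,
and 0-fold / 4-fold diversity.

Alleles are polarized by the majority-homozygote rule: an allele is called
ancestral when more than a configured fraction (default one half) of
individuals are homozygous for it; dosages are then recoded to derived
counts. Reference-discordant ancestral calls are excluded by default to
avoid reference bias in the load tallies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

__all__ = [
    "polarize_to_derived", "split_missense_by_score",
    "tally_load_ratios", "pi0_pi4_ratio",
]

LOAD_CLASSES = ("SYN", "TOL", "DEL", "LoF")


def polarize_to_derived(gm: GenotypeMatrix, majority: float = 0.5,
                        require_ref_ancestral: bool = True,
                        denominator: str = "called"
                        ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Recode dosages to derived-allele counts.

    A site is polarized when one homozygote class exceeds ``majority`` of
    individuals (``denominator='called'`` counts called genotypes only;
    ``'all'`` counts every sample, missing included). When the alternate
    allele is ancestral, dosages flip (0<->2). Sites with no majority class
    get status ``excluded_tie``; with ``require_ref_ancestral`` sites whose
    ancestral allele is not the reference get ``excluded_nonref``. Excluded
    sites are dropped from the returned matrix.
    """
    if not 0.0 < majority < 1.0:
        raise ValueError("majority must be in (0, 1)")
    if denominator not in ("called", "all"):
        raise ValueError("denominator must be 'called' or 'all'")
    dos = gm.dosage
    called = dos != MISSING
    hom_ref = (dos == 0).sum(axis=1)
    hom_alt = (dos == 2).sum(axis=1)
    denom = called.sum(axis=1) if denominator == "called" else np.full(
        gm.n_sites, gm.n_samples)
    denom_safe = np.maximum(denom, 1)

    anc_is_ref = hom_ref / denom_safe > majority
    anc_is_alt = hom_alt / denom_safe > majority
    status = np.where(anc_is_ref, "polarized",
                      np.where(anc_is_alt, "polarized", "excluded_tie"))
    ancestral = np.where(anc_is_ref, gm.ref,
                         np.where(anc_is_alt, [a[0] for a in gm.alt], ""))
    derived = np.where(anc_is_ref, [a[0] for a in gm.alt],
                       np.where(anc_is_alt, gm.ref, ""))
    if require_ref_ancestral:
        nonref = anc_is_alt.copy()
        status = np.where(nonref, "excluded_nonref", status)
        keep = anc_is_ref
    else:
        keep = anc_is_ref | anc_is_alt

    table = pd.DataFrame({
        "chrom": gm.chrom, "pos": gm.pos,
        "ancestral": ancestral, "derived": derived, "status": status,
    })
    out = gm.take_sites(np.flatnonzero(keep))
    flip = anc_is_alt[keep]
    if flip.any():
        d = out.dosage
        flipped = np.where(d == MISSING, MISSING, 2 - d)
        out.dosage = np.where(flip[:, None], flipped, d).astype(np.int8)
    return out, table


def split_missense_by_score(ann: pd.DataFrame, scores: pd.DataFrame,
                            cutoff: float = 0.5) -> pd.DataFrame:
    """Split MIS annotations into DEL (score < cutoff) and TOL (>= cutoff).

    ``scores`` columns: chrom, pos, alt, score, confidence. Missense sites
    with no score, NA score or low confidence are marked ``MIS_excluded``
    and skipped by the load tallies.
    """
    s = scores.copy()
    if "confidence" not in s.columns:
        s["confidence"] = "high"
    finite = s["score"].notna()
    if ((s.loc[finite, "score"] < 0) | (s.loc[finite, "score"] > 1)).any():
        raise ValueError("deleteriousness scores must lie in [0, 1]")
    key = ["chrom", "pos", "alt"]
    s["chrom"] = s["chrom"].astype(str)
    out = ann.copy()
    out["chrom"] = out["chrom"].astype(str)
    out = out.merge(s[key + ["score", "confidence"]], on=key, how="left")
    is_mis = out["effect"] == "MIS"
    usable = is_mis & out["score"].notna() & (out["confidence"].str.lower() != "low")
    out.loc[usable & (out["score"] < cutoff), "effect"] = "DEL"
    out.loc[usable & (out["score"] >= cutoff), "effect"] = "TOL"
    out.loc[is_mis & ~usable, "effect"] = "MIS_excluded"
    return out


def tally_load_ratios(gm: GenotypeMatrix, ann: pd.DataFrame,
                      zygosity_matched: bool = True
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual derived-allele counts by class and zygosity plus
    DEL/SYN and LoF/SYN ratios.

    ``gm`` must already be polarized (dosage = derived count). With
    ``zygosity_matched`` ratios divide het by het-SYN and hom by hom-SYN
    (so heterozygous and homozygous load tracts are compared separately);
    otherwise the denominator is the total SYN count.
    Returns (per-sample table, per-population means).
    """
    ann_idx = ann.reset_index(drop=True)
    if len(ann_idx) != gm.n_sites:
        raise ValueError("annotation rows must align 1:1 with gm sites")
    rows = []
    class_masks = {c: (ann_idx["effect"] == c).to_numpy() for c in LOAD_CLASSES}
    if not class_masks["SYN"].any():
        raise ValueError("no SYN sites available as the load denominator")
    dos = gm.dosage
    for j, sample in enumerate(gm.samples):
        d = dos[:, j]
        het = d == 1
        hom = d == 2
        rec = {"sample": sample, "population": gm.pop_of[sample]}
        for c, m in class_masks.items():
            rec[f"{c}_het"] = int((het & m).sum())
            rec[f"{c}_hom"] = int((hom & m).sum())
        for c in ("DEL", "LoF"):
            for z in ("het", "hom"):
                num = rec[f"{c}_{z}"]
                den = (rec[f"SYN_{z}"] if zygosity_matched
                       else rec["SYN_het"] + rec["SYN_hom"])
                rec[f"{c.lower()}_syn_{z}"] = num / den if den > 0 else np.nan
        rows.append(rec)
    per_sample = pd.DataFrame(rows)
    ratio_cols = [c for c in per_sample.columns if "_syn_" in c]
    count_cols = [f"{c}_{z}" for c in LOAD_CLASSES for z in ("het", "hom")]
    per_pop = per_sample.groupby("population")[ratio_cols + count_cols].mean()
    return per_sample, per_pop


def pi0_pi4_ratio(gm: GenotypeMatrix, degeneracy: pd.DataFrame, pop: str
                  ) -> tuple[float, float, float]:
    """Mean per-site diversity at 0-fold vs 4-fold degenerate sites.

    Monomorphic annotated sites contribute zero diversity but count in the
    denominators, so pi_0 and pi_4 are per-annotated-site averages. Returns
    (pi0, pi4, pi0/pi4); the ratio is NaN when pi4 is zero.
    """
    from .diversity import _pop_site_arrays

    n, _, _, pi = _pop_site_arrays(gm, pop)
    key = pd.MultiIndex.from_arrays([gm.chrom.astype(str), gm.pos])
    site_pi = pd.Series(np.where(n > 1, pi, 0.0), index=key)

    def class_pi(fold: int) -> float:
        sub = degeneracy[degeneracy["fold"] == fold]
        if len(sub) == 0:
            return float("nan")
        idx = pd.MultiIndex.from_arrays([sub["chrom"].astype(str), sub["pos"]])
        matched = site_pi.reindex(idx).fillna(0.0)  # monomorphic -> 0
        return float(matched.sum() / len(sub))

    pi0 = class_pi(0)
    pi4 = class_pi(4)
    ratio = pi0 / pi4 if (pi4 and not np.isnan(pi4) and pi4 > 0) else float("nan")
    return pi0, pi4, ratio
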