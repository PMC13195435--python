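"""Read, filter, and LD-prune multi-sample genotype data.

Filtering mirrors a VCFtools-style pass (``--min-meanDP --minGQ --minQ
--maf --remove-indels --max-missing --min-alleles 2 --max-alleles 2``) and
pruning mirrors PLINK ``--indep-pairwise <window> <step> <r2>`` on dosage
(composite) r-squared.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

__all__ = [
    "SiteFilterSpec", "LDPruneSpec", "FilterLog",
    "read_popmap", "read_vcf", "write_vcf",
    "apply_site_filters", "genotype_r2", "ld_prune",
]


@dataclass
class SiteFilterSpec:
    """Site-level filter thresholds (defaults follow common practice for
    resequencing panels: mean depth >= 3, GQ >= 10, QUAL >= 30, MAF >= 0.05,
    SNPs only, call rate >= 0.8, biallelic only)."""

    min_mean_dp: float = 3.0
    min_gq: int = 10
    min_qual: float = 30.0
    min_maf: float = 0.05
    remove_indels: bool = True
    max_missing: float = 0.8   # VCFtools semantics: required call-rate fraction
    biallelic_only: bool = True
    strict_format: bool = False  # error (vs skip) when DP/GQ rules lack data

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")


@dataclass
class LDPruneSpec:
    """PLINK-style pruning window: SNP-count window, SNP step, r2 cutoff."""

    window_snps: int = 100
    step_snps: int = 1
    r2_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.step_snps < 1:
            raise ValueError("step_snps must be >= 1")


@dataclass
class FilterLog:
    """Per-rule removal counts; rules are applied in the listed order and a
    removed site is attributed to the first rule it fails."""

    n_input: int = 0
    n_output: int = 0
    removed: dict = field(default_factory=dict)
    skipped_rules: list = field(default_factory=list)

    def total_removed(self) -> int:
        return int(sum(self.removed.values()))

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_output": self.n_output,
                "removed": self.removed,
                "skipped_rules": self.skipped_rules,
            },
            indent=2,
        )


def read_popmap(path) -> dict:
    """Read a two-column sample<TAB>population table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["population"]))


def read_vcf(path, popmap) -> GenotypeMatrix:
    """Load a VCF 4.x file into a :class:`GenotypeMatrix`.

    ``popmap`` may be a path to a TSV or a sample->population dict. Dosages
    count occurrences of the first ALT allele; any unresolved or partial GT
    becomes :data:`MISSING`. Multiallelic records are retained and flagged so
    the biallelic filter can remove them later.
    """
    from cyvcf2 import VCF

    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ValueError(f"samples absent from popmap: {absent}")

    try:
        contig_lengths = {s: int(ln) for s, ln in zip(vcf.seqnames, vcf.seqlens)}
    except Exception:
        contig_lengths = None

    chroms, poss, refs, alts, quals, multi = [], [], [], [], [], []
    dosages, dps, gqs = [], [], []
    header = vcf.raw_header
    has_dp = "##FORMAT=<ID=DP," in header
    has_gq = "##FORMAT=<ID=GQ," in header
    for rec in vcf:
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(tuple(rec.ALT))
        quals.append(rec.QUAL if rec.QUAL is not None else np.nan)
        multi.append(len(rec.ALT) > 1)
        gt = np.asarray(rec.genotype.array())[:, :2]
        called = np.all(gt >= 0, axis=1)
        dos = np.where(called, (gt == 1).sum(axis=1), MISSING).astype(np.int8)
        dosages.append(dos)
        d = rec.format("DP") if has_dp else None
        q = rec.format("GQ") if has_gq else None
        if d is not None:
            dps.append(np.where(d[:, 0] < 0, -1, d[:, 0]).astype(np.int32))
        else:
            dps.append(np.full(len(samples), -1, dtype=np.int32))
        if q is not None:
            qq = q[:, 0].astype(float)
            qq = np.where(np.isfinite(qq), qq, -1)
            gqs.append(qq.astype(np.int32))
        else:
            gqs.append(np.full(len(samples), -1, dtype=np.int32))

    n = len(poss)
    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=alts,
        qual=np.array(quals, dtype=float),
        multiallelic=np.array(multi, dtype=bool),
        dosage=np.vstack(dosages) if n else np.zeros((0, len(samples)), np.int8),
        samples=samples,
        pop_of={s: popmap[s] for s in samples},
        dp=np.vstack(dps) if (n and has_dp) else None,
        gq=np.vstack(gqs) if (n and has_gq) else None,
        contig_lengths=contig_lengths,
    )
    order = np.lexsort((gm.pos, gm.chrom.astype(str)))
    if not np.array_equal(order, np.arange(n)):
        gm = gm.take_sites(order)
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix back out as a minimal plain-text VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in gm.chrom_lengths().items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.dp is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        if gm.gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        fmt = "GT" + (":DP" if gm.dp is not None else "") + (":GQ" if gm.gq is not None else "")
        for i in range(gm.n_sites):
            qual = gm.qual[i]
            qual_s = "." if np.isnan(qual) else f"{qual:g}"
            cells = []
            for j in range(gm.n_samples):
                cell = gt_str[int(gm.dosage[i, j])]
                if gm.dp is not None:
                    cell += ":" + (str(int(gm.dp[i, j])) if gm.dp[i, j] >= 0 else ".")
                if gm.gq is not None:
                    cell += ":" + (str(int(gm.gq[i, j])) if gm.gq[i, j] >= 0 else ".")
                cells.append(cell)
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t"
                f"{','.join(gm.alt[i])}\t{qual_s}\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def apply_site_filters(gm: GenotypeMatrix, spec: SiteFilterSpec) -> tuple[GenotypeMatrix, FilterLog]:
    """Apply site-level filters; returns the filtered matrix and a log.

    Rule order: GQ masking of individual genotypes first, then per-site
    checks biallelic-SNP -> QUAL -> mean depth -> call rate -> MAF, with each
    removed site attributed to the first rule it fails. MAF is computed on
    called alleles only, so sites monomorphic after GQ masking fall to the
    MAF rule.
    """
    log = FilterLog(n_input=gm.n_sites)
    dosage = gm.dosage.copy()

    # genotype-level GQ mask before any per-site accounting
    if spec.min_gq > 0:
        if gm.gq is None:
            if spec.strict_format:
                raise ValueError("GQ filter requested but VCF has no GQ FORMAT field")
            log.skipped_rules.append("min_gq")
            warnings.warn("VCF lacks GQ; min_gq rule skipped (permissive mode)")
        else:
            dosage[(gm.gq >= 0) & (gm.gq < spec.min_gq)] = MISSING

    called = dosage != MISSING
    n_called = called.sum(axis=1)
    keep = np.ones(gm.n_sites, dtype=bool)

    def apply_rule(name: str, ok: np.ndarray) -> None:
        newly = keep & ~ok
        log.removed[name] = int(newly.sum())
        keep[newly] = False

    if spec.biallelic_only:
        apply_rule("multiallelic", ~gm.multiallelic)
    if spec.remove_indels:
        is_snp = np.array(
            [len(r) == 1 and all(len(a) == 1 for a in al)
             for r, al in zip(gm.ref, gm.alt)], dtype=bool,
        )
        apply_rule("indel", is_snp)

    with np.errstate(invalid="ignore"):
        qual_ok = ~(gm.qual < spec.min_qual)  # NaN QUAL passes (missing annotation)
    apply_rule("qual", qual_ok)

    if spec.min_mean_dp > 0:
        if gm.dp is None:
            if spec.strict_format:
                raise ValueError("mean-DP filter requested but VCF has no DP FORMAT field")
            log.skipped_rules.append("min_mean_dp")
            warnings.warn("VCF lacks DP; min_mean_dp rule skipped (permissive mode)")
        else:
            dp_ok = np.where((gm.dp >= 0) & called, gm.dp, 0).astype(float)
            n_with_dp = ((gm.dp >= 0) & called).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_dp = dp_ok.sum(axis=1) / np.maximum(n_with_dp, 1)
            apply_rule("mean_dp", (n_with_dp > 0) & (mean_dp >= spec.min_mean_dp))

    call_rate = n_called / max(gm.n_samples, 1)
    apply_rule("call_rate", call_rate >= spec.max_missing)

    alt_count = np.where(called, dosage, 0).sum(axis=1)
    n_alleles = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt_count / np.maximum(n_alleles, 1)
    maf = np.minimum(p, 1 - p)
    apply_rule("maf", (n_alleles > 0) & (maf >= spec.min_maf))

    out = gm.take_sites(np.flatnonzero(keep))
    out.dosage = dosage[keep]
    log.n_output = out.n_sites
    return out, log


def genotype_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples; NaN if either is constant or <2 complete."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _window_r2(dos: np.ndarray, j: int, idx: np.ndarray) -> np.ndarray:
    """r2 of SNP j against SNPs ``idx`` with pairwise-complete handling."""
    x = dos[j].astype(float)
    Y = dos[idx].astype(float)
    mx = x != MISSING
    MY = Y != MISSING
    both = MY & mx
    n = both.sum(axis=1).astype(float)
    xs = np.where(both, x, 0.0)
    ys = np.where(both, Y, 0.0)
    sx = xs.sum(axis=1)
    sy = ys.sum(axis=1)
    sxx = (xs * xs).sum(axis=1)
    syy = (ys * ys).sum(axis=1)
    sxy = (xs * ys).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / np.maximum(n, 1)
        vx = sxx - sx * sx / np.maximum(n, 1)
        vy = syy - sy * sy / np.maximum(n, 1)
        r2 = cov * cov / (vx * vy)
    r2[(n < 2) | (vx <= 0) | (vy <= 0)] = np.nan
    return r2


def ld_prune(gm: GenotypeMatrix, spec: LDPruneSpec | None = None) -> tuple[GenotypeMatrix, np.ndarray]:
    """Sliding-window LD pruning; returns (pruned matrix, kept site indices).

    Within each window of ``window_snps`` SNPs (advanced by ``step_snps``),
    any retained pair with r2 above the threshold drops the later-positioned
    SNP. Afterwards no retained pair inside any window exceeds the threshold.
    """
    spec = spec or LDPruneSpec()
    keep = np.ones(gm.n_sites, dtype=bool)
    for c in pd.unique(gm.chrom):
        sites = np.flatnonzero(gm.chrom == c)
        n = len(sites)
        w, step = spec.window_snps, spec.step_snps
        if step == 1:
            # with unit step every window is covered by checking each SNP
            # against the previous w-1 kept SNPs
            for local_j in range(1, n):
                lo = max(0, local_j - w + 1)
                prev = sites[lo:local_j][keep[sites[lo:local_j]]]
                if prev.size == 0:
                    continue
                r2 = _window_r2(gm.dosage, sites[local_j], prev)
                if np.any(r2 > spec.r2_threshold):
                    keep[sites[local_j]] = False
        else:
            start = 0
            while start < n:
                win = sites[start:start + w]
                for a_i in range(len(win)):
                    if not keep[win[a_i]]:
                        continue
                    later = win[a_i + 1:][keep[win[a_i + 1:]]]
                    if later.size:
                        r2 = _window_r2(gm.dosage, win[a_i], later)
                        keep[later[r2 > spec.r2_threshold]] = False
                if start + w >= n:
                    break
                start += step
    kept_idx = np.flatnonzero(keep)
    return gm.take_sites(kept_idx), kept_idx
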