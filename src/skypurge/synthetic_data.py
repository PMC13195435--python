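"""Synthetic sky-island cohorts with known truth for every pipeline stage.

The generator emulates a seven-population, three-lineage resequencing
design: Balding-Nichols allele-frequency divergence, per-population
autozygosity tracts (literal haplotype-copy segments, so ROH detection has
positional ground truth), deleterious mutation classes with frequency
suppression and an optional purging deficit of homozygous deleterious
genotypes, environment-associated loci along a precipitation-like gradient,
and paired current/future climate grids for several emission scenarios and
climate models. A toy gene annotation (GFF3 + FASTA) is built so that
effect classification recovers every configured coding class exactly, and a
fabricated per-site deleteriousness score table separates DEL from TOL.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .offset import ClimateGrid

__all__ = ["SynthConfig", "SimulatedCohort", "simulate_cohort", "write_fixture_bundle"]

# population layout of the emulated study range (south -> north)
DEFAULT_POPS = ("HDL", "WTS", "BJS", "JMS", "BHS", "SS", "JK")
DEFAULT_LINEAGES = {
    "HDL": "southern",
    "WTS": "central", "BJS": "central", "JMS": "central",
    "BHS": "central", "SS": "central",
    "JK": "northern",
}
DEFAULT_COORDS = {
    "HDL": (113.8, 36.1), "WTS": (113.5, 38.9), "BJS": (114.2, 39.5),
    "JMS": (115.3, 40.0), "BHS": (115.5, 39.8), "SS": (115.8, 40.5),
    "JK": (116.5, 40.4),
}
BIO_VARS = tuple(f"bio{i}" for i in range(1, 20))

# toy codon templates: (ref codon, offset of SNP within codon, alt CDS base)
_CLASS_CODONS = {
    "SYN": ("GGT", 2, "A"),   # GGT -> GGA, both Gly (4-fold third position)
    "TOL": ("GCT", 0, "A"),   # GCT -> ACT, Ala -> Thr missense
    "DEL": ("GCT", 0, "T"),   # GCT -> TCT, Ala -> Ser missense
    "LoF": ("TGG", 1, "A"),   # TGG -> TAG, Trp -> stop gained
}
_FILLER_CODON = "GGC"
_GENE_CDS_LEN = 300           # 100 codons: ATG + 98 usable + stop
_USABLE_CODONS = 98
_GENE_GAP = 200
_GENE_REGION_START = 10_000


@dataclass
class SynthConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated design: 7 populations of 20 diploids in 3
    lineages, ~20k SNPs on 4 chromosomes, one heavily selfing population
    (JK) that also carries the purging deficit, deleterious classes with
    frequency suppression, and 100 adaptive loci tied to a precipitation-
    like gradient (bio18).
    """

    seed: int
    n_per_pop: int = 20
    pops: tuple = DEFAULT_POPS
    lineage_of: dict = field(default_factory=lambda: dict(DEFAULT_LINEAGES))
    coords: dict = field(default_factory=lambda: dict(DEFAULT_COORDS))
    chrom_lengths: dict = field(default_factory=lambda: {
        f"Chr{i}": 2_500_000 for i in range(1, 5)})
    n_snps: int = 20_000
    lineage_f: float = 0.08
    pop_f: dict = field(default_factory=lambda: {
        "HDL": 0.10, "WTS": 0.06, "BJS": 0.10, "JMS": 0.08,
        "BHS": 0.08, "SS": 0.08, "JK": 0.15})
    autozygosity: dict = field(default_factory=lambda: {
        "HDL": 0.05, "WTS": 0.05, "BJS": 0.05, "JMS": 0.05,
        "BHS": 0.05, "SS": 0.05, "JK": 0.30})
    roh_scale_bp: int = 200_000
    class_fractions: dict = field(default_factory=lambda: {
        "SYN": 0.15, "TOL": 0.05, "DEL": 0.05, "LoF": 0.02})
    suppression: dict = field(default_factory=lambda: {"DEL": 0.5, "LoF": 0.7})
    purging_delta: dict = field(default_factory=lambda: {"JK": 0.3})
    n_adaptive: int = 100
    adaptive_slope: float = 4.0
    env_gradient_var: str = "bio18"
    sweep_pop: str | None = "JK"                 # focal population of the sweep
    sweep_region: tuple = ("Chr3", 1_500_000, 1_700_000)
    sweep_strength: float = 0.95    # fraction of the distance to fixation
    missing_rate: float = 0.002
    na_score_fraction: float = 0.03   # fraction of missense sites without a score
    grid_shape: tuple = (6, 6)
    scenarios: dict = field(default_factory=lambda: {
        "ssp126": 0.5, "ssp245": 1.0, "ssp370": 1.5, "ssp585": 2.0})
    gcm_factors: dict = field(default_factory=lambda: {
        "ACCESS-CM2": 0.9, "BCC-CSM2-MR": 1.0, "CMCC-ESM2": 1.1})

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if sum(self.class_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("effect-class fractions must sum to <= 1")
        for name, d in (("autozygosity", self.autozygosity),
                        ("purging_delta", self.purging_delta),
                        ("suppression", self.suppression)):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{k}]={v} outside [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for p in self.pops:
            if p not in self.lineage_of or p not in self.coords:
                raise ValueError(f"population {p} lacks lineage or coordinates")
        n_coding = int(sum(round(f * self.n_snps) for f in self.class_fractions.values()))
        capacity = sum(
            (length - 2 * _GENE_REGION_START) // (_GENE_CDS_LEN + _GENE_GAP)
            for length in self.chrom_lengths.values()
        ) * _USABLE_CODONS
        if n_coding > capacity:
            raise ValueError(
                f"class mix needs {n_coding} coding SNPs but the gene layout "
                f"only has room for {capacity}")

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    @property
    def samples(self) -> list:
        return [f"{p}_{i:02d}" for p in self.pops for i in range(1, self.n_per_pop + 1)]

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimulatedCohort:
    """Everything a downstream stage needs, plus the generating truth."""

    config: SynthConfig
    gm: GenotypeMatrix
    env: pd.DataFrame                # pop x (lon, lat, bio1..bio19)
    current_grid: ClimateGrid
    future_grids: list               # ClimateGrid per (scenario, model)
    scores: pd.DataFrame             # chrom, pos, alt, score, confidence
    gff_text: str
    fasta: dict                      # chrom -> sequence
    truth_sites: pd.DataFrame        # per-SNP truth
    truth_individuals: pd.DataFrame  # realized autozygosity per sample
    truth_tracts: pd.DataFrame       # placed tract coordinates
    truth_pops: pd.DataFrame         # per-population F / delta / autozygosity
    truth_grid: pd.DataFrame         # displacement vectors per scenario/model


def _balding_nichols(rng, p: np.ndarray, f: float) -> np.ndarray:
    """Draw daughter frequencies around p with divergence f (f=0: identical)."""
    if f <= 0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))


def _logit(p):
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def _env_tables(cfg: SynthConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Population env table, climate-grid cell table and the per-variable
    surface coefficients (smooth bilinear functions of lon/lat)."""
    lons = np.array([cfg.coords[p][0] for p in cfg.pops])
    lats = np.array([cfg.coords[p][1] for p in cfg.pops])
    lon_lo, lon_hi = lons.min() - 0.5, lons.max() + 0.5
    lat_lo, lat_hi = lats.min() - 0.5, lats.max() + 0.5

    def norm(lon, lat):
        return ((lon - lon_lo) / (lon_hi - lon_lo),
                (lat - lat_lo) / (lat_hi - lat_lo))

    coefs = {}
    for v in BIO_VARS:
        coefs[v] = {
            "base": float(rng.uniform(20, 80)),
            "a": float(rng.normal(0, 10)),
            "b": float(rng.normal(0, 10)),
            "c": float(rng.normal(0, 3)),
        }
    # the gradient variable declines smoothly toward the dry north-west
    # interior (equal lon/lat weight gives an even spread of population
    # scores along the gradient)
    coefs[cfg.env_gradient_var] = {"base": 60.0, "a": -14.0, "b": -14.0, "c": 0.0}

    def surface(v, lon, lat):
        u, w = norm(lon, lat)
        k = coefs[v]
        return k["base"] + k["a"] * u + k["b"] * w + k["c"] * u * w

    env = pd.DataFrame(index=list(cfg.pops))
    env["lon"], env["lat"] = lons, lats
    for v in BIO_VARS:
        env[v] = surface(v, lons, lats)

    nx, ny = cfg.grid_shape
    glon, glat = np.meshgrid(np.linspace(lon_lo, lon_hi, nx),
                             np.linspace(lat_lo, lat_hi, ny))
    cells = pd.DataFrame({"lon": glon.ravel(), "lat": glat.ravel()})
    for v in BIO_VARS:
        cells[v] = surface(v, cells["lon"].to_numpy(), cells["lat"].to_numpy())
    return env, cells, coefs


def _layout_sites(cfg: SynthConfig, rng):
    """Assign classes, genomic positions and the toy gene annotation.

    Coding SNPs are packed into consecutive usable codons of tandem
    single-exon genes at the start of each chromosome (every fifth gene on
    the minus strand); noncoding SNPs are scattered outside gene bodies.
    """
    counts = {c: int(round(f * cfg.n_snps)) for c, f in cfg.class_fractions.items()}
    n_coding = sum(counts.values())
    n_noncoding = cfg.n_snps - n_coding
    classes = []
    for c, k in counts.items():
        classes.extend([c] * k)
    rng.shuffle(classes)

    chroms = list(cfg.chrom_lengths)
    weights = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    genes = []          # (gene_id, chrom, start, end, strand)
    site_rows = []      # chrom, pos, ref, alt, true_class, gene
    fasta_patches = {c: [] for c in chroms}  # (pos0, seq) replacements

    # distribute the genes we need across chromosomes proportionally
    n_genes = int(np.ceil(n_coding / _USABLE_CODONS)) if n_coding else 0
    gene_chrom = [chroms[i % len(chroms)] for i in range(n_genes)]
    next_start = {c: _GENE_REGION_START + 1 for c in chroms}
    coding_iter = iter(classes)
    gene_regions = {c: [] for c in chroms}
    remaining = n_coding
    for gi in range(n_genes):
        chrom = gene_chrom[gi]
        start = next_start[chrom]
        end = start + _GENE_CDS_LEN - 1
        next_start[chrom] = end + 1 + _GENE_GAP
        strand = "-" if gi % 5 == 4 else "+"
        gid = f"gene{gi + 1:04d}"
        genes.append((gid, chrom, start, end, strand))
        gene_regions[chrom].append((start, end))
        n_here = min(_USABLE_CODONS, remaining)
        remaining -= n_here
        codons = ["ATG"] + [_FILLER_CODON] * (_GENE_CDS_LEN // 3 - 2) + ["TAA"]
        for slot in range(n_here):
            cls = next(coding_iter)
            codon, within, alt_cds = _CLASS_CODONS[cls]
            codon_i = 1 + slot           # skip ATG
            codons[codon_i] = codon
            cds_idx = codon_i * 3 + within
            if strand == "+":
                pos = start + cds_idx
                ref, alt = codon[within], alt_cds
            else:
                pos = end - cds_idx
                comp = str.maketrans("ACGT", "TGCA")
                ref = codon[within].translate(comp)
                alt = alt_cds.translate(comp)
            site_rows.append((chrom, pos, ref, alt, cls, gid))
        cds_seq = "".join(codons)
        patch = cds_seq if strand == "+" else cds_seq.translate(
            str.maketrans("ACGT", "TGCA"))[::-1]
        fasta_patches[chrom].append((start - 1, patch))

    # noncoding positions outside all gene bodies
    n_per_chrom = rng.multinomial(n_noncoding, weights)
    bases = np.array(list("ACGT"))
    taken = {c: set(r[1] for r in site_rows if r[0] == c) for c in chroms}
    for chrom, k in zip(chroms, n_per_chrom):
        length = cfg.chrom_lengths[chrom]
        lo_blocked = max((e for _, e in gene_regions[chrom]), default=0)
        placed = 0
        while placed < k:
            pos = int(rng.integers(max(lo_blocked + 1, 1), length + 1))
            if pos in taken[chrom]:
                continue
            taken[chrom].add(pos)
            ref, alt = rng.choice(bases, size=2, replace=False)
            site_rows.append((chrom, pos, str(ref), str(alt), "NC", ""))
            placed += 1

    sites = pd.DataFrame(site_rows,
                         columns=["chrom", "pos", "ref", "alt", "true_class", "gene"])
    sites = sites.sort_values(["chrom", "pos"]).reset_index(drop=True)

    gff_lines = ["##gff-version 3"]
    for gid, chrom, start, end, strand in genes:
        gff_lines.append(f"{chrom}\tsynth\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}")
        gff_lines.append(f"{chrom}\tsynth\tCDS\t{start}\t{end}\t.\t{strand}\t0\tParent={gid}")
    gff_text = "\n".join(gff_lines) + "\n"
    return sites, gff_text, fasta_patches


def _build_fasta(cfg: SynthConfig, rng, sites: pd.DataFrame, patches: dict) -> dict:
    """Random background sequence, gene patches applied, then the reference
    base at every noncoding SNP forced to the site's ref allele."""
    fasta = {}
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom, length in cfg.chrom_lengths.items():
        arr = lut[rng.integers(0, 4, size=length)]
        for pos0, patch in patches.get(chrom, []):
            arr[pos0:pos0 + len(patch)] = np.frombuffer(patch.encode(), dtype=np.uint8)
        sub = sites[(sites["chrom"] == chrom) & (sites["true_class"] == "NC")]
        ref_bytes = np.frombuffer("".join(sub["ref"]).encode(), dtype=np.uint8)
        arr[sub["pos"].to_numpy() - 1] = ref_bytes
        fasta[chrom] = arr.tobytes().decode()
    return fasta


def simulate_cohort(cfg: SynthConfig) -> SimulatedCohort:
    """Generate one cohort (genotypes, environment, climate grids,
    annotation, scores) together with its truth tables."""
    rng = np.random.default_rng(cfg.seed)
    env, grid_cells, coefs = _env_tables(cfg, rng)
    sites, gff_text, patches = _layout_sites(cfg, rng)
    fasta = _build_fasta(cfg, rng, sites, patches)
    n = len(sites)
    pops = list(cfg.pops)

    # ancestral (reference) allele frequency; derived = alternate allele
    p_ancestral = rng.uniform(0.05, 0.95, size=n)
    q0 = 1 - p_ancestral
    for cls, strength in cfg.suppression.items():
        mask = (sites["true_class"] == cls).to_numpy()
        q0[mask] *= (1 - strength)

    lineages = sorted(set(cfg.lineage_of.values()))
    q_lin = {lin: _balding_nichols(rng, q0, cfg.lineage_f) for lin in lineages}
    q_pop = {p: _balding_nichols(rng, q_lin[cfg.lineage_of[p]], cfg.pop_f[p])
             for p in pops}

    # adaptive loci: population frequency is an exact logit cline along the
    # gradient (selection strong enough to overwhelm drift at these loci);
    # clinal selection signal is observable at intermediate frequencies, so
    # their midpoint frequency is drawn away from the boundaries
    nc_idx = np.flatnonzero((sites["true_class"] == "NC").to_numpy())
    n_adaptive = min(cfg.n_adaptive, len(nc_idx))
    adaptive_idx = rng.choice(nc_idx, size=n_adaptive, replace=False)
    q0[adaptive_idx] = rng.uniform(0.35, 0.65, size=n_adaptive)
    slopes = np.zeros(n)
    signs = rng.choice([-1.0, 1.0], size=n_adaptive)
    slopes[adaptive_idx] = cfg.adaptive_slope * signs
    grad = env[cfg.env_gradient_var]
    z_env = ((grad - grad.mean()) / grad.std(ddof=0)).to_dict()
    for p in pops:
        shift = slopes[adaptive_idx] * z_env[p]
        q_pop[p][adaptive_idx] = 1 / (1 + np.exp(-(
            _logit(q0[adaptive_idx]) + shift)))

    # planted selective sweep: push the focal population's frequencies most
    # of the way to fixation inside the sweep region (low pi, high Fst)
    sweep_idx = np.array([], dtype=int)
    if cfg.sweep_pop is not None and cfg.sweep_strength > 0:
        sc, ss, se = cfg.sweep_region
        in_region = ((sites["chrom"] == sc) & (sites["pos"] >= ss)
                     & (sites["pos"] <= se)).to_numpy()
        sweep_idx = np.flatnonzero(in_region & ~np.isin(np.arange(n), adaptive_idx))
        q = q_pop[cfg.sweep_pop][sweep_idx]
        target = (q > 0.5).astype(float)
        q_pop[cfg.sweep_pop][sweep_idx] = q + cfg.sweep_strength * (target - q)

    # genotypes: Hardy-Weinberg within population
    samples = cfg.samples
    dosage = np.empty((n, len(samples)), dtype=np.int8)
    pop_of = {}
    col = 0
    cols_of_pop = {}
    for p in pops:
        k = cfg.n_per_pop
        dosage[:, col:col + k] = rng.binomial(
            2, q_pop[p][:, None], size=(n, k)).astype(np.int8)
        cols_of_pop[p] = (col, col + k)
        for s in samples[col:col + k]:
            pop_of[s] = p
        col += k

    # autozygosity tracts: copy one haplotype across sampled intervals
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    chrom_names = list(cfg.chrom_lengths)
    chrom_w = np.array([cfg.chrom_lengths[c] for c in chrom_names], float)
    chrom_w /= chrom_w.sum()
    chrom_site_idx = {c: np.flatnonzero(chrom_arr == c) for c in chrom_names}
    tract_rows = []
    indiv_rows = []
    for p in pops:
        target = cfg.autozygosity.get(p, 0.0)
        lo, hi = cols_of_pop[p]
        for j in range(lo, hi):
            sample = samples[j]
            covered: dict = {c: [] for c in chrom_names}
            total = 0
            while target > 0 and total < target * cfg.genome_length:
                c = chrom_names[int(rng.choice(len(chrom_names), p=chrom_w))]
                length = max(int(rng.exponential(cfg.roh_scale_bp)), 2_000)
                length = min(length, cfg.chrom_lengths[c])
                start = int(rng.integers(1, cfg.chrom_lengths[c] - length + 2))
                end = start + length - 1
                merged = []
                new = (start, end)
                for iv in covered[c]:
                    if iv[1] < new[0] - 1 or iv[0] > new[1] + 1:
                        merged.append(iv)
                    else:
                        new = (min(iv[0], new[0]), max(iv[1], new[1]))
                merged.append(new)
                covered[c] = sorted(merged)
                total = sum(e - s + 1 for ivs in covered.values() for s, e in ivs)
            for c, ivs in covered.items():
                idx_c = chrom_site_idx[c]
                pos_c = pos_arr[idx_c]
                for s, e in ivs:
                    tract_rows.append((sample, c, s, e))
                    inside = idx_c[(pos_c >= s) & (pos_c <= e)]
                    if inside.size:
                        hap = rng.random(inside.size) < q_pop[p][inside]
                        dosage[inside, j] = (2 * hap).astype(np.int8)
            indiv_rows.append((sample, p, total / cfg.genome_length))

    # purging: convert a fraction delta of homozygous-derived DEL genotypes
    # to heterozygous in designated populations
    del_mask = (sites["true_class"] == "DEL").to_numpy()
    for p, delta in cfg.purging_delta.items():
        if delta <= 0 or p not in cols_of_pop:
            continue
        lo, hi = cols_of_pop[p]
        block = dosage[:, lo:hi]
        hom_del = del_mask[:, None] & (block == 2)
        flip = hom_del & (rng.random(block.shape) < delta)
        block[flip] = 1
        dosage[:, lo:hi] = block

    # missingness
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = MISSING

    qual = rng.uniform(25, 500, size=n)
    gm = GenotypeMatrix(
        chrom=sites["chrom"].to_numpy(dtype=object),
        pos=pos_arr.astype(np.int64),
        ref=sites["ref"].to_numpy(dtype=object),
        alt=[(a,) for a in sites["alt"]],
        qual=qual,
        multiallelic=np.zeros(n, dtype=bool),
        dosage=dosage,
        samples=samples,
        pop_of=pop_of,
        contig_lengths=dict(cfg.chrom_lengths),
    )

    # fabricated deleteriousness scores for missense sites
    mis_mask = sites["true_class"].isin(["DEL", "TOL"]).to_numpy()
    mis_idx = np.flatnonzero(mis_mask)
    na_pick = rng.random(mis_idx.size) < cfg.na_score_fraction
    score_rows = []
    for k, i in enumerate(mis_idx):
        cls = sites.loc[i, "true_class"]
        if na_pick[k]:
            score_rows.append((sites.loc[i, "chrom"], int(sites.loc[i, "pos"]),
                               sites.loc[i, "alt"], np.nan, "low"))
        elif cls == "DEL":
            score_rows.append((sites.loc[i, "chrom"], int(sites.loc[i, "pos"]),
                               sites.loc[i, "alt"], float(rng.uniform(0.01, 0.49)),
                               "high"))
        else:
            score_rows.append((sites.loc[i, "chrom"], int(sites.loc[i, "pos"]),
                               sites.loc[i, "alt"], float(rng.uniform(0.5, 0.99)),
                               "high"))
    scores = pd.DataFrame(score_rows,
                          columns=["chrom", "pos", "alt", "score", "confidence"])
    sites = sites.copy()
    sites["score_na"] = False
    sites.loc[mis_idx[na_pick], "score_na"] = True
    sites["adaptive"] = False
    sites.loc[adaptive_idx, "adaptive"] = True
    sites["in_sweep"] = False
    if sweep_idx.size:
        sites.loc[sweep_idx, "in_sweep"] = True
    sites["env_slope"] = slopes
    sites["ancestral"] = sites["ref"]
    effect_of = {"SYN": "SYN", "TOL": "MIS", "DEL": "MIS", "LoF": "LoF", "NC": "noncoding"}
    sites["true_effect"] = sites["true_class"].map(effect_of)
    sites["snp"] = sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)

    # climate grids
    current = ClimateGrid(grid_cells.copy(), epoch="current")
    futures = []
    grid_rows = []
    dir_k = {v: float(rng.choice([-1.0, 1.0])) for v in BIO_VARS}
    sd_k = {v: float(grid_cells[v].std(ddof=0)) for v in BIO_VARS}
    for scen, scale in cfg.scenarios.items():
        for gcm, factor in cfg.gcm_factors.items():
            fut = grid_cells.copy()
            for v in BIO_VARS:
                delta = 0.5 * scale * factor * dir_k[v] * sd_k[v]
                fut[v] = fut[v] + delta
                grid_rows.append((scen, gcm, v, delta))
            futures.append(ClimateGrid(fut, epoch="future", scenario=scen, model=gcm))
    truth_grid = pd.DataFrame(grid_rows,
                              columns=["scenario", "model", "variable", "delta"])

    truth_pops = pd.DataFrame({
        "population": pops,
        "lineage": [cfg.lineage_of[p] for p in pops],
        "pop_f": [cfg.pop_f[p] for p in pops],
        "autozygosity": [cfg.autozygosity.get(p, 0.0) for p in pops],
        "purging_delta": [cfg.purging_delta.get(p, 0.0) for p in pops],
    }).set_index("population")

    return SimulatedCohort(
        config=cfg,
        gm=gm,
        env=env,
        current_grid=current,
        future_grids=futures,
        scores=scores,
        gff_text=gff_text,
        fasta=fasta,
        truth_sites=sites,
        truth_individuals=pd.DataFrame(
            indiv_rows, columns=["sample", "population", "realized_autozygosity"]),
        truth_tracts=pd.DataFrame(
            tract_rows, columns=["sample", "chrom", "start", "end"]),
        truth_pops=truth_pops,
        truth_grid=truth_grid,
    )


def write_fixture_bundle(cohort: SimulatedCohort, outdir, force: bool = False) -> dict:
    """Write the cohort as plain-text files loadable by every pipeline stage.

    Produces VCF, popmap TSV, environment CSV, climate-grid CSVs, GFF3,
    FASTA, score TSV, truth JSON and a manifest with the seed, config hash
    and per-file SHA256. Re-running with the same seed reproduces
    byte-identical payloads.
    """
    from .genotype_io import write_vcf

    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    write_vcf(cohort.gm, out / "cohort.vcf")
    with open(out / "popmap.tsv", "w") as fh:
        for s in cohort.gm.samples:
            fh.write(f"{s}\t{cohort.gm.pop_of[s]}\n")
    cohort.env.to_csv(out / "env.csv", index_label="population")
    cohort.current_grid.cells.to_csv(out / "climate_current.csv", index=False)
    for g in cohort.future_grids:
        g.cells.to_csv(out / f"climate_{g.scenario}_{g.model}.csv", index=False)
    with open(out / "genes.gff3", "w") as fh:
        fh.write(cohort.gff_text)
    with open(out / "ref.fa", "w") as fh:
        for chrom, seq in cohort.fasta.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    cohort.scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    truth = {
        "sites": cohort.truth_sites.replace({np.nan: None}).to_dict("records"),
        "individuals": cohort.truth_individuals.to_dict("records"),
        "tracts": cohort.truth_tracts.to_dict("records"),
        "populations": cohort.truth_pops.reset_index().to_dict("records"),
        "grid_displacements": cohort.truth_grid.to_dict("records"),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh)

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": cohort.config.seed,
        "config_hash": cohort.config.config_hash(),
        "n_snps": int(cohort.gm.n_sites),
        "n_samples": int(cohort.gm.n_samples),
        "files": {
            f: hashlib.sha256((out / f).read_bytes()).hexdigest() for f in files
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
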