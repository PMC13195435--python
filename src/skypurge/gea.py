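"""Genotype-environment association scans.

Two complementary detectors are fitted as model objects:

* :class:`LatentFactorModel` — per-SNP univariate linear association between
  dosage and an environmental variable, with K latent factors (principal
  components of the environment-residualized genotype matrix) absorbing
  population structure, and genomic-inflation-factor calibration of the
  p-values (lambda = median chi2 / 0.456).
* :class:`RdaModel` — redundancy analysis: constrained ordination of the
  centered genotype matrix on the standardized environmental predictors;
  SNPs whose loadings sit more than ``sd_cutoff`` standard deviations from
  an axis mean are flagged as outliers.

Core candidates are the SNPs flagged by both methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix

__all__ = [
    "select_env_variables", "standardize_env", "impute_dosage",
    "LatentFactorModel", "LfmmResult", "RdaModel", "RdaResult",
    "intersect_core_snps",
]

CHI2_1_MEDIAN = float(stats.chi2.median(df=1))   # 0.4549...


def standardize_env(env: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean / unit-variance standardization of every column."""
    if env.isna().any().any():
        raise ValueError("environment table contains missing values")
    sd = env.std(ddof=0)
    if (sd == 0).any():
        warnings.warn(f"constant environment variables: {list(sd.index[sd == 0])}")
    return (env - env.mean()) / sd.replace(0, 1)


def select_env_variables(env: pd.DataFrame, importance: dict | pd.Series,
                         r_max: float = 0.8) -> list:
    """Greedy correlation filter: walk variables by descending importance,
    keeping one iff its |Pearson r| with every kept variable is < r_max.
    Constant variables are excluded with a warning."""
    imp = pd.Series(importance)
    order = [v for v in imp.sort_values(ascending=False).index if v in env.columns]
    kept: list = []
    corr = env[order].corr().abs()
    for v in order:
        if env[v].std(ddof=0) == 0:
            warnings.warn(f"variable {v} is constant; excluded")
            continue
        if all(corr.loc[v, k] < r_max for k in kept):
            kept.append(v)
    return kept


def impute_dosage(gm_or_array, min_call_rate: float | None = None):
    """Mean-impute missing dosages; optionally subset to sites with call
    rate >= ``min_call_rate`` first. Returns (sites x samples float array,
    kept site index array)."""
    if isinstance(gm_or_array, GenotypeMatrix):
        dos = gm_or_array.dosage
    else:
        dos = np.asarray(gm_or_array)
    called = dos != MISSING
    keep = np.arange(dos.shape[0])
    if min_call_rate is not None:
        ok = called.mean(axis=1) >= min_call_rate
        keep = np.flatnonzero(ok)
        dos = dos[ok]
        called = called[ok]
    d = dos.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(called, d, 0).sum(axis=1) / np.maximum(called.sum(axis=1), 1)
    d = np.where(called, d, means[:, None])
    return d, keep


# ---------------------------------------------------------------------------
# LFMM
# ---------------------------------------------------------------------------

@dataclass
class LfmmResult:
    """Per-(SNP, variable) association results from a fitted latent-factor
    model."""

    table: pd.DataFrame          # snp, variable, beta, t, p_raw, p
    gif: dict                    # variable -> genomic inflation factor
    k: int
    p_threshold: float = 1e-5

    def significant(self) -> pd.DataFrame:
        """SNPs significant for at least one variable (calibrated p <=
        threshold), with per-variable provenance."""
        hits = self.table[self.table["p"] <= self.p_threshold]
        if not len(hits):
            return pd.DataFrame(columns=["snp", "variables", "min_p"])
        g = hits.groupby("snp")
        return pd.DataFrame({
            "snp": list(g.groups),
            "variables": [sorted(sub["variable"]) for _, sub in g],
            "min_p": g["p"].min().to_numpy(),
        })

    def snp_set(self) -> set:
        return set(self.significant()["snp"])

    def summary(self) -> str:
        n_sig = len(self.snp_set())
        gif = ", ".join(f"{v}={g:.3f}" for v, g in self.gif.items())
        return (f"LFMM scan: K={self.k}, {self.table['snp'].nunique()} SNPs x "
                f"{self.table['variable'].nunique()} variables; "
                f"{n_sig} SNPs with p <= {self.p_threshold:g}; GIF {gif}")


class LatentFactorModel:
    """Latent-factor association model for one genotype panel.

    Parameters
    ----------
    dosage : (n_sites, n_samples) array or GenotypeMatrix (missing dosages
        are mean-imputed; typically pre-filtered to call rate >= 0.99).
    env : DataFrame of environmental variables, one row per sample in
        column order matching the dosage columns.
    k : number of latent factors (defaults to the number of source
        populations when built via from_genotypes).
    """

    def __init__(self, dosage, env: pd.DataFrame, k: int,
                 snp_ids: list | None = None):
        d, _ = impute_dosage(dosage)
        self.y = d.T                                  # samples x snps
        self.env = standardize_env(env.reset_index(drop=True))
        if self.y.shape[0] != len(self.env):
            raise ValueError("sample count mismatch between dosage and env")
        n = self.y.shape[0]
        if k < 0 or k >= min(n, self.y.shape[1]):
            raise ValueError(f"K={k} must satisfy 0 <= K < min(samples, SNPs)")
        self.k = k
        self.snp_ids = list(snp_ids) if snp_ids is not None else list(range(self.y.shape[1]))

    @classmethod
    def from_genotypes(cls, gm: GenotypeMatrix, env: pd.DataFrame,
                       k: int | None = None, min_call_rate: float = 0.99
                       ) -> "LatentFactorModel":
        d, kept = impute_dosage(gm, min_call_rate=min_call_rate)
        if k is None:
            k = len(gm.populations)
        ids = [f"{gm.chrom[i]}:{gm.pos[i]}" for i in kept]
        env_rows = env.loc[[gm.pop_of[s] for s in gm.samples]] \
            if set(env.index) >= set(gm.pop_of.values()) else env
        return cls(d, env_rows.reset_index(drop=True), k, snp_ids=ids)

    def _latent_factors(self) -> np.ndarray:
        """Left singular vectors of the genotype matrix after removing the
        environmental projection (ridge-free least squares)."""
        yc = self.y - self.y.mean(axis=0)
        if self.k == 0:
            return np.zeros((yc.shape[0], 0))
        x = self.env.to_numpy(float)
        beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
        resid = yc - x @ beta
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        return u[:, : self.k]

    def fit(self, p_threshold: float = 1e-5, calibrate: bool = True) -> LfmmResult:
        n = self.y.shape[0]
        u = self._latent_factors()
        rows = []
        gifs = {}
        yc = self.y - self.y.mean(axis=0)
        for var in self.env.columns:
            x = np.column_stack([np.ones(n), self.env[var].to_numpy(float), u])
            df = n - x.shape[1]
            if df <= 0:
                raise ValueError("not enough samples for the requested K")
            xtx_inv = np.linalg.pinv(x.T @ x)
            beta = xtx_inv @ x.T @ self.y
            resid = self.y - x @ beta
            sigma2 = (resid ** 2).sum(axis=0) / df
            se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
            t = beta[1] / se
            p_raw = 2 * stats.t.sf(np.abs(t), df)
            z2 = stats.chi2.isf(np.clip(p_raw, 1e-300, 1.0), df=1)
            lam = float(np.median(z2) / CHI2_1_MEDIAN) if calibrate else 1.0
            lam = max(lam, 1e-12)
            p_cal = stats.chi2.sf(z2 / lam, df=1) if calibrate else p_raw
            gifs[var] = lam
            rows.append(pd.DataFrame({
                "snp": self.snp_ids,
                "variable": var,
                "beta": beta[1],
                "t": t,
                "p_raw": p_raw,
                "p": p_cal,
            }))
        table = pd.concat(rows, ignore_index=True)
        return LfmmResult(table=table, gif=gifs, k=self.k, p_threshold=p_threshold)


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

@dataclass
class RdaResult:
    loadings: pd.DataFrame       # snp x axis loadings
    axis_variance: np.ndarray    # fraction of total genotype variance per axis
    outliers: pd.DataFrame       # snp, axes (list), max_abs_z
    sd_cutoff: float

    def snp_set(self) -> set:
        return set(self.outliers["snp"])

    def summary(self) -> str:
        var = ", ".join(f"RDA{i + 1}={v:.3f}" for i, v in enumerate(self.axis_variance))
        return (f"RDA scan: {len(self.loadings)} SNPs, {len(self.axis_variance)} "
                f"constrained axes ({var}); {len(self.outliers)} outliers at "
                f"|z| > {self.sd_cutoff}")


class RdaModel:
    """Redundancy analysis of a genotype matrix on environmental predictors."""

    def __init__(self, dosage, env: pd.DataFrame, snp_ids: list | None = None):
        d, _ = impute_dosage(dosage)
        self.y = d.T
        self.env = standardize_env(env.reset_index(drop=True))
        if self.y.shape[0] != len(self.env):
            raise ValueError("sample count mismatch between dosage and env")
        self.snp_ids = list(snp_ids) if snp_ids is not None else list(range(self.y.shape[1]))

    @classmethod
    def from_genotypes(cls, gm: GenotypeMatrix, env: pd.DataFrame,
                       min_call_rate: float = 0.99) -> "RdaModel":
        d, kept = impute_dosage(gm, min_call_rate=min_call_rate)
        ids = [f"{gm.chrom[i]}:{gm.pos[i]}" for i in kept]
        env_rows = env.loc[[gm.pop_of[s] for s in gm.samples]] \
            if set(env.index) >= set(gm.pop_of.values()) else env
        return cls(d, env_rows.reset_index(drop=True), snp_ids=ids)

    def fit(self, n_axes: int | None = None, sd_cutoff: float = 3.5,
            scale_genotypes: bool = False) -> RdaResult:
        """Constrained ordination on centered (by default unscaled) dosages,
        matching the usual landscape-genomics RDA protocol; strongly
        differentiated clinal loci then stand out by both correlation and
        variance. ``scale_genotypes`` switches to correlation-based RDA."""
        x = self.env.to_numpy(float)
        if n_axes is None:
            n_axes = x.shape[1]
        if n_axes > x.shape[1]:
            raise ValueError("n_axes cannot exceed the number of env variables")
        yc = self.y - self.y.mean(axis=0)
        if scale_genotypes:
            sd = yc.std(axis=0)
            yc = yc / np.where(sd == 0, 1, sd)
        beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
        fitted = x @ beta
        _, s, vt = np.linalg.svd(fitted, full_matrices=False)
        k = min(n_axes, len(s))
        total_var = (yc ** 2).sum()
        axis_var = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
        # SNP scores: right singular vectors scaled by singular values
        loadings = vt[:k].T * s[:k]
        cols = [f"RDA{i + 1}" for i in range(k)]
        ldf = pd.DataFrame(loadings, columns=cols)
        ldf.insert(0, "snp", self.snp_ids)
        mu = loadings.mean(axis=0)
        sd = loadings.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1, sd)
        z = (loadings - mu) / sd
        flag = np.abs(z) > sd_cutoff
        out_rows = []
        for i in np.flatnonzero(flag.any(axis=1)):
            axes = [cols[a] for a in np.flatnonzero(flag[i])]
            out_rows.append((self.snp_ids[i], axes, float(np.abs(z[i]).max())))
        outliers = pd.DataFrame(out_rows, columns=["snp", "axes", "max_abs_z"])
        return RdaResult(loadings=ldf, axis_variance=axis_var,
                         outliers=outliers, sd_cutoff=sd_cutoff)


def intersect_core_snps(lfmm: LfmmResult, rda: RdaResult) -> pd.DataFrame:
    """Core candidates: SNPs flagged by both LFMM and RDA, with merged
    provenance (LFMM variables and RDA axes)."""
    lf = lfmm.significant().set_index("snp")
    rd = rda.outliers.set_index("snp")
    if len(lf) and len(rd):
        universe_l = set(lfmm.table["snp"])
        universe_r = set(rda.loadings["snp"])
        if universe_l.isdisjoint(universe_r):
            raise ValueError("LFMM and RDA were run on disjoint SNP universes")
    core = sorted(set(lf.index) & set(rd.index))
    return pd.DataFrame({
        "snp": core,
        "lfmm_variables": [lf.loc[s, "variables"] for s in core],
        "lfmm_min_p": [lf.loc[s, "min_p"] for s in core],
        "rda_axes": [rd.loc[s, "axes"] for s in core],
        "rda_max_abs_z": [rd.loc[s, "max_abs_z"] for s in core],
    })
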