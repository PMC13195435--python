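"""Gradient-forest genomic offset.

A random-forest regression is fitted per SNP (allele frequency as response,
environmental variables as predictors). Every split's impurity reduction is
attributed to its predictor at its split value; importances are weighted by
the SNP's out-of-bag R^2 (negative values truncated to zero), binned along
each predictor's observed range, and accumulated into nondecreasing
cumulative-importance step functions. Environmental vectors mapped through
these functions live in "genomic climate space"; the genomic offset of a
grid cell is the Euclidean distance between its transformed current and
future climates. Offsets are computed per climate model and scenario, then
averaged across models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ClimateGrid", "GradientForestModel", "GradientForestResult", "OffsetGrid",
    "fit_gradient_forest", "transform_env", "compute_offset", "average_offsets",
]

CELL_KEY = ["lon", "lat"]


@dataclass
class ClimateGrid:
    """Raster of climate values: one row per cell with lon, lat and the
    bioclimatic variables; labelled with epoch/scenario/model."""

    cells: pd.DataFrame
    epoch: str = "current"           # current | future
    scenario: str = ""               # e.g. ssp126..ssp585
    model: str = ""                  # GCM label

    def __post_init__(self) -> None:
        for c in CELL_KEY:
            if c not in self.cells.columns:
                raise ValueError(f"climate grid needs a {c!r} column")
        self.cells = self.cells.reset_index(drop=True)

    @property
    def variables(self) -> list:
        return [c for c in self.cells.columns if c not in CELL_KEY]

    def registry(self) -> pd.DataFrame:
        return self.cells[CELL_KEY]


@dataclass
class _StepFunction:
    """Nondecreasing cumulative-importance step function for one predictor."""

    positions: np.ndarray = field(default_factory=lambda: np.array([]))
    cumulative: np.ndarray = field(default_factory=lambda: np.array([]))

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if len(self.positions) == 0:
            return np.zeros_like(x)
        idx = np.searchsorted(self.positions, x, side="right")
        padded = np.concatenate(([0.0], self.cumulative))
        return padded[idx]

    @property
    def maximum(self) -> float:
        return float(self.cumulative[-1]) if len(self.cumulative) else 0.0


@dataclass
class GradientForestResult:
    """Fitted per-predictor cumulative-importance functions."""

    functions: dict                  # predictor -> _StepFunction
    predictor_importance: pd.Series  # total weighted importance per predictor
    snp_r2: pd.Series                # out-of-bag R^2 per SNP (pre-truncation)
    n_trees: int
    n_bins: int
    seed: int

    @property
    def predictors(self) -> list:
        return list(self.functions)

    def transform(self, values) -> np.ndarray:
        return transform_env(self, values)

    def summary(self) -> str:
        tot = self.predictor_importance.sum()
        parts = ", ".join(
            f"{k}={v / tot:.2f}" if tot > 0 else f"{k}=0"
            for k, v in self.predictor_importance.sort_values(ascending=False).items()
        )
        pos_r2 = (self.snp_r2 > 0).sum()
        return (f"gradient forest: {len(self.snp_r2)} SNPs ({pos_r2} with "
                f"positive OOB R^2), {self.n_trees} trees/SNP; "
                f"importance shares: {parts}")


class GradientForestModel:
    """Gradient forest over a population x SNP allele-frequency table.

    Parameters
    ----------
    freqs : DataFrame, one row per population/unit, one column per SNP.
    env : DataFrame of environmental predictors aligned row-wise with freqs.
    """

    def __init__(self, freqs: pd.DataFrame, env: pd.DataFrame):
        if len(freqs) != len(env):
            raise ValueError("freqs and env must have the same number of rows")
        if len(freqs) < 2:
            raise ValueError("need at least two units to fit")
        self.freqs = freqs.reset_index(drop=True)
        self.env = env.reset_index(drop=True)

    def fit(self, n_trees: int = 500, n_bins: int = 200,
            seed: int = 0) -> GradientForestResult:
        x = self.env.to_numpy(float)
        predictors = list(self.env.columns)
        n_pred = len(predictors)
        split_imp: dict = {p: ([], []) for p in predictors}  # positions, importances
        r2s = {}
        rng = np.random.default_rng(seed)
        informative = 0
        for snp in self.freqs.columns:
            y = self.freqs[snp].to_numpy(float)
            if np.ptp(y) == 0:
                r2s[snp] = 0.0
                continue
            # greedy split choice (all predictors tried at each node) keeps
            # importance attribution on the true driver instead of crediting
            # randomly forced predictors
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=None,
                oob_score=True,
                bootstrap=True,
                random_state=int(rng.integers(0, 2 ** 31 - 1)),
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # small-n OOB warnings
                rf.fit(x, y)
                oob = rf.oob_score_ if hasattr(rf, "oob_score_") else 0.0
            r2s[snp] = float(oob) if np.isfinite(oob) else 0.0
            weight = max(r2s[snp], 0.0)
            if weight == 0.0:
                continue
            informative += 1
            pos_list: dict = {p: [] for p in predictors}
            imp_list: dict = {p: [] for p in predictors}
            total_decrease = 0.0
            for est in rf.estimators_:
                t = est.tree_
                internal = t.children_left != -1
                w = t.weighted_n_node_samples
                dec = np.zeros(t.node_count)
                left, right = t.children_left, t.children_right
                idx = np.flatnonzero(internal)
                dec[idx] = (
                    w[idx] * t.impurity[idx]
                    - w[left[idx]] * t.impurity[left[idx]]
                    - w[right[idx]] * t.impurity[right[idx]]
                )
                dec = np.maximum(dec, 0.0)
                for i in idx:
                    p = predictors[t.feature[i]]
                    pos_list[p].append(t.threshold[i])
                    imp_list[p].append(dec[i])
            total_decrease = sum(sum(v) for v in imp_list.values())
            if total_decrease <= 0:
                continue
            for p in predictors:
                if imp_list[p]:
                    split_imp[p][0].extend(pos_list[p])
                    split_imp[p][1].extend(
                        np.asarray(imp_list[p]) * weight / total_decrease
                    )
        if informative == 0:
            warnings.warn("no SNP had positive out-of-bag R^2; all cumulative "
                          "importance functions are zero")
        functions = {}
        totals = {}
        for p in predictors:
            pos = np.asarray(split_imp[p][0], dtype=float)
            imp = np.asarray(split_imp[p][1], dtype=float)
            totals[p] = float(imp.sum())
            if len(pos) == 0:
                functions[p] = _StepFunction()
                continue
            lo, hi = self.env[p].min(), self.env[p].max()
            edges = np.linspace(lo, hi, n_bins + 1)
            which = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, n_bins - 1)
            binned = np.bincount(which, weights=imp, minlength=n_bins)
            nonzero = np.flatnonzero(binned > 0)
            positions = edges[nonzero + 1]           # step at the bin's upper edge
            cumulative = np.cumsum(binned[nonzero])
            functions[p] = _StepFunction(positions, cumulative)
        return GradientForestResult(
            functions=functions,
            predictor_importance=pd.Series(totals),
            snp_r2=pd.Series(r2s),
            n_trees=n_trees, n_bins=n_bins, seed=seed,
        )


def fit_gradient_forest(freqs: pd.DataFrame, env: pd.DataFrame,
                        n_trees: int = 500, n_bins: int = 200,
                        seed: int = 0) -> GradientForestResult:
    """Convenience wrapper around :class:`GradientForestModel`."""
    return GradientForestModel(freqs, env).fit(n_trees=n_trees, n_bins=n_bins,
                                               seed=seed)


def transform_env(model: GradientForestResult, values) -> np.ndarray:
    """Map environmental values through the cumulative-importance functions.

    ``values`` may be a Series/dict (one vector) or a DataFrame (one row per
    cell); columns must match the model's predictors. Values below a
    predictor's first split map to 0, above its last split to the function's
    maximum.
    """
    if isinstance(values, (pd.Series, dict)):
        values = pd.DataFrame([values])
        squeeze = True
    else:
        squeeze = False
    missing = [p for p in model.predictors if p not in values.columns]
    if missing:
        raise ValueError(f"missing predictors: {missing}")
    unknown = [c for c in values.columns if c not in model.predictors
               and c not in CELL_KEY]
    if unknown:
        raise ValueError(f"unknown variables: {unknown}")
    out = np.column_stack([
        model.functions[p](values[p].to_numpy(float)) for p in model.predictors
    ])
    return out[0] if squeeze else out


@dataclass
class OffsetGrid:
    """Per-cell genomic offset for one (model, scenario) combination."""

    cells: pd.DataFrame              # lon, lat, offset
    scenario: str = ""
    model: str = ""

    def values(self) -> np.ndarray:
        return self.cells["offset"].to_numpy(float)


def compute_offset(model: GradientForestResult, current: ClimateGrid,
                   future: ClimateGrid) -> OffsetGrid:
    """Per-cell Euclidean distance between transformed current and future
    climates; grids must share an identical cell registry."""
    if not current.registry().equals(future.registry()):
        raise ValueError("current and future grids have different cell registries")
    cur = transform_env(model, current.cells)
    fut = transform_env(model, future.cells)
    offset = np.sqrt(((fut - cur) ** 2).sum(axis=1))
    cells = current.registry().copy()
    cells["offset"] = offset
    return OffsetGrid(cells=cells, scenario=future.scenario, model=future.model)


def average_offsets(grids: list) -> OffsetGrid:
    """Cell-wise arithmetic mean of offsets across climate models for one
    scenario; alignment is strict (no silent NaN propagation)."""
    if not grids:
        raise ValueError("no offset grids to average")
    scenarios = {g.scenario for g in grids}
    if len(scenarios) != 1:
        raise ValueError(f"mismatched scenarios: {sorted(scenarios)}")
    ref = grids[0].cells[CELL_KEY]
    stack = []
    for g in grids:
        if not g.cells[CELL_KEY].equals(ref):
            raise ValueError("offset grids have different cell registries")
        v = g.values()
        if np.isnan(v).any():
            raise ValueError(f"offset grid for model {g.model!r} has missing cells")
        stack.append(v)
    cells = ref.copy()
    cells["offset"] = np.mean(stack, axis=0)
    return OffsetGrid(cells=cells, scenario=grids[0].scenario,
                      model="+".join(g.model for g in grids))
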