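"""Pagel-style tests of correlated evolution between two binary traits.

Two binary traits x and y evolve jointly as a 4-state chain on
``(x, y) in {00, 01, 10, 11}`` (state index ``2x + y``); simultaneous
change of both traits is forbidden.  The battery fits eight models —
independent vs three dependency structures ("x depends on y", "y depends
on x", mutual), each under equal-rates and all-rates-different — and ranks
them by AIC, with a likelihood-ratio test for the nested mutual-ARD vs
independent-ARD comparison as a companion statistic.

"x depends on y" means x's transition rates vary with y's current state
while y's rates are functions of y alone.  Under equal rates, forward and
backward rates of a trait are equal within each conditioning state.
Parameter counts: independent ER/ARD = 2/4, one-way dependence = 3/6,
mutual = 4/8.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .mk_hmm import (
    ALL_RATES_DIFFERENT,
    EQUAL_RATES,
    FitResult,
    MkHmmModel,
    fit_ml,
    model_select,
)
from .phylo_core import PhyloTree, drop_tips

__all__ = [
    "PagelModelSpec",
    "PagelResult",
    "DEPENDENCIES",
    "build_pagel_model",
    "fit_battery",
    "lr_test",
]

DEPENDENCIES = ("independent", "x_on_y", "y_on_x", "mutual")
RATE_SCHEMES = (EQUAL_RATES, ALL_RATES_DIFFERENT)

#: delta-AIC margin for calling one dependency structure better supported
SUPPORT_DELTA_AIC = 2.0


@dataclass(frozen=True)
class PagelModelSpec:
    dependency: str
    rates: str

    def __post_init__(self):
        if self.dependency not in DEPENDENCIES:
            raise ValueError(f"unknown dependency {self.dependency!r}")
        if self.rates not in RATE_SCHEMES:
            raise ValueError(f"unknown rate scheme {self.rates!r}")

    @property
    def name(self) -> str:
        cat = "ER" if self.rates == EQUAL_RATES else "ARD"
        return f"{self.dependency}/{cat}"


def build_pagel_model(spec: PagelModelSpec, root_prior: str = "flat") -> MkHmmModel:
    """Index matrix for the 4-state two-trait chain under the spec.

    Reuses the generic CTMC machinery: the result is an ordinary
    :class:`MkHmmModel` with four observed states and no hidden layer.
    """
    x_dep = spec.dependency in ("x_on_y", "mutual")
    y_dep = spec.dependency in ("y_on_x", "mutual")
    ard = spec.rates == ALL_RATES_DIFFERENT

    im = np.zeros((4, 4), dtype=np.int64)
    param_of: dict = {}

    def param(key) -> int:
        if key not in param_of:
            param_of[key] = len(param_of) + 1
        return param_of[key]

    for x in (0, 1):
        for y in (0, 1):
            s = 2 * x + y
            # x changes: (x,y) -> (1-x, y)
            cond = y if x_dep else None
            direction = (x, 1 - x) if ard else "sym"
            im[s, 2 * (1 - x) + y] = param(("x", cond, direction))
            # y changes: (x,y) -> (x, 1-y)
            cond = x if y_dep else None
            direction = (y, 1 - y) if ard else "sym"
            im[s, 2 * x + (1 - y)] = param(("y", cond, direction))

    return MkHmmModel(
        n_obs=4,
        n_hidden=1,
        index_matrix=im,
        constraint=spec.rates,
        root_prior=root_prior,
        name=spec.name,
    )


@dataclass
class PagelResult:
    """Outcome of the eight-model battery on one trait pair."""

    fits: dict  # name -> FitResult
    table: pd.DataFrame
    best: str
    lr_statistic: float
    lr_df: int
    lr_p: float
    verdict: str
    n_tips_used: int
    n_dropped: int

    def to_dict(self) -> dict:
        return {
            "models": {name: f.to_dict() for name, f in self.fits.items()},
            "best": self.best,
            "lr_statistic": self.lr_statistic,
            "lr_df": self.lr_df,
            "lr_p": self.lr_p,
            "verdict": self.verdict,
            "n_tips_used": self.n_tips_used,
            "n_dropped": self.n_dropped,
        }


def lr_test(dep: FitResult, indep: FitResult) -> tuple:
    """Likelihood-ratio test of a dependent model against its nested
    independent counterpart: statistic ``2(logL_dep - logL_indep)`` floored
    at zero, df = difference in parameter count, p from chi-square."""
    df = dep.k - indep.k
    if df <= 0:
        raise ValueError("models are not a nested dependent/independent pair")
    stat = max(0.0, 2.0 * (dep.logL - indep.logL))
    p = float(chi2.sf(stat, df))
    return stat, df, p


def _combine_tips(tree: PhyloTree, x, y):
    """4-state tip vector on the tips observed for both traits."""
    shared = {}
    for lab in tree.tip_labels:
        xv = x.get(lab)
        yv = y.get(lab)
        if xv is None or yv is None:
            continue
        if isinstance(xv, float) and np.isnan(xv):
            continue
        if isinstance(yv, float) and np.isnan(yv):
            continue
        shared[lab] = 2 * int(xv) + int(yv)
    return shared


def fit_battery(
    tree: PhyloTree,
    x,
    y,
    seed: int = 0,
    n_restarts: int = 3,
    root_prior: str = "flat",
) -> PagelResult:
    """Fit the eight-model battery and rank by AIC.

    Tips lacking either trait are dropped pairwise (counts recorded).
    Dependent ARD (ER) fits are warm-started from the independent ARD (ER)
    estimates — the independent model is nested in every dependent one, so
    this guarantees the dependent fit starts at the independent optimum.
    """
    shared = _combine_tips(tree, x, y)
    n_dropped = tree.n_tips - len(shared)
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} tips carry both traits; need >= 4")
    if len(shared) < 20:
        warnings.warn(f"only {len(shared)} shared tips; low power")
    work_tree = (
        drop_tips(tree, [t for t in tree.tip_labels if t not in shared])
        if n_dropped
        else tree
    )

    fits: dict = {}
    for i, scheme in enumerate(RATE_SCHEMES):
        indep_spec = PagelModelSpec("independent", scheme)
        indep_model = build_pagel_model(indep_spec, root_prior)
        indep_fit = fit_ml(
            work_tree, shared, indep_model, n_restarts=n_restarts, seed=seed + i
        )
        fits[indep_spec.name] = indep_fit
        for dep in ("x_on_y", "y_on_x", "mutual"):
            spec = PagelModelSpec(dep, scheme)
            model = build_pagel_model(spec, root_prior)
            start = _nested_start(indep_model, indep_fit.rates, model)
            fits[spec.name] = fit_ml(
                work_tree,
                shared,
                model,
                n_restarts=n_restarts,
                seed=seed + 10 + i,
                start=start,
            )

    table = model_select(list(fits.values()))
    best = str(table.iloc[0]["model"])

    dep_ard = fits["mutual/ARD"]
    indep_ard = fits["independent/ARD"]
    stat, df, p = lr_test(dep_ard, indep_ard)

    best_dep_aic = min(
        f.AIC for name, f in fits.items() if not name.startswith("independent")
    )
    best_indep_aic = min(
        f.AIC for name, f in fits.items() if name.startswith("independent")
    )
    if best_indep_aic - best_dep_aic >= SUPPORT_DELTA_AIC:
        verdict = "dependent evolution better supported"
    elif best_dep_aic - best_indep_aic >= SUPPORT_DELTA_AIC:
        verdict = "independent evolution better supported"
    else:
        verdict = "similar support for dependent and independent evolution"

    return PagelResult(
        fits=fits,
        table=table,
        best=best,
        lr_statistic=stat,
        lr_df=df,
        lr_p=p,
        verdict=verdict,
        n_tips_used=len(shared),
        n_dropped=n_dropped,
    )


def _nested_start(indep_model: MkHmmModel, indep_rates, dep_model: MkHmmModel):
    """Map independent-model rates onto a dependent model's parameters."""
    Q = indep_model.rate_matrix(indep_rates)
    start = np.zeros(dep_model.n_params)
    im = dep_model.index_matrix
    for i in range(4):
        for j in range(4):
            if im[i, j] > 0:
                start[im[i, j] - 1] = max(Q[i, j], 1e-9)
    return start
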