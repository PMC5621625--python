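"""Adjusted sequential attributable fractions by permutation averaging.

A risk factor's attributable fraction (AF) is (O - E_S)/O: observed cases
minus the cases expected under counterfactual removal of the factor, over
observed cases.  Expected cases come from posterior predicted probabilities
with the factor's design columns (main effect and every interaction touching
it) set to their unexposed reference.  Sequential AFs depend on the order in
which factors are removed, so each factor's final AF is the average of its
sequential AF over all removal orderings — its Shapley value, which makes the
per-factor AFs sum exactly to the combined AF of removing everything.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DesignMatrix, Posterior

__all__ = [
    "Factor",
    "resolve_factors",
    "predict_counterfactual",
    "attributable_fraction",
    "sequential_af",
    "AFReport",
]

MAX_FACTORS = 6


@dataclass(frozen=True)
class Factor:
    """A removable risk factor: a design column and its reference value."""

    name: str
    column: str
    reference: float = 0.0


#: built-in factor names -> design column
_KNOWN_FACTORS = {
    "recent": "recent_conflict",
    "longer": "longer_conflict",
    "evi": "evi",
}


def resolve_factors(design: DesignMatrix, names,
                    evi_reference_quantile: float = 0.9) -> list[Factor]:
    """Turn factor names into :class:`Factor` objects bound to this design.

    Binary indicators get reference 0 (unexposed).  The continuous EVI factor
    is removed *to* a protective reference — the sample upper quantile of the
    (possibly standardised) EVI column — because low vegetation is the hazard
    and no unexposed zero state exists for a continuous field.
    """
    factors = []
    for name in names:
        if isinstance(name, Factor):
            factors.append(name)
            continue
        column = _KNOWN_FACTORS.get(name, name)
        if column not in design.columns:
            raise KeyError(f"factor {name!r}: no design column {column!r}")
        if column == "evi":
            ref = float(np.quantile(design.col("evi"), evi_reference_quantile))
        else:
            ref = 0.0
        factors.append(Factor(name=name, column=column, reference=ref))
    return factors


def _counterfactual_X(design: DesignMatrix, removed: list[Factor]) -> np.ndarray:
    """Design copy with removed factors at reference and interactions rebuilt."""
    X = design.X.copy()
    col_idx = {c: i for i, c in enumerate(design.columns)}
    removed_cols = set()
    for f in removed:
        X[:, col_idx[f.column]] = f.reference
        removed_cols.add(f.column)
    for name, (pa, pb, ca, cb) in design.interactions.items():
        if name not in col_idx:
            continue
        if pa in removed_cols or pb in removed_cols:
            X[:, col_idx[name]] = (X[:, col_idx[pa]] - ca) * (X[:, col_idx[pb]] - cb)
    return X


def explained_variation(posterior: Posterior, design: DesignMatrix) -> float:
    """Latent-scale variance-partition coefficient of the fixed effects.

    R^2 = var(fixed-effect linear predictor) over (var(full linear predictor)
    + pi^2/3), computed at posterior means; used by the optional
    explained-variation scaling of predicted probabilities.
    """
    beta_mean = posterior.beta.mean(axis=0)
    fixed = design.X @ beta_mean
    eta_mean = posterior.linear_predictor(design, max_draws=200).mean(axis=0)
    total = float(np.var(eta_mean)) + math.pi ** 2 / 3.0
    return float(np.var(fixed)) / total


def _scaled(phat: np.ndarray, ybar: float, scaling: str, r2: float) -> np.ndarray:
    if scaling == "none":
        return phat
    if scaling == "blend":
        # calibrated shrink toward the observed prevalence
        return ybar + r2 * (phat - ybar)
    if scaling == "literal":
        return r2 * phat
    raise ValueError(f"unknown scaling {scaling!r}")


def predict_counterfactual(posterior: Posterior, design: DesignMatrix,
                           removed_factors: list[Factor],
                           scaling: str = "none", r2: float | None = None,
                           max_draws: int = 400) -> float:
    """Expected case count E_S with the given factor set removed."""
    X = _counterfactual_X(design, list(removed_factors))
    phat = posterior.fitted_probabilities(design, max_draws=max_draws, X=X)
    if scaling != "none" and r2 is None:
        r2 = explained_variation(posterior, design)
    phat = _scaled(phat, float(design.y.mean()), scaling, r2 if r2 is not None else 1.0)
    return float(phat.sum())


def attributable_fraction(observed: float, expected: float) -> float:
    """AF = (O - E)/O; negative values are legitimate and reported as-is."""
    if observed <= 0:
        raise ValueError("attributable fraction undefined for zero observed cases")
    return (observed - expected) / observed


@dataclass
class AFReport:
    """Per-permutation sequential AFs, Shapley averages and subset AFs."""

    factors: list[str]
    observed: float
    expected: dict = field(repr=False)           # frozenset of names -> E_S
    per_permutation: pd.DataFrame = field(repr=False)
    averaged: dict = field(default_factory=dict)  # factor -> mean sequential AF
    combined: dict = field(default_factory=dict)  # tuple of names -> AF
    scaling: str = "none"
    r2: float | None = None

    def table(self) -> pd.DataFrame:
        """Report layout: subset AFs (full set, pairs) then averaged per-factor
        AFs, as percentages."""
        rows = []
        for subset, af in self.combined.items():
            if len(subset) > 1:
                rows.append({"predictors": " + ".join(subset),
                             "af_pct": round(100.0 * af, 2), "kind": "combined"})
        for fac in self.factors:
            rows.append({"predictors": fac,
                         "af_pct": round(100.0 * self.averaged[fac], 2),
                         "kind": "averaged"})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "factors": self.factors,
            "observed": self.observed,
            "expected": {"+".join(sorted(k)): v for k, v in self.expected.items()},
            "averaged": self.averaged,
            "combined": {"+".join(k): v for k, v in self.combined.items()},
            "scaling": self.scaling,
            "r2": self.r2,
            "per_permutation": self.per_permutation.to_dict(orient="records"),
        }


def sequential_af(posterior: Posterior, design: DesignMatrix, factors,
                  scaling: str = "none", evi_reference_quantile: float = 0.9,
                  max_draws: int = 400) -> AFReport:
    """Sequential AFs over all removal orderings, averaged per factor.

    For each ordering the sequential AF of the factor at step k is the
    increment AF(first k removed) - AF(first k-1 removed); averaging over the
    k! orderings yields Shapley values whose sum equals the all-factors
    combined AF exactly.  Subset AFs for every singleton and pair plus the
    full set are reported alongside.
    """
    resolved = resolve_factors(design, factors,
                               evi_reference_quantile=evi_reference_quantile)
    names = [f.name for f in resolved]
    if not 1 <= len(names) <= MAX_FACTORS:
        raise ValueError(
            f"sequential AF supports 1-{MAX_FACTORS} factors (got {len(names)}); "
            "prune the factor list — permutation count grows factorially")
    if len(set(names)) != len(names):
        raise ValueError("duplicate factor names")
    by_name = {f.name: f for f in resolved}
    observed = float(design.y.sum())
    if observed <= 0:
        raise ValueError("no observed cases")

    r2 = explained_variation(posterior, design) if scaling != "none" else None

    expected: dict[frozenset, float] = {}

    def e_of(subset: frozenset) -> float:
        if subset not in expected:
            expected[subset] = predict_counterfactual(
                posterior, design, [by_name[n] for n in subset],
                scaling=scaling, r2=r2, max_draws=max_draws)
        return expected[subset]

    def af_of(subset: frozenset) -> float:
        return attributable_fraction(observed, e_of(subset))

    perm_rows = []
    sums = {n: 0.0 for n in names}
    orderings = list(itertools.permutations(names))
    for perm in orderings:
        prev = 0.0
        removed: set[str] = set()
        for k, fac in enumerate(perm, start=1):
            removed.add(fac)
            cum = af_of(frozenset(removed))
            perm_rows.append({"permutation": " > ".join(perm), "factor": fac,
                              "position": k, "sequential_af": cum - prev})
            sums[fac] += cum - prev
            prev = cum

    averaged = {n: sums[n] / len(orderings) for n in names}
    combined: dict[tuple, float] = {}
    for size in (1, 2):
        for subset in itertools.combinations(names, size):
            if size <= len(names):
                combined[subset] = af_of(frozenset(subset))
    if len(names) > 2:
        combined[tuple(names)] = af_of(frozenset(names))

    return AFReport(
        factors=names, observed=observed, expected=expected,
        per_permutation=pd.DataFrame(perm_rows), averaged=averaged,
        combined=combined, scaling=scaling, r2=r2,
    )
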