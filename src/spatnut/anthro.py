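"""Growth z-scores via the LMS transform, undernutrition classification and
descriptive prevalence tables.

The LMS transform maps a raw anthropometric measurement onto a z-score using a
reference table of skewness (L), median (M) and coefficient of variation (S)
indexed by sex and a key variable (height in cm for weight-for-height, age in
months for height-for-age).  References are pluggable: any table with the
required columns can be supplied, and a small synthetic reference is bundled so
the full pipeline runs offline.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LMSReference",
    "lms_zscore",
    "classify_undernutrition",
    "prevalence_table",
    "synthetic_reference",
]

#: indicator vocabulary: weight-for-height and height-for-age
INDICATORS = ("wfh", "hfa")
SEXES = ("male", "female")

DEFAULT_CUTOFF = -2.0
#: validity screen: |z| above this is treated as implausible and blanked
DEFAULT_VALIDITY_LIMIT = 6.0


class ReferenceError(ValueError):
    """Malformed or incomplete LMS reference table."""


@dataclass
class LMSReference:
    """LMS reference curves indexed by (indicator, sex, key).

    ``table`` columns: indicator, sex, key, L, M, S with keys strictly
    increasing within each (indicator, sex) series.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"indicator", "sex", "key", "L", "M", "S"}
        missing = required - set(self.table.columns)
        if missing:
            raise ReferenceError(f"reference table missing columns: {sorted(missing)}")
        if (self.table["M"] <= 0).any():
            raise ReferenceError("reference M values must be positive")
        if (self.table["S"] <= 0).any():
            raise ReferenceError("reference S values must be positive")
        for (ind, sex), grp in self.table.groupby(["indicator", "sex"]):
            keys = grp["key"].to_numpy(dtype=float)
            if not np.all(np.diff(keys) > 0):
                raise ReferenceError(f"keys not strictly increasing for ({ind}, {sex})")

    @classmethod
    def from_csv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def lookup(self, indicator: str, sex: str, key) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolate (L, M, S) linearly in the key; clamps at the ends."""
        grp = self.table[(self.table["indicator"] == indicator) & (self.table["sex"] == sex)]
        if grp.empty:
            raise ReferenceError(f"no reference series for ({indicator}, {sex})")
        keys = grp["key"].to_numpy(dtype=float)
        key = np.asarray(key, dtype=float)
        L = np.interp(key, keys, grp["L"].to_numpy(dtype=float))
        M = np.interp(key, keys, grp["M"].to_numpy(dtype=float))
        S = np.interp(key, keys, grp["S"].to_numpy(dtype=float))
        return L, M, S

    def zscore(self, indicator: str, sex: str, key, measure, tail_adjust: bool = False):
        L, M, S = self.lookup(indicator, sex, key)
        return lms_zscore(measure, L, M, S, tail_adjust=tail_adjust)


def _lms_centile(z: float, L, M, S):
    """Measurement value at a given reference z (inverse LMS)."""
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    safe_L = np.where(L == 0.0, 1.0, L)
    with np.errstate(invalid="ignore"):
        out = np.where(
            L == 0.0,
            M * np.exp(S * z),
            M * np.power(1.0 + L * S * z, 1.0 / safe_L),
        )
    return out


def lms_zscore(measure, L, M, S, tail_adjust: bool = False):
    """LMS z-score of ``measure`` given reference parameters.

    z = ((measure/M)^L - 1) / (L*S) for L != 0 and log(measure/M)/S at L = 0.
    With ``tail_adjust`` z-scores beyond +/-3 are rescaled linearly using the
    distance between the reference's 2 SD and 3 SD bounds (the restricted
    adjustment used with growth standards), which caps the influence of
    extreme measurements.
    """
    measure = np.asarray(measure, dtype=float)
    if np.any(measure[np.isfinite(measure)] <= 0):
        raise ValueError("measure must be positive")
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        # (x/M)^L - 1 via expm1(L log(x/M)): accurate uniformly as L -> 0
        z = np.where(
            L == 0.0,
            np.log(measure / M) / S,
            np.expm1(L * np.log(measure / M)) / (np.where(L == 0.0, 1.0, L) * S),
        )
    if tail_adjust:
        sd2p, sd3p = _lms_centile(2.0, L, M, S), _lms_centile(3.0, L, M, S)
        sd2n, sd3n = _lms_centile(-2.0, L, M, S), _lms_centile(-3.0, L, M, S)
        hi = z > 3.0
        lo = z < -3.0
        z = np.where(hi, 3.0 + (measure - sd3p) / (sd3p - sd2p), z)
        z = np.where(lo, -3.0 + (measure - sd3n) / (sd2n - sd3n), z)
    if z.ndim == 0:
        return float(z)
    return z


def classify_undernutrition(z, cutoff: float = DEFAULT_CUTOFF,
                            validity_limit: float = DEFAULT_VALIDITY_LIMIT):
    """Binary outcome: 1 iff z-score strictly below the cutoff.

    Missing or implausible z-scores (|z| > validity_limit) yield missing
    outcomes; callers drop those records with a logged count.
    """
    z = np.asarray(z, dtype=float)
    out = np.where(z < cutoff, 1.0, 0.0)
    invalid = ~np.isfinite(z) | (np.abs(z) > validity_limit)
    out = np.where(invalid, np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def prevalence_table(dataset: pd.DataFrame, grouping: str,
                     outcome_cols: tuple[str, ...] = ("stunted", "wasted")) -> pd.DataFrame:
    """Per-group child counts and outcome percentages, with a total row.

    ``dataset`` is child-level with a ``grouping`` column and binary outcome
    columns; a ``cluster_id`` column, when present, adds per-group cluster
    counts.  Percentages are reported to 2 decimals; groups with no children
    report blank (NA) percentages rather than zero.
    """
    if grouping not in dataset.columns:
        raise KeyError(f"grouping column {grouping!r} not in dataset")
    rows = []
    groups = list(dataset.groupby(grouping, sort=True, dropna=False, observed=False))
    for name, grp in groups:
        row = {grouping: name, "n_children": len(grp)}
        if "cluster_id" in dataset.columns:
            row["n_clusters"] = grp["cluster_id"].nunique()
        for col in outcome_cols:
            if col not in grp.columns:
                continue
            count = int(grp[col].sum())
            row[f"n_{col}"] = count
            row[f"pct_{col}"] = round(100.0 * count / len(grp), 2) if len(grp) else np.nan
        rows.append(row)
    total = {grouping: "Total", "n_children": int(len(dataset))}
    if "cluster_id" in dataset.columns:
        total["n_clusters"] = dataset["cluster_id"].nunique()
    for col in outcome_cols:
        if col not in dataset.columns:
            continue
        count = int(dataset[col].sum())
        total[f"n_{col}"] = count
        total[f"pct_{col}"] = round(100.0 * count / len(dataset), 2) if len(dataset) else np.nan
    rows.append(total)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundled synthetic reference
# ---------------------------------------------------------------------------

def synthetic_reference() -> LMSReference:
    """A small, smooth LMS reference so tests and demos run fully offline.

    Weight-for-height is keyed by height 65-120 cm; height-for-age by age
    6-59 months.  The curves are plausible in shape and magnitude but are NOT
    a published growth standard; analyses of real data should load one via
    :meth:`LMSReference.from_csv`.
    """
    rows = []
    heights = np.arange(65.0, 121.0, 5.0)
    for sex, m_shift in (("male", 0.0), ("female", -0.25)):
        for h in heights:
            # median weight roughly quadratic in height
            m = 2.0 + 0.09 * (h - 65.0) + 0.0011 * (h - 65.0) ** 2 + m_shift
            rows.append({"indicator": "wfh", "sex": sex, "key": h,
                         "L": -0.35, "M": round(m, 4), "S": 0.082})
    ages = np.arange(6.0, 60.0, 3.0)
    for sex, m_shift in (("male", 0.0), ("female", -0.7)):
        for a in ages:
            m = 65.0 + 0.95 * a - 0.004 * a ** 2 + m_shift
            rows.append({"indicator": "hfa", "sex": sex, "key": a,
                         "L": 1.0, "M": round(m, 4), "S": 0.038})
    return LMSReference(pd.DataFrame(rows))
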