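"""Domain tables, delimited-text readers/writers with quarantine, and run
configuration.

All files are comma-separated UTF-8 with ISO-8601 dates.  Readers never drop
rows silently: rows violating an invariant are diverted into a quarantine
report (row number + reason) and only valid rows are returned.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .exposure import ExposureWindows, VocabularyError, normalize_acled_type

log = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "EmptyInputError",
    "SurveyDataset",
    "ConflictEventTable",
    "ClusterGeography",
    "AdjacencyGraph",
    "MCMCSettings",
    "HyperPriors",
    "AFSettings",
    "SimSettings",
    "RunConfig",
    "read_survey_table",
    "write_survey_table",
    "read_conflict_events",
    "write_conflict_events",
    "read_geography",
    "read_adjacency",
]


class SchemaError(ValueError):
    """Input file is missing a mandatory column."""


class EmptyInputError(ValueError):
    """Input file contains no data rows."""


LIVELIHOODS = ("agro-pastoral", "pastoral", "riverine", "urban", "idp")
SEXES = ("male", "female")

#: columns that must be present in a survey file
SURVEY_MANDATORY = (
    "child_id", "cluster_id", "district_id", "region_id", "survey_date",
    "age_months", "sex", "livelihood",
)
SURVEY_BINARY = (
    "diarrhoea", "ari", "fever", "suspected_measles",
    "vitamin_a", "measles_vax", "polio_vax", "female_head",
    "carbohydrate", "protein", "fats", "fruits_veg",
)
SURVEY_NUMERIC = (
    "household_size", "n_under5", "mother_age", "mother_muac",
    "weight_kg", "height_cm", "whz", "haz",
)
SURVEY_COLUMNS = SURVEY_MANDATORY + SURVEY_BINARY + SURVEY_NUMERIC

AGE_RANGE = (6, 59)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SurveyDataset:
    """Validated child-level records plus the quarantine report."""

    records: pd.DataFrame
    quarantine: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "child_id", "reason"]))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ConflictEventTable:
    """Validated, type-normalised conflict events plus quarantine report."""

    events: pd.DataFrame
    quarantine: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "event_id", "reason"]))

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class ClusterGeography:
    """Cluster locations/context plus seasonal environmental covariates.

    ``clusters``: cluster_id, district_id, region_id, lon, lat, livelihood.
    ``covariates``: cluster_id, season, rainfall, evi, temperature,
    distance_to_water, urbanisation — complete for all four seasons.
    """

    clusters: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if self.clusters["cluster_id"].duplicated().any():
            dup = self.clusters.loc[self.clusters["cluster_id"].duplicated(), "cluster_id"].iloc[0]
            raise ValueError(f"duplicate cluster_id: {dup!r}")
        per_cluster = self.covariates.groupby("cluster_id")["season"].nunique()
        known = per_cluster.reindex(self.clusters["cluster_id"])
        if known.isna().any() or (known < 4).any():
            missing = known[known.isna() | (known < 4)].index[0]
            raise ValueError(f"cluster {missing!r} lacks covariates for all four seasons")

    @property
    def cluster_ids(self) -> list:
        return list(self.clusters["cluster_id"])

    def district_of(self) -> pd.Series:
        return self.clusters.set_index("cluster_id")["district_id"]


class AdjacencyGraph:
    """Symmetric cluster adjacency with no self-loops.

    Stores neighbour lists; connected components are exposed because the
    intrinsic autoregression is constrained per component.
    """

    def __init__(self, nodes, edges):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            g.add_edge(a, b)
        unknown = set(g.nodes) - set(nodes)
        if unknown:
            raise ValueError(f"edge references unknown node(s): {sorted(unknown)[:3]}")
        self._g = g
        self.nodes = list(nodes)

    @property
    def edges(self) -> list[tuple]:
        return [tuple(e) for e in self._g.edges]

    def neighbors(self, node) -> list:
        return list(self._g.neighbors(node))

    def components(self) -> list[list]:
        order = {n: i for i, n in enumerate(self.nodes)}
        comps = [sorted(c, key=order.get) for c in nx.connected_components(self._g)]
        return sorted(comps, key=lambda c: order[c[0]])

    def degree(self) -> dict:
        return dict(self._g.degree)

    def structure_matrix(self, order=None) -> np.ndarray:
        """ICAR structure matrix Q = D - A in the given node order."""
        order = self.nodes if order is None else list(order)
        idx = {n: i for i, n in enumerate(order)}
        q = np.zeros((len(order), len(order)))
        for a, b in self._g.edges:
            q[idx[a], idx[b]] -= 1.0
            q[idx[b], idx[a]] -= 1.0
        for n in order:
            q[idx[n], idx[n]] = self._g.degree(n)
        return q

    @classmethod
    def from_csv(cls, path, nodes=None) -> "AdjacencyGraph":
        df = pd.read_csv(path)
        for col in ("node_a", "node_b"):
            if col not in df.columns:
                raise SchemaError(f"adjacency file missing mandatory column {col!r}")
        edges = list(zip(df["node_a"], df["node_b"]))
        if nodes is None:
            nodes = sorted({n for e in edges for n in e})
        return cls(nodes, edges)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.edges, columns=["node_a", "node_b"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if df.empty:
        raise EmptyInputError(f"{path} has a header but no data rows")
    return df


def read_survey_table(path, extra_mandatory: tuple = ()) -> SurveyDataset:
    """Read and validate a child-level survey CSV.

    Unknown columns are ignored with a logged warning; rows violating record
    invariants are quarantined with a reason.  Returns only valid rows.
    """
    df = _read_csv(path)
    for col in SURVEY_MANDATORY + tuple(extra_mandatory):
        if col not in df.columns:
            raise SchemaError(f"survey file missing mandatory column {col!r}")
    unknown = [c for c in df.columns if c not in SURVEY_COLUMNS]
    if unknown:
        log.warning("ignoring unknown survey columns: %s", unknown)
        df = df.drop(columns=unknown)
    for col in SURVEY_BINARY + SURVEY_NUMERIC:
        if col not in df.columns:
            df[col] = np.nan
    return validate_survey(df)


def validate_survey(df: pd.DataFrame) -> SurveyDataset:
    """Apply record invariants, splitting rows into valid vs quarantined."""
    df = df.reset_index(drop=True).copy()
    reasons: dict[int, str] = {}

    def flag(mask, reason):
        for i in np.flatnonzero(np.asarray(mask)):
            reasons.setdefault(int(i), reason)

    dates = pd.to_datetime(df["survey_date"], errors="coerce")
    flag(dates.isna(), "unparseable survey_date")
    df["survey_date"] = dates

    age = pd.to_numeric(df["age_months"], errors="coerce")
    flag(age.isna() | (age < AGE_RANGE[0]) | (age > AGE_RANGE[1]), "age out of range")
    flag(~df["sex"].isin(SEXES), "unknown sex")
    flag(~df["livelihood"].isin(LIVELIHOODS), "unknown livelihood")
    for col in SURVEY_BINARY:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & ~vals.isin([0, 1])
        flag(bad, f"non-binary flag {col}")
    for col in ("weight_kg", "height_cm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        flag(vals.notna() & (vals <= 0), f"non-positive {col}")
    # anthropometry present for at least one analysis
    wt = pd.to_numeric(df["weight_kg"], errors="coerce")
    ht = pd.to_numeric(df["height_cm"], errors="coerce")
    whz = pd.to_numeric(df["whz"], errors="coerce")
    haz = pd.to_numeric(df["haz"], errors="coerce")
    wasting_ok = whz.notna() | (wt.notna() & ht.notna())
    stunting_ok = haz.notna() | ht.notna()
    flag(~(wasting_ok | stunting_ok), "no usable anthropometry")

    bad_rows = sorted(reasons)
    quarantine = pd.DataFrame({
        "row": [i + 1 for i in bad_rows],
        "child_id": [df.at[i, "child_id"] for i in bad_rows],
        "reason": [reasons[i] for i in bad_rows],
    })
    valid = df.drop(index=bad_rows).reset_index(drop=True)
    return SurveyDataset(records=valid, quarantine=quarantine)


def write_survey_table(dataset: SurveyDataset | pd.DataFrame, path) -> None:
    df = dataset.records if isinstance(dataset, SurveyDataset) else dataset
    out = df.copy()
    if "survey_date" in out.columns:
        out["survey_date"] = pd.to_datetime(out["survey_date"]).dt.strftime("%Y-%m-%d")
    # %.17g round-trips float64 exactly
    out.to_csv(path, index=False, float_format="%.17g")


EVENT_MANDATORY = ("event_id", "event_date", "acled_type")


def read_conflict_events(path) -> ConflictEventTable:
    """Read a conflict event CSV; normalise dates and type labels.

    Rows with unparseable dates or a type outside the nine-label vocabulary
    are quarantined with a reason.
    """
    df = _read_csv(path)
    for col in EVENT_MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"event file missing mandatory column {col!r}")
    if "district_id" not in df.columns and not {"lon", "lat"} <= set(df.columns):
        raise SchemaError("event file needs district_id and/or lon+lat columns")
    df = df.reset_index(drop=True).copy()
    reasons: dict[int, str] = {}

    dates = pd.to_datetime(df["event_date"], errors="coerce")
    for i in np.flatnonzero(dates.isna().to_numpy()):
        reasons.setdefault(int(i), "unparseable event_date")
    df["event_date"] = dates

    normalized = []
    for i, label in enumerate(df["acled_type"]):
        try:
            normalized.append(normalize_acled_type(label))
        except VocabularyError:
            reasons.setdefault(i, f"unknown event type {label!r}")
            normalized.append(label)
    df["acled_type"] = normalized

    bad_rows = sorted(reasons)
    quarantine = pd.DataFrame({
        "row": [i + 1 for i in bad_rows],
        "event_id": [df.at[i, "event_id"] for i in bad_rows],
        "reason": [reasons[i] for i in bad_rows],
    })
    valid = df.drop(index=bad_rows).reset_index(drop=True)
    return ConflictEventTable(events=valid, quarantine=quarantine)


def write_conflict_events(table: ConflictEventTable | pd.DataFrame, path) -> None:
    df = table.events if isinstance(table, ConflictEventTable) else table
    out = df.copy()
    out["event_date"] = pd.to_datetime(out["event_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.17g")


def read_geography(clusters_path, covariates_path) -> ClusterGeography:
    clusters = _read_csv(clusters_path)
    for col in ("cluster_id", "district_id", "region_id", "lon", "lat", "livelihood"):
        if col not in clusters.columns:
            raise SchemaError(f"geography file missing mandatory column {col!r}")
    cov = _read_csv(covariates_path)
    for col in ("cluster_id", "season", "rainfall", "evi", "temperature",
                "distance_to_water", "urbanisation"):
        if col not in cov.columns:
            raise SchemaError(f"covariate file missing mandatory column {col!r}")
    return ClusterGeography(clusters=clusters, covariates=cov)


def read_adjacency(path, nodes=None) -> AdjacencyGraph:
    return AdjacencyGraph.from_csv(path, nodes=nodes)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class MCMCSettings:
    chains: int = 4
    iterations: int = 5000
    burnin: int = 2000
    thinning: int = 2


@dataclass
class HyperPriors:
    """Gamma(shape, rate) hyperpriors on precisions; Gaussian precision on
    fixed effects."""

    tau_shape: float = 1.0
    tau_rate: float = 5e-4
    beta_precision: float = 1e-4


@dataclass
class AFSettings:
    factors: tuple = ("recent", "longer", "evi")
    scaling: str = "none"  # none | blend | literal
    evi_reference_quantile: float = 0.9


@dataclass
class SimSettings:
    n_districts: int = 4
    clusters_per_district: int = 5
    n_children: int = 500
    n_rounds: int = 4
    start_date: str = "2007-01-01"
    end_date: str = "2010-12-31"


@dataclass
class RunConfig:
    """Resolved, validated run configuration; the single source of randomness
    (every stage derives its generator from ``seed``)."""

    seed: int
    outdir: str = "runs/out"
    outcomes: tuple = ("wasted",)
    cutoff: float = -2.0
    linkage: str = "district"
    buffer_km: float = 10.0
    recent_lo: int = 0
    recent_hi: int = 91
    longer_hi: int = 366
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    hyperpriors: HyperPriors = field(default_factory=HyperPriors)
    af: AFSettings = field(default_factory=AFSettings)
    sim: SimSettings = field(default_factory=SimSettings)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed must be explicit")
        self.windows  # validates ordering
        if self.mcmc.iterations <= self.mcmc.burnin:
            raise ValueError("mcmc iterations must exceed burn-in")
        if self.af.scaling not in ("none", "blend", "literal"):
            raise ValueError(f"unknown AF scaling {self.af.scaling!r}")

    @property
    def windows(self) -> ExposureWindows:
        return ExposureWindows(self.recent_lo, self.recent_hi, self.longer_hi)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if seed is not None:
            raw["seed"] = seed
        for key, sub in (("mcmc", MCMCSettings), ("hyperpriors", HyperPriors),
                         ("af", AFSettings), ("sim", SimSettings)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for tup_key in ("outcomes",):
            if tup_key in raw and isinstance(raw[tup_key], list):
                raw[tup_key] = tuple(raw[tup_key])
        if "af" in raw and isinstance(raw["af"].factors, list):
            raw["af"].factors = tuple(raw["af"].factors)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
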