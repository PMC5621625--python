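"""Synthetic geography, conflict streams, covariates and survey outcomes.

Everything downstream of data ingestion is testable offline: this module
draws a multi-district cluster geography with adjacency, spatially smooth
seasonal environmental fields, a seasonally inhomogeneous Poisson conflict
stream, and child-level outcomes from the same hierarchical logistic model
family the fitting code estimates — with every true parameter recorded, so
parameter-recovery and model-comparison tests have a known target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .data_io import AdjacencyGraph, ClusterGeography, SurveyDataset, LIVELIHOODS
from .exposure import CONFLICT_CLASSES, ExposureWindows, DEFAULT_WINDOWS, build_exposure_matrix
from .model import SEASONS, build_design, icar_draw

__all__ = [
    "TruthParams",
    "generate_geography",
    "simulate_conflict_events",
    "simulate_survey",
    "morans_i",
    "DEFAULT_MARGINALS",
]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


#: default covariate marginals for simulated children; any plausible set
#: suffices for recovery tests, these are deliberately simple
DEFAULT_MARGINALS = {
    "illness_p": 0.15,          # diarrhoea / ari / fever / suspected_measles
    "vitamin_a_p": 0.6,
    "measles_vax_p": 0.6,
    "polio_vax_p": 0.7,
    "female_head_p": 0.3,
    "female_p": 0.5,
    "household_size_base": 3,   # 3 + Poisson(3)
    "household_size_lam": 3.0,
    "n_under5_lam": 1.0,        # 1 + Poisson(1)
    "mother_age_range": (16.0, 45.0),
    "mother_muac_mean": 26.0,
    "mother_muac_sd": 2.0,
    "food_p": {"carbohydrate": 0.6, "protein": 0.5, "fats": 0.3, "fruits_veg": 0.35},
}

#: nine-label types available within each analysis class, for event typing
_CLASS_LABELS = {
    "battle": ("battle - no change of territory",
               "battle - non-state actor overtakes territory",
               "battle - government regains territory"),
    "remote_violence": ("remote violence",),
    "violence_against_civilians": ("violence against civilians",),
    "other": ("headquarters or base established", "strategic development",
              "riots or protests", "non-violent transfer of territory"),
}


@dataclass
class TruthParams:
    """Known generative parameters for the synthetic survey model.

    ``betas`` maps design column names (raw, unstandardised scale) to
    log-odds coefficients; the default conflict effects correspond to odds
    ratios 1.37 (recent) and 1.76 (longer term) for wasting and the intercept
    to a 21% baseline prevalence.  Precisions may be ``inf`` to switch a
    random-effect block off exactly.
    """

    intercept: float = _logit(0.21)
    betas: dict = field(default_factory=lambda: {
        "recent_conflict": math.log(1.37),
        "longer_conflict": math.log(1.76),
    })
    intercept_stunting: float | None = None
    betas_stunting: dict | None = None
    tau_u: float = 4.0
    tau_v: float = 25.0
    tau_d: float = 25.0
    tau_w: float = 25.0
    conflict_base_rate: float = 0.08    # events per district-month, Deyr level
    season_multipliers: dict = field(default_factory=lambda: {
        "Jilal": 1.4, "Gu": 0.7, "Hagaa": 1.0, "Deyr": 0.9})
    class_mix: tuple = (0.54, 0.08, 0.28, 0.10)

    def __post_init__(self) -> None:
        for name in ("tau_u", "tau_v", "tau_d", "tau_w"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(m <= 0 for m in self.season_multipliers.values()):
            raise ValueError("seasonal intensity multipliers must be positive")
        if self.conflict_base_rate < 0:
            raise ValueError("conflict_base_rate must be non-negative")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or len(self.class_mix) != 4:
            raise ValueError("class_mix must be four proportions summing to 1")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)

    @classmethod
    def from_json(cls, path) -> "TruthParams":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["class_mix"] = tuple(raw["class_mix"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def generate_geography(n_districts: int, clusters_per_district: int,
                       seed: int, icar_ready: bool = True,
                       livelihood_mix: tuple = (0.42, 0.27, 0.16, 0.04, 0.11),
                       ) -> tuple[ClusterGeography, AdjacencyGraph]:
    """Jittered-grid cluster geography with Delaunay adjacency and smooth
    seasonal environmental fields.

    Districts sit on a coarse grid (three districts per region); clusters
    jitter around their district centre.  Environmental fields are draws from
    a squared-exponential Gaussian process over cluster centroids with
    season-specific means, so they are spatially smooth by construction.
    """
    if n_districts < 1 or clusters_per_district < 1:
        raise ValueError("counts must be >= 1")
    n_clusters = n_districts * clusters_per_district
    if icar_ready and n_clusters < 2:
        raise ValueError("ICAR is undefined on a single cluster; need >= 2")
    rng = np.random.default_rng(seed)

    side = int(np.ceil(np.sqrt(n_districts)))
    rows = []
    for d in range(n_districts):
        dx, dy = d % side, d // side
        region = f"R{d // 3:02d}"
        for c in range(clusters_per_district):
            rows.append({
                "cluster_id": f"D{d:03d}-C{c:03d}",
                "district_id": f"D{d:03d}",
                "region_id": region,
                "lon": 42.0 + dx + rng.uniform(0.1, 0.9),
                "lat": 2.0 + dy + rng.uniform(0.1, 0.9),
                "livelihood": rng.choice(LIVELIHOODS, p=livelihood_mix),
            })
    clusters = pd.DataFrame(rows)

    pts = clusters[["lon", "lat"]].to_numpy()
    edges = set()
    if n_clusters >= 4:
        try:
            tri = Delaunay(pts)
            for simplex in tri.simplices:
                for i in range(3):
                    a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
                    edges.add((a, b))
        except Exception:  # degenerate geometry; fall back to kNN below
            edges = set()
    if not edges and n_clusters >= 2:
        k = min(3, n_clusters - 1)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for i in range(n_clusters):
            for j in np.argsort(d2[i])[:k]:
                edges.add(tuple(sorted((i, int(j)))))
    ids = list(clusters["cluster_id"])
    graph = AdjacencyGraph(ids, [(ids[a], ids[b]) for a, b in edges])

    # smooth seasonal fields: GP draws with length scale ~ one grid cell
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2 * 0.8 ** 2)) + 1e-8 * np.eye(n_clusters)
    chol = np.linalg.cholesky(cov)

    def gp():
        return chol @ rng.standard_normal(n_clusters)

    season_rain = {"Jilal": 5.0, "Gu": 90.0, "Hagaa": 20.0, "Deyr": 60.0}
    season_temp = {"Jilal": 30.0, "Gu": 27.0, "Hagaa": 28.0, "Deyr": 27.5}
    season_evi = {"Jilal": 0.15, "Gu": 0.35, "Hagaa": 0.22, "Deyr": 0.30}
    dist_water = np.exp(1.0 + 0.8 * gp())            # km, season-constant
    urban = (clusters["livelihood"] == "urban").astype(float).to_numpy()

    cov_rows = []
    for season in SEASONS:
        rain = np.clip(season_rain[season] * np.exp(0.4 * gp()), 0.0, None)
        evi = 1.0 / (1.0 + np.exp(-(np.log(season_evi[season] /
                                           (1 - season_evi[season])) + 0.5 * gp())))
        temp = season_temp[season] + 1.5 * gp()
        for i, cid in enumerate(ids):
            cov_rows.append({
                "cluster_id": cid, "season": season,
                "rainfall": rain[i], "evi": evi[i], "temperature": temp[i],
                "distance_to_water": dist_water[i], "urbanisation": urban[i],
            })
    geography = ClusterGeography(clusters=clusters, covariates=pd.DataFrame(cov_rows))
    return geography, graph


# ---------------------------------------------------------------------------
# Conflict stream
# ---------------------------------------------------------------------------

def simulate_conflict_events(geography: ClusterGeography, truth: TruthParams,
                             start_date, end_date, seed: int) -> pd.DataFrame:
    """Seasonally inhomogeneous Poisson conflict stream per district.

    District-month counts are Poisson with rate = base x seasonal multiplier;
    each event gets a class from the stated mixture, a concrete nine-label
    type within the class, a day uniform in its month and the location of a
    random cluster of the district (jittered).
    """
    from .model import season_of

    start, end = pd.Timestamp(start_date), pd.Timestamp(end_date)
    if end < start:
        raise ValueError("end_date precedes start_date")
    rng = np.random.default_rng(seed)
    months = pd.period_range(start, end, freq="M")
    districts = geography.clusters["district_id"].unique()
    by_district = {d: g for d, g in geography.clusters.groupby("district_id")}

    rows = []
    eid = 0
    for month in months:
        mid_month = month.to_timestamp() + pd.Timedelta(days=14)
        mult = truth.season_multipliers[season_of(mid_month)]
        lam = truth.conflict_base_rate * mult
        for dist in districts:
            count = rng.poisson(lam)
            for _ in range(count):
                cls = CONFLICT_CLASSES[rng.choice(4, p=truth.class_mix)]
                label = _CLASS_LABELS[cls][rng.integers(len(_CLASS_LABELS[cls]))]
                day = int(rng.integers(month.days_in_month))
                date = month.to_timestamp() + pd.Timedelta(days=day)
                row = by_district[dist].iloc[rng.integers(len(by_district[dist]))]
                rows.append({
                    "event_id": f"E{eid:06d}",
                    "event_date": date,
                    "lon": row["lon"] + rng.normal(0, 0.02),
                    "lat": row["lat"] + rng.normal(0, 0.02),
                    "district_id": dist,
                    "region_id": row["region_id"],
                    "acled_type": label,
                    "fatalities": int(rng.poisson(1.5)),
                })
                eid += 1
    columns = ["event_id", "event_date", "lon", "lat", "district_id",
               "region_id", "acled_type", "fatalities"]
    events = pd.DataFrame(rows, columns=columns)
    events = events.sort_values("event_date", kind="stable").reset_index(drop=True)
    events["event_id"] = [f"E{i:06d}" for i in range(len(events))]
    return events


# ---------------------------------------------------------------------------
# Survey outcomes
# ---------------------------------------------------------------------------

def _effect_draw(size: int, tau: float, rng) -> np.ndarray:
    if not np.isfinite(tau):
        return np.zeros(size)
    return rng.normal(0.0, 1.0 / np.sqrt(tau), size)


def simulate_survey(geography: ClusterGeography, adjacency: AdjacencyGraph,
                    events: pd.DataFrame, truth: TruthParams, n_children: int,
                    survey_dates, seed: int,
                    marginals: dict | None = None,
                    windows: ExposureWindows = DEFAULT_WINDOWS,
                    linkage: str = "district",
                    date_jitter_days: int = 30) -> SurveyDataset:
    """Draw a child-level survey dataset from the hierarchical model.

    Children are allocated to (cluster, round) cells multinomially with equal
    cluster probabilities; covariates follow :data:`DEFAULT_MARGINALS`;
    exposure indicators are computed from ``events`` through the ordinary
    exposure code path; and outcomes are Bernoulli with

        logit p = intercept + x'beta + u + v + w + d

    where u is an ICAR draw (per-component sum-to-zero), v and d iid normal,
    and w a centred first-order random walk over survey rounds.  Outcomes are
    encoded as z-scores placed on the correct side of the -2 cutoff so that
    classification recovers them exactly.

    Each cluster's survey within a round is dated round date +/- uniform
    jitter (``date_jitter_days``), mimicking a field roll-out; this also
    breaks the exact collinearity between calendar-season indicators and the
    per-round temporal effect that arises when every cluster shares one date.
    """
    marg = dict(DEFAULT_MARGINALS)
    if marginals:
        marg.update(marginals)
    rng = np.random.default_rng(seed)
    survey_dates = [pd.Timestamp(t) for t in survey_dates]
    clusters = geography.clusters
    n_clusters = len(clusters)
    n_cells = n_clusters * len(survey_dates)

    # one concrete survey date per (cluster, round)
    cell_dates = {}
    for ci in range(n_clusters):
        for ri, rdate in enumerate(survey_dates):
            offset = int(rng.integers(-date_jitter_days, date_jitter_days + 1)) \
                if date_jitter_days else 0
            cell_dates[ci, ri] = rdate + pd.Timedelta(days=offset)

    counts = rng.multinomial(n_children, np.full(n_cells, 1.0 / n_cells))
    rows = []
    child = 0
    for cell, count in enumerate(counts):
        crow = clusters.iloc[cell // len(survey_dates)]
        sdate = cell_dates[cell // len(survey_dates), cell % len(survey_dates)]
        for _ in range(count):
            hh = marg["household_size_base"] + rng.poisson(marg["household_size_lam"])
            rows.append({
                "child_id": f"ch{child:06d}",
                "cluster_id": crow["cluster_id"],
                "district_id": crow["district_id"],
                "region_id": crow["region_id"],
                "survey_date": sdate,
                "age_months": int(rng.integers(6, 60)),
                "sex": "female" if rng.random() < marg["female_p"] else "male",
                "diarrhoea": int(rng.random() < marg["illness_p"]),
                "ari": int(rng.random() < marg["illness_p"]),
                "fever": int(rng.random() < marg["illness_p"]),
                "suspected_measles": int(rng.random() < marg["illness_p"]),
                "vitamin_a": int(rng.random() < marg["vitamin_a_p"]),
                "measles_vax": int(rng.random() < marg["measles_vax_p"]),
                "polio_vax": int(rng.random() < marg["polio_vax_p"]),
                "household_size": hh,
                "n_under5": int(min(1 + rng.poisson(marg["n_under5_lam"]), hh)),
                "female_head": int(rng.random() < marg["female_head_p"]),
                "mother_age": float(rng.uniform(*marg["mother_age_range"])),
                "mother_muac": float(rng.normal(marg["mother_muac_mean"],
                                                marg["mother_muac_sd"])),
                "carbohydrate": int(rng.random() < marg["food_p"]["carbohydrate"]),
                "protein": int(rng.random() < marg["food_p"]["protein"]),
                "fats": int(rng.random() < marg["food_p"]["fats"]),
                "fruits_veg": int(rng.random() < marg["food_p"]["fruits_veg"]),
                "livelihood": crow["livelihood"],
                "weight_kg": np.nan,
                "height_cm": np.nan,
            })
            child += 1
    df = pd.DataFrame(rows)

    survey_index = pd.DataFrame(
        [(clusters["cluster_id"].iloc[ci], cell_dates[ci, ri])
         for ci in range(n_clusters) for ri in range(len(survey_dates))],
        columns=["cluster_id", "survey_date"]).drop_duplicates()
    exposure = build_exposure_matrix(events, clusters, survey_index,
                                     linkage=linkage, windows=windows)

    variant = "B" if ("recent_conflict" in truth.betas
                      or "longer_conflict" in truth.betas) else "A"
    df_tmp = df.copy()
    df_tmp["wasted"] = 0.0  # placeholder outcome; only X is used below
    design = build_design(df_tmp, exposure, geography, variant=variant,
                          outcome="wasted", standardize=False, drop_constant=False)

    def eta_for(intercept: float, betas: dict) -> np.ndarray:
        unknown = set(betas) - set(design.columns)
        if unknown:
            missing = sorted(unknown)[0]
            raise ValueError(f"truth coefficient for unknown covariate {missing!r}")
        eta = np.full(design.n, intercept)
        for name, b in betas.items():
            eta += b * design.col(name)
        return eta

    # latent effects shared by both outcomes
    Q = adjacency.structure_matrix(order=design.cluster_ids)
    pos = {c: i for i, c in enumerate(design.cluster_ids)}
    comps = [np.array(sorted(pos[c] for c in comp if c in pos))
             for comp in adjacency.components()]
    comps = [c for c in comps if len(c)]
    u = icar_draw(Q, truth.tau_u, comps, rng)
    v = _effect_draw(len(design.cluster_ids), truth.tau_v, rng)
    d = _effect_draw(len(design.district_ids), truth.tau_d, rng)
    if np.isfinite(truth.tau_w) and len(design.round_dates) > 1:
        w = np.cumsum(rng.normal(0, 1.0 / np.sqrt(truth.tau_w),
                                 len(design.round_dates)))
        w -= w.mean()
    else:
        w = np.zeros(len(design.round_dates))
    latent = (u[design.cluster_codes] + v[design.cluster_codes]
              + w[design.round_codes] + d[design.district_codes])

    def draw_outcome(intercept, betas):
        eta = eta_for(intercept, betas) + latent
        p = 1.0 / (1.0 + np.exp(-eta))
        return (rng.random(design.n) < p).astype(int)

    y_wasted = draw_outcome(truth.intercept, truth.betas)
    st_intercept = (truth.intercept if truth.intercept_stunting is None
                    else truth.intercept_stunting)
    st_betas = truth.betas if truth.betas_stunting is None else truth.betas_stunting
    y_stunted = draw_outcome(st_intercept, st_betas)

    # encode outcomes as z-scores strictly on the correct side of the cutoff
    def encode(y):
        mag = np.abs(rng.normal(0.0, 0.8, len(y)))
        return np.where(y == 1, -2.0 - 0.05 - mag, -2.0 + 0.05 + mag)

    if design.n != len(df):  # synthetic covariates are complete by construction
        raise RuntimeError("design dropped rows of a synthetic dataset")
    df = df.reset_index(drop=True)
    df["whz"] = np.round(encode(y_wasted), 4)
    df["haz"] = np.round(encode(y_stunted), 4)
    df["wasted"] = y_wasted
    df["stunted"] = y_stunted
    return SurveyDataset(records=df)


# ---------------------------------------------------------------------------
# Spatial autocorrelation utility (used by smoothness tests)
# ---------------------------------------------------------------------------

def morans_i(values: np.ndarray, graph: AdjacencyGraph, order: list) -> float:
    """Moran's I of node values under binary graph weights."""
    values = np.asarray(values, dtype=float)
    pos = {n: i for i, n in enumerate(order)}
    z = values - values.mean()
    num = 0.0
    n_edges = 0
    for a, b in graph.edges:
        num += 2.0 * z[pos[a]] * z[pos[b]]
        n_edges += 2
    denom = (z ** 2).sum()
    if denom == 0 or n_edges == 0:
        return np.nan
    return (len(values) / n_edges) * (num / denom)
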