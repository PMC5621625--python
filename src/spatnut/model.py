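"""Design construction and the Bayesian hierarchical spatio-temporal logistic
model.

The linear predictor for child i is

    logit p_i = x_i' beta + u_{c(i)} + v_{c(i)} + w_{t(i)} + d_{dist(i)}

with a convolution (BYM) prior at cluster level — u an intrinsic
conditional autoregression (ICAR) on the cluster adjacency graph with a
per-component sum-to-zero constraint, v iid Gaussian — an iid Gaussian
district effect d, and a first-order random walk w over survey rounds, also
constrained to sum to zero.  Precisions carry Gamma hyperpriors and fixed
effects a weak Gaussian prior.

Inference is by Polya-Gamma augmented Gibbs sampling: conditional on the
augmentation variables every Gaussian block has a conjugate multivariate
normal update and each precision a conjugate Gamma update, so the sampler is
exact for the stated posterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._polya_gamma import random_polyagamma
from .anthro import classify_undernutrition
from .data_io import AdjacencyGraph, SurveyDataset

log = logging.getLogger(__name__)

__all__ = [
    "SEASONS",
    "season_of",
    "screen_collinearity",
    "CollinearityReport",
    "DesignMatrix",
    "build_design",
    "PriorSpec",
    "Posterior",
    "fit_model",
    "summarize_effects",
    "icar_draw",
    "sample_gmrf",
    "split_rhat",
    "effective_sample_size",
]

# ---------------------------------------------------------------------------
# Seasons
# ---------------------------------------------------------------------------

#: Deyr (short rains) is the reference level in the design
SEASONS = ("Deyr", "Gu", "Hagaa", "Jilal")

_MONTH_SEASON = {1: "Jilal", 2: "Jilal", 3: "Jilal", 4: "Gu", 5: "Gu", 6: "Gu",
                 7: "Hagaa", 8: "Hagaa", 9: "Hagaa", 10: "Deyr", 11: "Deyr"}


def season_of(date, december: str = "Jilal") -> str:
    """Somali season of a calendar date.

    Jan-Mar Jilal (harsh dry), Apr-Jun Gu (main rains), Jul-Sep Hagaa (short
    dry), Oct-Nov Deyr (short rains).  December belongs to both rainy-Deyr and
    dry-Jilal descriptions; the tie is resolved to Jilal by default and is
    configurable.
    """
    if december not in ("Jilal", "Deyr"):
        raise ValueError("december must resolve to 'Jilal' or 'Deyr'")
    month = pd.Timestamp(date).month
    return december if month == 12 else _MONTH_SEASON[month]


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

@dataclass
class CollinearityReport:
    correlations: pd.DataFrame
    flagged: pd.DataFrame          # columns: col_a, col_b, r
    constant_columns: list[str]
    threshold: float


def screen_collinearity(table: pd.DataFrame, threshold: float = 0.6) -> CollinearityReport:
    """Pairwise Pearson correlations among numeric columns.

    Pairs with |r| >= threshold are flagged (fitting proceeds with a warning,
    never an abort).  Constant columns have undefined correlations and are
    reported as such.
    """
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        raise ValueError("need at least two numeric columns to screen")
    constant = [c for c in num.columns if num[c].nunique(dropna=True) <= 1]
    corr = num.corr()
    rows = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= threshold:
                rows.append({"col_a": a, "col_b": b, "r": float(r)})
    flagged = pd.DataFrame(rows, columns=["col_a", "col_b", "r"])
    if len(flagged):
        log.warning("collinearity screen flagged %d pairs at |r| >= %.2f",
                    len(flagged), threshold)
    return CollinearityReport(corr, flagged, constant, threshold)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

#: continuous covariates standardised (mean 0, sd 1) before fitting
CONTINUOUS_COLS = ("household_size", "n_under5", "mother_age", "mother_muac",
                   "distance_to_water", "evi", "rainfall", "temperature")

#: interaction structure examined in the conflict model (variant B)
INTERACTION_PAIRS = (
    ("recent_conflict", "carbohydrate"), ("recent_conflict", "protein"),
    ("recent_conflict", "evi"), ("recent_conflict", "rainfall"),
    ("longer_conflict", "carbohydrate"), ("longer_conflict", "protein"),
    ("longer_conflict", "evi"), ("longer_conflict", "rainfall"),
    ("carbohydrate", "evi"), ("carbohydrate", "rainfall"),
    ("protein", "evi"), ("protein", "rainfall"),
    ("evi", "temperature"),
)


@dataclass
class DesignMatrix:
    """Response, covariate block and grouping index maps for one model run."""

    X: np.ndarray
    columns: list[str]
    y: np.ndarray
    cluster_codes: np.ndarray
    district_codes: np.ndarray
    round_codes: np.ndarray
    cluster_ids: list
    district_ids: list
    round_dates: list
    variant: str
    outcome: str
    transforms: dict = field(default_factory=dict)       # col -> (center, scale)
    interactions: dict = field(default_factory=dict)     # col -> (pa, pb, ca, cb)
    n_dropped_missing: int = 0
    dropped_constant: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def col(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)


def _assign_rounds(dates: pd.Series, gap_days: int = 90) -> tuple[dict, list]:
    """Group survey dates into rounds: a new round starts at a gap > 90 days.

    Field surveys roll out over weeks, so calendar dates within one biannual
    round differ; clustering by gaps recovers the round structure without
    requiring an explicit round column.
    """
    uniq = sorted(pd.to_datetime(dates).unique())
    index: dict = {}
    round_starts: list = []
    prev = None
    r = -1
    for t in uniq:
        if prev is None or (t - prev).days > gap_days:
            r += 1
            round_starts.append(pd.Timestamp(t))
        index[t] = r
        prev = t
    return index, round_starts


def _derive_outcome(df: pd.DataFrame, outcome: str, cutoff: float) -> pd.Series:
    if outcome in df.columns and df[outcome].notna().any():
        return pd.to_numeric(df[outcome], errors="coerce")
    zcol = {"wasted": "whz", "stunted": "haz"}.get(outcome)
    if zcol is None or zcol not in df.columns:
        raise KeyError(f"cannot derive outcome {outcome!r}")
    return pd.Series(classify_undernutrition(df[zcol].to_numpy(float), cutoff), index=df.index)


def build_design(dataset: SurveyDataset | pd.DataFrame, exposure: pd.DataFrame,
                 geography, variant: str = "B", outcome: str = "wasted",
                 cutoff: float = -2.0, standardize: bool = True,
                 december: str = "Jilal", drop_constant: bool = True) -> DesignMatrix:
    """Assemble the model design for variant A (no conflict) or B (conflict).

    Variant A excludes the conflict indicators and every interaction involving
    them; variant B includes recent/longer-term indicators plus the full
    interaction set.  Continuous covariates are standardised (recorded in
    ``transforms`` for back-reporting); interactions are products of centered
    parents.  Records missing any model covariate are dropped with a logged
    count.  Constant columns are dropped (the intercept is separate).
    """
    if variant not in ("A", "B"):
        raise ValueError(f"unknown model variant {variant!r}")
    df = dataset.records.copy() if isinstance(dataset, SurveyDataset) else dataset.copy()
    df["survey_date"] = pd.to_datetime(df["survey_date"])
    df["season"] = [season_of(d, december) for d in df["survey_date"]]

    cov = geography.covariates
    df = df.merge(cov, on=["cluster_id", "season"], how="left", validate="m:1")
    exp = exposure.copy()
    exp["survey_date"] = pd.to_datetime(exp["survey_date"])
    df = df.merge(exp[["cluster_id", "survey_date", "recent_any", "longer_any"]],
                  on=["cluster_id", "survey_date"], how="left", validate="m:1")
    missing_exp = df["recent_any"].isna()
    if missing_exp.any():
        missing = df.loc[missing_exp, "cluster_id"].iloc[0]
        raise ValueError(f"no exposure entry for cluster {missing!r} "
                         f"(cluster/survey pair absent from exposure matrix)")

    y = _derive_outcome(df, outcome, cutoff)

    cols: dict[str, pd.Series] = {}
    for lv in ("pastoral", "riverine", "urban", "idp"):
        cols[f"livelihood_{lv}"] = (df["livelihood"] == lv).astype(float)
    for c in ("vitamin_a", "measles_vax", "polio_vax", "diarrhoea", "ari",
              "fever", "suspected_measles", "female_head",
              "carbohydrate", "protein", "fats", "fruits_veg"):
        cols[c] = pd.to_numeric(df[c], errors="coerce")
    cols["sex_female"] = (df["sex"] == "female").astype(float)
    age = pd.to_numeric(df["age_months"], errors="coerce")
    cols["age_12_23"] = ((age >= 12) & (age < 24)).astype(float)
    cols["age_24_59"] = (age >= 24).astype(float)
    for c in ("household_size", "n_under5", "mother_age", "mother_muac"):
        cols[c] = pd.to_numeric(df[c], errors="coerce")
    for s in SEASONS[1:]:
        cols[f"season_{s.lower()}"] = (df["season"] == s).astype(float)
    for c in ("distance_to_water", "evi", "rainfall", "temperature", "urbanisation"):
        cols[c] = pd.to_numeric(df[c], errors="coerce")
    if variant == "B":
        cols["recent_conflict"] = df["recent_any"].astype(float)
        cols["longer_conflict"] = df["longer_any"].astype(float)

    design_df = pd.DataFrame(cols, index=df.index)
    keep = design_df.notna().all(axis=1) & y.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropping %d records with missing covariates/outcome", n_dropped)
    design_df = design_df.loc[keep]
    y = y.loc[keep].to_numpy(float)
    df = df.loc[keep]

    transforms: dict[str, tuple[float, float]] = {}
    if standardize:
        for c in CONTINUOUS_COLS:
            vals = design_df[c]
            sd = float(vals.std(ddof=0))
            if sd > 0:
                transforms[c] = (float(vals.mean()), sd)
                design_df[c] = (vals - vals.mean()) / sd

    interactions: dict[str, tuple] = {}
    if variant == "B":
        for pa, pb in INTERACTION_PAIRS:
            ca, cb = float(design_df[pa].mean()), float(design_df[pb].mean())
            name = f"{pa}:{pb}"
            design_df[name] = (design_df[pa] - ca) * (design_df[pb] - cb)
            interactions[name] = (pa, pb, ca, cb)

    dropped_constant = [c for c in design_df.columns
                        if design_df[c].nunique(dropna=True) <= 1] if drop_constant else []
    if dropped_constant:
        log.warning("dropping constant design columns: %s", dropped_constant)
        design_df = design_df.drop(columns=dropped_constant)
        interactions = {k: v for k, v in interactions.items() if k not in dropped_constant}

    design_df.insert(0, "intercept", 1.0)

    cluster_ids = sorted(df["cluster_id"].unique())
    district_ids = sorted(df["district_id"].unique())
    t_index, round_dates = _assign_rounds(df["survey_date"])
    c_index = {c: i for i, c in enumerate(cluster_ids)}
    d_index = {d: i for i, d in enumerate(district_ids)}

    return DesignMatrix(
        X=design_df.to_numpy(float),
        columns=list(design_df.columns),
        y=y,
        cluster_codes=df["cluster_id"].map(c_index).to_numpy(int),
        district_codes=df["district_id"].map(d_index).to_numpy(int),
        round_codes=df["survey_date"].map(t_index).to_numpy(int),
        cluster_ids=cluster_ids,
        district_ids=district_ids,
        round_dates=[pd.Timestamp(t) for t in round_dates],
        variant=variant,
        outcome=outcome,
        transforms=transforms,
        interactions=interactions,
        n_dropped_missing=n_dropped,
        dropped_constant=dropped_constant,
    )


# ---------------------------------------------------------------------------
# Priors, posterior container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Gamma(shape, rate) hyperpriors on all precisions; Gaussian fixed-effect
    prior with the given precision."""

    tau_shape: float = 1.0
    tau_rate: float = 5e-4
    beta_precision: float = 1e-4

    def __post_init__(self):
        if self.tau_shape <= 0 or self.tau_rate <= 0 or self.beta_precision <= 0:
            raise ValueError("prior parameters must be positive")


@dataclass
class Posterior:
    """Retained MCMC draws of all model blocks plus draw metadata."""

    beta: np.ndarray                 # (S, p)
    columns: list[str]
    u: np.ndarray | None             # (S, n_clusters)
    v: np.ndarray | None
    w: np.ndarray | None             # (S, n_rounds)
    d: np.ndarray | None             # (S, n_districts)
    tau: dict                        # name -> (S,)
    chain: np.ndarray                # (S,)
    iteration: np.ndarray            # (S,)
    cluster_ids: list
    district_ids: list
    random_effects: tuple

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def linear_predictor(self, design: DesignMatrix, max_draws: int | None = None,
                         X: np.ndarray | None = None) -> np.ndarray:
        """(draws x records) linear predictor; optionally a modified X."""
        sel = slice(None)
        if max_draws is not None and self.n_draws > max_draws:
            step = int(np.ceil(self.n_draws / max_draws))
            sel = slice(None, None, step)
        X = design.X if X is None else X
        eta = self.beta[sel] @ X.T
        if self.u is not None:
            eta += self.u[sel][:, design.cluster_codes]
        if self.v is not None:
            eta += self.v[sel][:, design.cluster_codes]
        if self.w is not None:
            eta += self.w[sel][:, design.round_codes]
        if self.d is not None:
            eta += self.d[sel][:, design.district_codes]
        return eta

    def fitted_probabilities(self, design: DesignMatrix, max_draws: int | None = 400,
                             X: np.ndarray | None = None) -> np.ndarray:
        """Posterior mean of expit(linear predictor), per record."""
        eta = self.linear_predictor(design, max_draws=max_draws, X=X)
        return _expit(eta).mean(axis=0)

    def diagnostics(self) -> pd.DataFrame:
        """Split-Rhat and effective sample size per fixed-effect coefficient."""
        rows = []
        chains = np.unique(self.chain)
        for j, name in enumerate(self.columns):
            per_chain = [self.beta[self.chain == c, j] for c in chains]
            m = min(len(x) for x in per_chain)
            stacked = np.stack([x[:m] for x in per_chain])
            rows.append({"term": name,
                         "rhat": split_rhat(stacked),
                         "ess": effective_sample_size(stacked)})
        return pd.DataFrame(rows)


def _expit(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# GMRF helpers
# ---------------------------------------------------------------------------

def sample_gmrf(precision: np.ndarray, rhs: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Draw from N(precision^-1 rhs, precision^-1) via Cholesky."""
    chol = np.linalg.cholesky(precision)
    mean = np.linalg.solve(precision, rhs)
    z = rng.standard_normal(len(rhs))
    return mean + np.linalg.solve(chol.T, z)


def icar_draw(Q: np.ndarray, tau: float, components: list[np.ndarray],
              rng: np.random.Generator) -> np.ndarray:
    """Draw u ~ ICAR(tau) on structure matrix Q, sum-to-zero per component.

    Sampled in the spectral domain: independent normals with variance
    1/(tau * lambda_k) on the non-null eigenvectors of each component's block,
    which enforces the sum-to-zero constraint exactly.  ``tau = inf`` returns
    zeros.
    """
    n = Q.shape[0]
    if not np.isfinite(tau):
        return np.zeros(n)
    if tau <= 0:
        raise ValueError("tau must be positive")
    u = np.zeros(n)
    for comp in components:
        if len(comp) < 2:
            continue
        block = Q[np.ix_(comp, comp)]
        lam, vec = np.linalg.eigh(block)
        keep = lam > 1e-10
        z = rng.standard_normal(int(keep.sum()))
        u[comp] = vec[:, keep] @ (z / np.sqrt(tau * lam[keep]))
    return u


def _rw1_structure(T: int) -> np.ndarray:
    R = np.zeros((T, T))
    for t in range(T - 1):
        R[t, t] += 1.0
        R[t + 1, t + 1] += 1.0
        R[t, t + 1] -= 1.0
        R[t + 1, t] -= 1.0
    return R


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat of an (n_chains, n_draws) array."""
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    splits = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    w = splits.var(axis=1, ddof=1).mean()
    b = half * splits.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chains: np.ndarray) -> float:
    """Effective sample size via the initial-monotone-sequence estimator."""
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if n < 4:
        return float(m * n)
    centered = chains - chains.mean(axis=1, keepdims=True)
    acov = np.empty((m, n))
    for c in range(m):
        full = np.correlate(centered[c], centered[c], mode="full")[n - 1:]
        acov[c] = full / n
    var0 = acov[:, 0].mean()
    if var0 == 0:
        return float(m * n)
    rho = acov.mean(axis=0) / var0
    # pair sums; stop at first negative, enforce monotonicity
    tau_sum = 0.0
    prev = np.inf
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else rho[2 * k - 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        prev = pair
        tau_sum += pair
    tau_int = 1.0 + 2.0 * tau_sum
    return float(m * n / max(tau_int, 1.0))


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

ALL_RANDOM_EFFECTS = ("icar", "iid_cluster", "temporal", "district")


def fit_model(design: DesignMatrix, adjacency: AdjacencyGraph | None = None,
              priors: PriorSpec | None = None,
              chains: int = 2, iterations: int = 2000, burnin: int = 1000,
              thinning: int = 2, seed: int = 0,
              random_effects: tuple = ALL_RANDOM_EFFECTS) -> Posterior:
    """Fit the hierarchical logistic model by Polya-Gamma Gibbs sampling.

    ``random_effects`` selects which latent blocks are active; an empty tuple
    gives a plain Bayesian logistic regression.  All randomness derives from
    ``seed``; identical inputs give bitwise-identical posteriors.
    """
    priors = priors or PriorSpec()
    if iterations <= burnin:
        raise ValueError("iterations must exceed burn-in")
    unknown = set(random_effects) - set(ALL_RANDOM_EFFECTS)
    if unknown:
        raise ValueError(f"unknown random effect blocks: {sorted(unknown)}")
    use_u = "icar" in random_effects
    use_v = "iid_cluster" in random_effects
    use_w = "temporal" in random_effects
    use_d = "district" in random_effects

    X, y = design.X, design.y
    n, p = X.shape
    kappa = y - 0.5
    ci, di, ti = design.cluster_codes, design.district_codes, design.round_codes
    nc, nd, nt = len(design.cluster_ids), len(design.district_ids), len(design.round_dates)

    if use_u:
        if adjacency is None:
            raise ValueError("ICAR block requested but no adjacency supplied")
        missing = set(design.cluster_ids) - set(adjacency.nodes)
        if missing:
            raise ValueError(f"adjacency lacks clusters in design: {sorted(missing)[:3]}")
        if nc < 2:
            raise ValueError("ICAR is undefined on a single cluster")
        Q = adjacency.structure_matrix(order=design.cluster_ids)
        pos = {c: i for i, c in enumerate(design.cluster_ids)}
        comps = []
        for comp in adjacency.components():
            idx = [pos[c] for c in comp if c in pos]
            if idx:
                comps.append(np.array(sorted(idx)))
        n_comp = len(comps)
    if use_w and nt < 2:
        use_w = False
    R = _rw1_structure(nt) if use_w else None
    # w is sampled jointly with beta: calendar covariates (seasons) can be
    # nearly collinear with the round walk, and separate blocks then mix at
    # a crawl; one Gaussian block removes that entirely.  The sum-to-zero
    # constraint is restored by shifting the mean into the intercept.
    if use_w:
        W_ind = np.zeros((n, nt))
        W_ind[np.arange(n), ti] = 1.0
        X_joint = np.hstack([X, W_ind])
        try:
            intercept_idx = design.columns.index("intercept")
        except ValueError:
            intercept_idx = None

    prior_prec = np.eye(p) * priors.beta_precision
    a0, b0 = priors.tau_shape, priors.tau_rate

    keep_per_chain = (iterations - burnin) // thinning
    S = keep_per_chain * chains
    out_beta = np.empty((S, p))
    out_u = np.empty((S, nc)) if use_u else None
    out_v = np.empty((S, nc)) if use_v else None
    out_w = np.empty((S, nt)) if use_w else None
    out_d = np.empty((S, nd)) if use_d else None
    out_tau = {name: np.empty(S) for name, used in
               (("tau_u", use_u), ("tau_v", use_v), ("tau_w", use_w), ("tau_d", use_d))
               if used}
    out_chain = np.empty(S, dtype=int)
    out_iter = np.empty(S, dtype=int)

    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)

    s_out = 0
    for chain_id in range(chains):
        rng = np.random.default_rng(chain_seeds[chain_id])
        beta = np.zeros(p)
        u = np.zeros(nc)
        v = np.zeros(nc)
        w = np.zeros(nt)
        dvec = np.zeros(nd)
        tau_u = tau_v = tau_w = tau_d = 1.0

        for it in range(iterations):
            eta = X @ beta + u[ci] + v[ci] + w[ti] + dvec[di]
            omega = random_polyagamma(eta, rng)

            if use_w:
                offset = u[ci] + v[ci] + dvec[di]
                prec = X_joint.T @ (X_joint * omega[:, None])
                prec[:p, :p] += prior_prec
                prec[p:, p:] += tau_w * R + 1e-10 * np.eye(nt)
                rhs = X_joint.T @ (kappa - omega * offset)
                draw = sample_gmrf(prec, rhs, rng)
                beta, w = draw[:p], draw[p:]
                if intercept_idx is not None:
                    shift = w.mean()
                    w = w - shift
                    beta[intercept_idx] += shift
                tau_w = rng.gamma(a0 + 0.5 * (nt - 1),
                                  1.0 / (b0 + 0.5 * float(w @ R @ w)))
            else:
                offset = u[ci] + v[ci] + w[ti] + dvec[di]
                prec = X.T @ (X * omega[:, None]) + prior_prec
                rhs = X.T @ (kappa - omega * offset)
                beta = sample_gmrf(prec, rhs, rng)
            if not np.all(np.isfinite(beta)):
                raise RuntimeError(f"non-finite beta update at chain {chain_id}, "
                                   f"iteration {it}")
            xb = X @ beta

            if use_u:
                resid = kappa - omega * (xb + v[ci] + w[ti] + dvec[di])
                Dc = np.bincount(ci, weights=omega, minlength=nc)
                rc = np.bincount(ci, weights=resid, minlength=nc)
                u = sample_gmrf(tau_u * Q + np.diag(Dc), rc, rng)
                for comp in comps:
                    u[comp] -= u[comp].mean()
                quad = float(u @ Q @ u)
                tau_u = rng.gamma(a0 + 0.5 * (nc - n_comp), 1.0 / (b0 + 0.5 * quad))
            if use_v:
                resid = kappa - omega * (xb + u[ci] + w[ti] + dvec[di])
                Dc = np.bincount(ci, weights=omega, minlength=nc)
                rc = np.bincount(ci, weights=resid, minlength=nc)
                var = 1.0 / (tau_v + Dc)
                v = var * rc + np.sqrt(var) * rng.standard_normal(nc)
                tau_v = rng.gamma(a0 + 0.5 * nc, 1.0 / (b0 + 0.5 * float(v @ v)))
            if use_d:
                resid = kappa - omega * (xb + u[ci] + v[ci] + w[ti])
                Dd = np.bincount(di, weights=omega, minlength=nd)
                rd = np.bincount(di, weights=resid, minlength=nd)
                var = 1.0 / (tau_d + Dd)
                dvec = var * rd + np.sqrt(var) * rng.standard_normal(nd)
                tau_d = rng.gamma(a0 + 0.5 * nd, 1.0 / (b0 + 0.5 * float(dvec @ dvec)))

            if it >= burnin and (it - burnin) % thinning == 0:
                out_beta[s_out] = beta
                if use_u:
                    out_u[s_out] = u
                    out_tau["tau_u"][s_out] = tau_u
                if use_v:
                    out_v[s_out] = v
                    out_tau["tau_v"][s_out] = tau_v
                if use_w:
                    out_w[s_out] = w
                    out_tau["tau_w"][s_out] = tau_w
                if use_d:
                    out_d[s_out] = dvec
                    out_tau["tau_d"][s_out] = tau_d
                out_chain[s_out] = chain_id
                out_iter[s_out] = it
                s_out += 1

    return Posterior(
        beta=out_beta[:s_out], columns=list(design.columns),
        u=out_u[:s_out] if use_u else None,
        v=out_v[:s_out] if use_v else None,
        w=out_w[:s_out] if use_w else None,
        d=out_d[:s_out] if use_d else None,
        tau={k: a[:s_out] for k, a in out_tau.items()},
        chain=out_chain[:s_out], iteration=out_iter[:s_out],
        cluster_ids=list(design.cluster_ids),
        district_ids=list(design.district_ids),
        random_effects=tuple(
            b for b, used in zip(ALL_RANDOM_EFFECTS, (use_u, use_v, use_w, use_d)) if used),
    )


# ---------------------------------------------------------------------------
# Effect summaries
# ---------------------------------------------------------------------------

def _unit_scale_divisor(name: str, design: DesignMatrix) -> float:
    """Scale factor turning a standardized coefficient into per-unit."""
    if name in design.transforms:
        return design.transforms[name][1]
    if name in design.interactions:
        pa, pb, _, _ = design.interactions[name]
        return _unit_scale_divisor(pa, design) * _unit_scale_divisor(pb, design)
    return 1.0


def summarize_effects(posterior: Posterior, design: DesignMatrix,
                      unit_scale: bool = True, ci_level: float = 0.95) -> pd.DataFrame:
    """Odds-ratio table: posterior median OR with equal-tailed credible
    interval per coefficient; ``significant`` iff the interval excludes 1.

    With ``unit_scale`` standardized coefficients are back-transformed to the
    per-unit scale recorded at design construction.
    """
    if posterior.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarise")
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    rows = []
    for j, name in enumerate(posterior.columns):
        draws = posterior.beta[:, j]
        if unit_scale:
            draws = draws / _unit_scale_divisor(name, design)
        # per-unit ORs of small-sd covariates can overflow to inf; that is
        # the mathematically correct value on this scale
        with np.errstate(over="ignore"):
            orv = np.exp(np.median(draws))
            lo, hi = np.exp(np.quantile(draws, [lo_q, hi_q]))
        rows.append({
            "term": name,
            "or": float(orv),
            "ci_lo": float(lo),
            "ci_hi": float(hi),
            "significant": bool(lo > 1.0 or hi < 1.0),
        })
    return pd.DataFrame(rows)
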