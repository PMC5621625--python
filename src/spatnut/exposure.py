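"""Conflict-event classification, temporal windowing and exposure linkage.

Events carry one of nine source type labels and are grouped into four analysis
classes.  Exposure of a (cluster, survey date) pair is determined by linking
events spatially (same district by default, or a distance buffer around the
cluster centroid) and temporally: events strictly less than ~3 months before
the survey count as *recent*, events 3-12 months before as *longer term*.
Months are operationalised as days with half-open windows [0, 91) and
[91, 366) so the arithmetic is unambiguous and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ACLED_TYPES",
    "CONFLICT_CLASSES",
    "DEFAULT_CLASS_MAP",
    "DEFAULT_WINDOWS",
    "normalize_acled_type",
    "classify_event_type",
    "window_exposure",
    "build_exposure_matrix",
    "summarize_events",
]

#: closed nine-label source vocabulary (canonical spellings)
ACLED_TYPES = (
    "battle - no change of territory",
    "battle - non-state actor overtakes territory",
    "battle - government regains territory",
    "headquarters or base established",
    "strategic development",
    "riots or protests",
    "violence against civilians",
    "non-violent transfer of territory",
    "remote violence",
)

CONFLICT_CLASSES = ("battle", "remote_violence", "violence_against_civilians", "other")

#: nine source labels -> four analysis classes.  The three battle subtypes map
#: to battle; remote violence and violence against civilians map to their
#: namesakes; everything else (base establishment, strategic development,
#: riots/protests, non-violent transfers) is "other".  Overridable in config.
DEFAULT_CLASS_MAP = {
    "battle - no change of territory": "battle",
    "battle - non-state actor overtakes territory": "battle",
    "battle - government regains territory": "battle",
    "headquarters or base established": "other",
    "strategic development": "other",
    "riots or protests": "other",
    "violence against civilians": "violence_against_civilians",
    "non-violent transfer of territory": "other",
    "remote violence": "remote_violence",
}


class VocabularyError(ValueError):
    """Event type label outside the closed nine-label vocabulary."""


def _label_key(label: str) -> str:
    """Reduce a type label to alphanumeric words for dialect-tolerant matching."""
    out = []
    for ch in str(label).lower():
        out.append(ch if ch.isalnum() else " ")
    words = "".join(out).split()
    # common connective variants ("riots/protests" vs "riots or protests")
    return " ".join(w for w in words if w not in ("or", "and", "of", "the"))


_CANONICAL_BY_KEY = {_label_key(t): t for t in ACLED_TYPES}


def normalize_acled_type(label: str) -> str:
    """Canonical nine-label spelling for a (possibly variant) type label.

    Raises :class:`VocabularyError` when the label is not recognisably one of
    the nine types.
    """
    key = _label_key(label)
    if key not in _CANONICAL_BY_KEY:
        raise VocabularyError(f"unknown conflict event type: {label!r}")
    return _CANONICAL_BY_KEY[key]


@dataclass(frozen=True)
class ExposureWindows:
    """Half-open day-offset windows (survey date minus event date)."""

    recent_lo: int = 0
    recent_hi: int = 91
    longer_hi: int = 366

    def __post_init__(self):
        if not (self.recent_lo < self.recent_hi < self.longer_hi):
            raise ValueError("windows must satisfy recent_lo < recent_hi < longer_hi")


DEFAULT_WINDOWS = ExposureWindows()


def classify_event_type(acled_type: str, class_map: dict | None = None) -> str:
    """Map a nine-label event type onto its four-class analysis group."""
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    canonical = normalize_acled_type(acled_type)
    if canonical not in class_map:
        raise VocabularyError(f"no class mapping for event type: {canonical!r}")
    return class_map[canonical]


def window_exposure(event_date, survey_date, windows: ExposureWindows = DEFAULT_WINDOWS) -> str:
    """Classify one event relative to one survey date: recent / longer / none.

    Delta = survey_date - event_date in days; [0, 91) days is recent,
    [91, 366) longer term, anything else (including future events) none.
    """
    delta = (pd.Timestamp(survey_date) - pd.Timestamp(event_date)).days
    if windows.recent_lo <= delta < windows.recent_hi:
        return "recent"
    if windows.recent_hi <= delta < windows.longer_hi:
        return "longer"
    return "none"


def _linked_clusters(event_row, geography: pd.DataFrame, linkage: str, buffer_km: float):
    if linkage == "district":
        return geography.loc[geography["district_id"] == event_row["district_id"], "cluster_id"]
    # buffer linkage: great-circle distance to cluster centroids
    if geography[["lon", "lat"]].isna().any().any():
        bad = geography.loc[geography[["lon", "lat"]].isna().any(axis=1), "cluster_id"].iloc[0]
        raise ValueError(f"buffer linkage requires centroids; cluster {bad!r} has none")
    d = _haversine_km(event_row["lon"], event_row["lat"],
                      geography["lon"].to_numpy(), geography["lat"].to_numpy())
    return geography.loc[d <= buffer_km, "cluster_id"]


def _haversine_km(lon1, lat1, lon2, lat2):
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * 6371.0 * np.arcsin(np.sqrt(a))


def build_exposure_matrix(events: pd.DataFrame, geography: pd.DataFrame,
                          survey_index: pd.DataFrame,
                          linkage: str = "district", buffer_km: float = 10.0,
                          windows: ExposureWindows = DEFAULT_WINDOWS,
                          class_map: dict | None = None) -> pd.DataFrame:
    """Per (cluster_id, survey_date) recent / longer-term exposure indicators.

    Parameters
    ----------
    events : table with event_date, district_id and/or (lon, lat), acled_type.
    geography : cluster table with cluster_id, district_id and centroids.
    survey_index : distinct (cluster_id, survey_date) pairs needing exposure.
    linkage : "district" links an event to every cluster of its district;
        "buffer" links to clusters within ``buffer_km`` of the centroid.

    Returns a frame keyed by (cluster_id, survey_date) with binary
    ``recent_any`` / ``longer_any``, event counts, and per-class indicators.
    An exposure value depends only on events dated strictly before the survey.
    """
    if linkage not in ("district", "buffer"):
        raise ValueError(f"unknown linkage rule: {linkage!r}")
    pairs = survey_index[["cluster_id", "survey_date"]].drop_duplicates().copy()
    pairs["survey_date"] = pd.to_datetime(pairs["survey_date"])

    cols: dict[str, np.ndarray] = {}
    n = len(pairs)
    for win in ("recent", "longer"):
        cols[f"{win}_count"] = np.zeros(n, dtype=int)
        for cls in CONFLICT_CLASSES:
            cols[f"{win}_{cls}"] = np.zeros(n, dtype=int)

    if len(events):
        ev = events.copy()
        ev["event_date"] = pd.to_datetime(ev["event_date"])
        ev["conflict_class"] = [classify_event_type(t, class_map) for t in ev["acled_type"]]
        pair_pos = {(c, d): i for i, (c, d) in
                    enumerate(zip(pairs["cluster_id"], pairs["survey_date"]))}
        survey_dates = np.sort(pairs["survey_date"].unique())
        for _, event in ev.iterrows():
            clusters = _linked_clusters(event, geography, linkage, buffer_km)
            if clusters.empty:
                continue
            for sdate in survey_dates:
                win = window_exposure(event["event_date"], sdate, windows)
                if win == "none":
                    continue
                for cid in clusters:
                    pos = pair_pos.get((cid, pd.Timestamp(sdate)))
                    if pos is None:
                        continue
                    cols[f"{win}_count"][pos] += 1
                    cols[f"{win}_{event['conflict_class']}"][pos] += 1

    out = pairs.reset_index(drop=True)
    out["recent_any"] = (cols["recent_count"] > 0).astype(int)
    out["longer_any"] = (cols["longer_count"] > 0).astype(int)
    out["recent_count"] = cols["recent_count"]
    out["longer_count"] = cols["longer_count"]
    for win in ("recent", "longer"):
        for cls in CONFLICT_CLASSES:
            out[f"{win}_{cls}"] = (cols[f"{win}_{cls}"] > 0).astype(int)
    return out


def summarize_events(events: pd.DataFrame, geography: pd.DataFrame | None = None,
                     class_map: dict | None = None) -> pd.DataFrame:
    """Descriptive per-region class counts with totals and percentages.

    Region comes from the event's district via ``geography`` when the event
    table has no region column.  The totals row carries the grand total and
    each class's share of all events as a percentage rounded to the nearest
    integer.
    """
    ev = events.copy()
    ev["conflict_class"] = [classify_event_type(t, class_map) for t in ev["acled_type"]]
    if "region_id" not in ev.columns:
        if geography is None:
            raise ValueError("need geography to resolve event regions")
        d2r = geography.drop_duplicates("district_id").set_index("district_id")["region_id"]
        ev["region_id"] = ev["district_id"].map(d2r)

    counts = (ev.pivot_table(index="region_id", columns="conflict_class",
                             aggfunc="size", fill_value=0)
              .reindex(columns=list(CONFLICT_CLASSES), fill_value=0))
    counts["total"] = counts.sum(axis=1)
    total_row = counts.sum(axis=0)
    counts.loc["Total"] = total_row
    grand = int(total_row["total"])
    pct = {cls: int(round(100.0 * total_row[cls] / grand)) if grand else np.nan
           for cls in CONFLICT_CLASSES}
    pct["total"] = 100 if grand else np.nan
    counts.loc["pct"] = pd.Series(pct)
    return counts.reset_index(names="region_id")
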