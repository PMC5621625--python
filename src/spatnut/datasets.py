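"""Bundled example data: published per-region aggregates for Somalia 2007-2010.

The 2007-2010 FSNAU nutrition-survey microdata and the matching ACLED conflict
extract are not publicly deposited, but the per-region aggregates (cluster and
child counts, stunting/wasting counts, and conflict-event counts by class) are
published.  They are re-entered here as a worked-example fixture so the
descriptive operations can be exercised end-to-end and checked against the
printed totals.

``region_summary_to_children`` and ``region_summary_to_events`` expand the
aggregates into synthetic record-level tables that reproduce the counts
exactly, so the *same code paths* used for record-level analysis produce the
descriptive tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "somalia_region_summary",
    "region_summary_to_children",
    "region_summary_to_events",
]

# zone, region, clusters, children, stunted, wasted, battle, remote violence,
# violence against civilians, other
_REGION_ROWS = [
    ("North East", "Bari", 9, 756, 201, 174, 16, 7, 21, 3),
    ("North East", "Mudug", 61, 6188, 804, 1055, 14, 3, 21, 3),
    ("North East", "Nugaal", 24, 1673, 383, 322, 6, 2, 8, 1),
    ("North West", "Awdal", 26, 862, 7, 177, 2, 0, 5, 0),
    ("North West", "Sanaag", 14, 412, 3, 97, 4, 0, 6, 0),
    ("North West", "Sool", 3, 142, 18, 24, 8, 0, 11, 8),
    ("North West", "Togdheer", 12, 673, 362, 124, 9, 0, 8, 1),
    ("North West", "Woqooyi Galbeed", 23, 2465, 1378, 480, 5, 0, 19, 3),
    ("South-Central", "Bakool", 75, 3534, 1150, 1330, 7, 1, 4, 8),
    ("South-Central", "Banadir", 1, 51, 0, 11, 366, 74, 123, 31),
    ("South-Central", "Bay", 98, 5568, 2133, 1798, 31, 0, 29, 14),
    ("South-Central", "Galgaduud", 77, 5831, 1908, 879, 36, 2, 11, 6),
    ("South-Central", "Gedo", 111, 6985, 1999, 2616, 11, 0, 7, 13),
    ("South-Central", "Hiraan", 142, 10743, 2260, 2085, 48, 3, 33, 10),
    ("South-Central", "Juba Dhexe", 77, 5253, 2734, 960, 9, 0, 4, 1),
    ("South-Central", "Juba Hoose", 71, 5560, 1553, 926, 26, 1, 20, 13),
    ("South-Central", "Shabelle Dhexe", 101, 7650, 2414, 1322, 22, 0, 16, 11),
    ("South-Central", "Shabelle Hoose", 141, 9432, 3432, 1355, 140, 16, 47, 7),
]

_COLUMNS = ["zone", "region_id", "n_clusters", "n_children", "n_stunted",
            "n_wasted", "battle", "remote_violence",
            "violence_against_civilians", "other"]

#: a representative nine-label type for each analysis class, used when
#: expanding class counts back into typed event rows
_CLASS_REPRESENTATIVE = {
    "battle": "battle - no change of territory",
    "remote_violence": "remote violence",
    "violence_against_civilians": "violence against civilians",
    "other": "strategic development",
}


def somalia_region_summary() -> pd.DataFrame:
    """The published 18-region survey and conflict aggregates, 2007-2010."""
    return pd.DataFrame(_REGION_ROWS, columns=_COLUMNS)


def region_summary_to_children(summary: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expand per-region aggregates into a child-level table.

    One row per examined child with region, a synthetic cluster id (the stated
    number of distinct clusters per region) and binary stunted/wasted flags
    reproducing the stated counts.  Outcome flags are assigned independently,
    which preserves every marginal count in the aggregates.
    """
    summary = somalia_region_summary() if summary is None else summary
    frames = []
    for _, row in summary.iterrows():
        n = int(row["n_children"])
        n_clusters = int(row["n_clusters"])
        stunted = np.zeros(n, dtype=int)
        stunted[: int(row["n_stunted"])] = 1
        wasted = np.zeros(n, dtype=int)
        wasted[: int(row["n_wasted"])] = 1
        clusters = [f"{row['region_id']}-c{i % n_clusters:04d}" for i in range(n)]
        frames.append(pd.DataFrame({
            "zone": row["zone"],
            "region_id": row["region_id"],
            "cluster_id": clusters,
            "stunted": stunted,
            "wasted": wasted,
        }))
    return pd.concat(frames, ignore_index=True)


def region_summary_to_events(summary: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expand per-region class counts into a typed event-level table.

    Each aggregated count becomes that many rows carrying a representative
    nine-label type for the class, so classification and summarisation run
    through the ordinary event code path.
    """
    summary = somalia_region_summary() if summary is None else summary
    rows = []
    for _, srow in summary.iterrows():
        for cls, label in _CLASS_REPRESENTATIVE.items():
            for i in range(int(srow[cls])):
                rows.append({
                    "event_id": f"{srow['region_id']}-{cls}-{i:03d}",
                    "event_date": "2008-06-15",
                    "region_id": srow["region_id"],
                    "district_id": srow["region_id"],
                    "acled_type": label,
                })
    return pd.DataFrame(rows)
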