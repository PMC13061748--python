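"""Bundled reference tables from the 12-site *Astragalus verus* dieback
survey of central Iranian rangelands that this pipeline re-implements.

The original stem maps are not deposited, but the survey's site-level
summaries are published and serve here as worked-example inputs: per-site
individual counts and richness, focal-species live/dead counts, reported
dieback percentages, site metadata, and the reported diversity-index values
(useful as cross-checks for the index implementations, since several indices
depend only on quantities the summary table prints).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["site_counts", "reported_diversity", "group_labels"]

# site_id -> group of the original design: five western (G1), three southern
# (G2), four eastern (G3) sites.
_GROUPS = {
    1: "G1", 5: "G1", 6: "G1", 11: "G1", 12: "G1",
    2: "G2", 3: "G2", 4: "G2",
    7: "G3", 8: "G3", 9: "G3", 10: "G3",
}

# Per-site counts: total individuals, richness, focal-species totals and
# live/dead split, plus elevation (m), mean annual temperature (deg C),
# aspect, and the reported dieback percentage.
_SITE_ROWS = [
    # site, n_total, richness, focal_total, focal_live, focal_dead,
    # elevation, mat, aspect, dieback_pct
    (1, 72, 9, 13, 7, 4, 2415, 11.7, "W", 30.7),
    (2, 107, 7, 85, 44, 41, 2691, 15.1, "NE", 48.2),
    (3, 182, 15, 40, 21, 19, 2642, 15.1, "SE", 47.5),
    (4, 121, 5, 25, 11, 14, 2631, 12.9, "NE", 56.0),
    (5, 343, 13, 181, 130, 51, 2297, 12.9, "NW", 28.2),
    (6, 190, 10, 62, 40, 22, 2352, 12.9, "E", 35.5),
    (7, 169, 12, 28, 3, 25, 2474, 17.4, "NE", 89.3),
    (8, 219, 14, 29, 9, 20, 2366, 17.4, "S", 69.0),
    (9, 297, 12, 24, 6, 18, 2364, 15.3, "S", 75.0),
    (10, 177, 16, 23, 6, 17, 2510, 15.3, "N", 73.9),
    (11, 284, 18, 48, 31, 17, 2330, 12.5, "W", 35.4),
    (12, 171, 17, 10, 2, 8, 2557, 12.5, "S", 80.0),
]

# Reported diversity indices per site (columns are site ids 1..12).
_DIVERSITY_ROWS = {
    "dominance": [0.24, 0.64, 0.19, 0.5, 0.32, 0.25, 0.22, 0.45, 0.41, 0.25, 0.12, 0.19],
    "simpson": [0.75, 0.35, 0.8, 0.49, 0.67, 0.74, 0.77, 0.54, 0.58, 0.74, 0.87, 0.8],
    "shannon": [1.64, 0.8, 1.92, 0.913, 1.56, 1.53, 1.77, 1.27, 1.422, 1.88, 2.37, 2.13],
    "evenness": [0.57, 0.32, 0.45, 0.49, 0.36, 0.46, 0.49, 0.25, 0.34, 0.41, 0.59, 0.49],
    "brillouin": [1.48, 0.72, 1.79, 0.85, 1.5, 1.45, 1.67, 1.18, 1.35, 1.75, 2.26, 1.98],
    "menhinick": [1.06, 0.67, 1.11, 0.45, 0.7, 0.72, 0.92, 0.94, 0.69, 1.2, 1.06, 1.3],
    "margalef": [1.87, 1.28, 2.69, 0.83, 2.05, 1.71, 2.14, 2.41, 1.93, 2.89, 3.0, 3.11],
    "equitability": [0.75, 0.41, 0.7, 0.56, 0.61, 0.66, 0.71, 0.48, 0.57, 0.67, 0.82, 0.75],
    "fisher_alpha": [2.71, 1.67, 3.87, 1.05, 2.67, 2.24, 2.95, 3.33, 2.5, 4.26, 4.27, 4.69],
    "berger_parker": [0.34, 0.79, 0.32, 0.66, 0.52, 0.33, 0.33, 0.65, 0.62, 0.46, 0.22, 0.37],
    "chao1": [10.5, 7, 20, 6, 14.5, 16, 13, 16.5, 13.5, 17.5, 18, 20],
}
_DIVERSITY_SITES = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]


def group_labels() -> dict[int, str]:
    """Site -> group map of the reference design."""
    return dict(_GROUPS)


def site_counts() -> pd.DataFrame:
    """Site-level summary of the reference survey, indexed by site_id.

    Columns: group, n_total, richness, focal_total, focal_live, focal_dead,
    elevation_m, mat_c, aspect, dieback_pct (the survey's reported value).
    """
    df = pd.DataFrame(
        _SITE_ROWS,
        columns=[
            "site_id", "n_total", "richness", "focal_total", "focal_live",
            "focal_dead", "elevation_m", "mat_c", "aspect", "dieback_pct",
        ],
    ).set_index("site_id")
    df.insert(0, "group", df.index.map(_GROUPS))
    return df


def reported_diversity() -> pd.DataFrame:
    """Reported diversity-index values, sites as rows, indices as columns."""
    return pd.DataFrame(_DIVERSITY_ROWS, index=pd.Index(_DIVERSITY_SITES, name="site_id"))
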