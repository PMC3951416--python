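"""Published summary data from the 2008 metropolitan-Tampa ovitrap survey.

These are transcriptions of printed summary tables from a three-city
(Tampa, St. Petersburg, Bradenton/Palmetto area) ovitrap survey of
*Aedes albopictus* (ALB), *Aedes aegypti* (AEG) and *Culex
quinquefasciatus* (CQ): 119 sites (100 urban grid cells, 19 cemeteries),
three traps per site, sampled in the early (June) and late (September)
rainy season. The raw trap-level counts were never deposited, so the
cross-tabulated occupancy counts and reported posterior means below are the
only public quantities; they serve as inputs for re-deriving the survey's
proportion-based statistics and coefficient interpretations.
"""

from __future__ import annotations

from .study_design import OCCUPANCY_CATEGORIES, OccupancyTable

#: total ovitraps deployed minus the 22 disturbed ones, across both seasons
TOTAL_UNDISTURBED_TRAPS = 692

# season totals of the published occupancy cross-tab:
# category -> (number of sites, number of individual traps)
_EARLY_COUNTS = {
    "ALB only": (0, 8),
    "AEG only": (18, 42),
    "CQ only": (17, 51),
    "ALB+AEG": (6, 9),
    "ALB+CQ": (4, 6),
    "AEG+CQ": (35, 46),
    "ALB+AEG+CQ": (12, 6),
    "none": (21, 118),
}
_LATE_COUNTS = {
    "ALB only": (14, 48),
    "AEG only": (26, 48),
    "CQ only": (18, 26),
    "ALB+AEG": (12, 17),
    "ALB+CQ": (4, 2),
    "AEG+CQ": (2, 1),
    "ALB+AEG+CQ": (7, 4),
    "none": (36, 217),
}

#: reported posterior-mean coefficients (log scale) of the seasonal /
#: co-occurrence abundance model, used for percent-change interpretation
POSTERIOR_MEANS = {
    "AEG": {"intercept": 1.48, "month": 0.82, "ALB_present": 0.35, "CQ_present": 0.55},
    "ALB": {"intercept": 0.99, "month": 1.42, "AEG_present": -0.05, "CQ_present": 0.49},
    "CQ": {"intercept": 4.27, "month": -0.68, "ALB_present": -0.07, "AEG_present": 0.03},
}


def published_occupancy_tables() -> dict[str, OccupancyTable]:
    """Season-total occupancy cross-tabs as :class:`OccupancyTable` objects.

    Early season: 113 sites / 286 wet traps (six all-dry sites excluded);
    late season: 119 sites / 347 wet traps. Proportions are recomputed from
    the category counts, not copied from the printed table.
    """
    tables = {}
    for season, counts, n_sites, n_traps in (
        ("early", _EARLY_COUNTS, 113, 286),
        ("late", _LATE_COUNTS, 119, 347),
    ):
        tables[season] = OccupancyTable(
            label=season,
            n_sites=n_sites,
            n_traps=n_traps,
            category_counts={cat: counts[cat] for cat in OCCUPANCY_CATEGORIES},
        )
    return tables
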