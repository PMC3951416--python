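"""Trap-level data handling, exclusion rules and occupancy summaries.

The sampling unit is an ovitrap: a water-filled cup sampled three times per
site in each of two rainy-season months (early = June, late = September).
Disturbed traps carry no usable information and are dropped; a site-season
whose remaining traps were all dry is removed entirely; otherwise the
response for each species is the mean count over valid (wet, undisturbed)
traps rounded half away from zero. Presence is defined at the site-season
level as any valid trap holding at least one larva.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPECIES = ("ALB", "AEG", "CQ")
ALL_SPECIES = SPECIES + ("OTHER",)
SEASONS = ("early", "late")
STATUSES = ("ok", "dry", "disturbed")
SITE_CLASSES = ("urban", "cemetery")

#: the eight mutually exclusive site occupancy categories, table order
OCCUPANCY_CATEGORIES = (
    "ALB only",
    "AEG only",
    "CQ only",
    "ALB+AEG",
    "ALB+CQ",
    "AEG+CQ",
    "ALB+AEG+CQ",
    "none",
)

#: default CSV column names for trap tables
DEFAULT_SCHEMA = {
    "city": "city",
    "site": "site",
    "site_class": "site_class",
    "season": "season",
    "trap": "trap",
    "status": "status",
    "count_alb": "count_alb",
    "count_aeg": "count_aeg",
    "count_cq": "count_cq",
    "count_other": "count_other",
}


@dataclass
class TrapObservation:
    """One ovitrap collection event."""

    city_id: str
    site_id: str
    site_class: str
    season: str
    trap_index: int
    counts: dict[str, int]
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown trap status {self.status!r}")
        for sp, c in self.counts.items():
            if sp not in ALL_SPECIES:
                raise ValueError(f"unknown species {sp!r}")
            if c != int(c) or c < 0:
                raise ValueError(f"count for {sp} must be a non-negative integer, got {c!r}")
            self.counts[sp] = int(c)

    @property
    def is_valid(self) -> bool:
        """True for traps contributing to the site mean (wet and intact)."""
        return self.status == "ok"


@dataclass
class SiteSeasonRecord:
    """Aggregated response unit: one site in one season.

    ``y[s]`` is the rounded mean count over valid traps for species ``s``
    and ``present[s]`` flags whether any valid trap held that species.
    """

    site_id: str
    city_id: str
    site_class: str
    season: str
    y: dict[str, int]
    present: dict[str, bool]
    n_valid_traps: int

    def __post_init__(self) -> None:
        if self.n_valid_traps < 1:
            raise ValueError("records require at least one valid trap")
        # presence with y == 0 is legal (a small mean can round down);
        # a positive rounded count for an absent species is not
        for sp, v in self.y.items():
            if v > 0 and not self.present[sp]:
                raise ValueError(f"positive rounded count for absent species {sp}")


def round_half_away(x) -> np.ndarray:
    """Round halves away from zero (2.5 -> 3, -2.5 -> -3).

    The rounding rule for site-mean responses, isolated here; numpy's default
    banker's rounding would send 2.5 to 2.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out.astype(np.int64) if out.ndim else int(out)


# ---------------------------------------------------------------------------
# reading / writing trap tables
# ---------------------------------------------------------------------------

def read_trap_table(path, schema: dict[str, str] | None = None) -> list[TrapObservation]:
    """Read a trap-level CSV into a list of :class:`TrapObservation`.

    ``schema`` maps the logical column roles of :data:`DEFAULT_SCHEMA` to
    the file's actual header names.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in schema.values() if c not in df.columns]
    if missing:
        raise KeyError(f"trap table is missing required columns: {missing}")
    obs = []
    count_cols = {sp: schema[f"count_{sp.lower()}"] for sp in ALL_SPECIES}
    for row in df.itertuples(index=False):
        r = dict(zip(df.columns, row))
        counts = {}
        for sp, col in count_cols.items():
            raw = r[col]
            try:
                counts[sp] = int(raw)
            except (TypeError, ValueError):
                raise ValueError(f"non-integer count {raw!r} in column {col}") from None
        obs.append(
            TrapObservation(
                city_id=str(r[schema["city"]]),
                site_id=str(r[schema["site"]]),
                site_class=str(r[schema["site_class"]]),
                season=str(r[schema["season"]]),
                trap_index=int(r[schema["trap"]]),
                counts=counts,
                status=str(r[schema["status"]]),
            )
        )
    return obs


def write_trap_table(traps: list[TrapObservation], path) -> None:
    """Write trap observations in the CSV dialect :func:`read_trap_table` reads."""
    rows = [
        {
            "city": t.city_id,
            "site": t.site_id,
            "site_class": t.site_class,
            "season": t.season,
            "trap": t.trap_index,
            "status": t.status,
            **{f"count_{sp.lower()}": t.counts.get(sp, 0) for sp in ALL_SPECIES},
        }
        for t in traps
    ]
    pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA.values())).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# exclusion rules and aggregation
# ---------------------------------------------------------------------------

def filter_and_aggregate(traps: list[TrapObservation]) -> list[SiteSeasonRecord]:
    """Apply exclusion rules and aggregate traps to site-season records.

    Disturbed traps are dropped outright. Dry traps are excluded from the
    mean's denominator (a dry cup cannot hold larvae) but do not remove the
    site; only a site-season whose traps are all dry (or all excluded)
    yields no record. The response is the per-species mean count over valid
    traps, rounded half away from zero.
    """
    key = lambda t: (t.city_id, t.site_id, t.season)
    records = []
    for (city, site, season), group in itertools.groupby(sorted(traps, key=key), key):
        group = list(group)
        idx = [t.trap_index for t in group]
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate trap_index within site {site!r} season {season!r}")
        valid = [t for t in group if t.is_valid]
        if not valid:
            continue
        y, present = {}, {}
        for sp in ALL_SPECIES:
            counts = np.array([t.counts.get(sp, 0) for t in valid], dtype=float)
            y[sp] = int(round_half_away(counts.mean()))
            present[sp] = bool((counts > 0).any())
        records.append(
            SiteSeasonRecord(
                site_id=site,
                city_id=city,
                site_class=group[0].site_class,
                season=season,
                y=y,
                present=present,
                n_valid_traps=len(valid),
            )
        )
    return records


def records_to_frame(records: list[SiteSeasonRecord]) -> pd.DataFrame:
    """Site-season records as a flat table ready for design-matrix assembly."""
    rows = []
    for r in records:
        row = {
            "site_id": r.site_id,
            "city_id": r.city_id,
            "site_class": r.site_class,
            "season": r.season,
            "month": SEASONS.index(r.season),
            "n_valid_traps": r.n_valid_traps,
        }
        for sp in ALL_SPECIES:
            row[f"y_{sp}"] = r.y.get(sp, 0)
            row[f"present_{sp}"] = int(r.present.get(sp, False))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# occupancy cross-tabulation
# ---------------------------------------------------------------------------

def _category(alb: bool, aeg: bool, cq: bool) -> str:
    members = [sp for sp, flag in zip(SPECIES, (alb, aeg, cq)) if flag]
    if not members:
        return "none"
    if len(members) == 1:
        return f"{members[0]} only"
    return "+".join(members)


@dataclass
class OccupancyTable:
    """Cross-tabulation of the eight exclusive occupancy categories.

    ``category_counts[cat] = (site_count, trap_count)``; trap counts are 0
    when no trap-level data were supplied. Species proportions are derived
    by summing every category containing the species over the stratum total.
    """

    label: str
    n_sites: int
    n_traps: int
    category_counts: dict[str, tuple[int, int]]
    species_proportions: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        site_total = sum(v[0] for v in self.category_counts.values())
        if site_total != self.n_sites:
            raise ValueError(
                f"category site counts sum to {site_total}, expected {self.n_sites}"
            )
        if not self.species_proportions:
            self.species_proportions = {
                sp: (
                    self.species_sites(sp) / self.n_sites if self.n_sites else np.nan,
                    self.species_traps(sp) / self.n_traps if self.n_traps else np.nan,
                )
                for sp in SPECIES
            }

    def species_sites(self, species: str) -> int:
        return sum(
            v[0] for cat, v in self.category_counts.items() if species in cat
        )

    def species_traps(self, species: str) -> int:
        return sum(
            v[1] for cat, v in self.category_counts.items() if species in cat
        )

    def to_frame(self) -> pd.DataFrame:
        row = {"stratum": self.label, "n_sites": self.n_sites, "n_traps": self.n_traps}
        for cat in OCCUPANCY_CATEGORIES:
            s, t = self.category_counts.get(cat, (0, 0))
            row[f"sites:{cat}"] = s
            row[f"traps:{cat}"] = t
        for sp in SPECIES:
            ps, pt = self.species_proportions[sp]
            row[f"prop_sites_{sp}"] = ps
            row[f"prop_traps_{sp}"] = pt
        return pd.DataFrame([row])


def cross_tabulate_occupancy(
    records: list[SiteSeasonRecord],
    label: str = "all",
    traps: list[TrapObservation] | None = None,
) -> OccupancyTable:
    """Assign each site-season to one of the eight occupancy categories.

    Site-level categories come from the records' presence flags; if the raw
    trap observations are supplied, each valid trap is also categorised by
    the species it contained (Table-style counts in parentheses).
    """
    cat_sites = {cat: 0 for cat in OCCUPANCY_CATEGORIES}
    cat_traps = {cat: 0 for cat in OCCUPANCY_CATEGORIES}
    for r in records:
        cat_sites[_category(*(r.present.get(sp, False) for sp in SPECIES))] += 1
    n_traps = 0
    if traps is not None:
        kept = {(r.city_id, r.site_id, r.season) for r in records}
        for t in traps:
            if t.is_valid and (t.city_id, t.site_id, t.season) in kept:
                n_traps += 1
                cat_traps[_category(*(t.counts.get(sp, 0) > 0 for sp in SPECIES))] += 1
    return OccupancyTable(
        label=label,
        n_sites=len(records),
        n_traps=n_traps,
        category_counts={
            cat: (cat_sites[cat], cat_traps[cat]) for cat in OCCUPANCY_CATEGORIES
        },
    )


def exclusive_cooccurrence(table: OccupancyTable, pair: tuple[str, str]) -> float:
    """Fraction of sites in exactly the two-species category for ``pair``.

    This is the *exclusive* co-occurrence of the pair: sites where the third
    species was also present fall in the triple category and are not counted.
    """
    a, b = sorted(pair, key=SPECIES.index)
    cat = f"{a}+{b}"
    if cat not in OCCUPANCY_CATEGORIES:
        raise ValueError(f"not a species pair: {pair!r}")
    if table.n_sites == 0:
        raise ValueError("empty stratum has no defined proportions")
    return table.category_counts[cat][0] / table.n_sites


def occupancy_statistics(
    records: list[SiteSeasonRecord],
    total_traps: int,
    traps: list[TrapObservation] | None = None,
) -> dict:
    """Season-wise exclusive co-occurrence and pooled trap occupancy.

    ``total_traps`` is the externally known number of undisturbed traps
    across both seasons (the denominator for pooled trap occupancy); it may
    exceed the traps represented in ``records`` because empty traps can be
    implicit.
    """
    tables = {
        season: cross_tabulate_occupancy(
            [r for r in records if r.season == season], season, traps
        )
        for season in SEASONS
    }
    return occupancy_statistics_from_tables(tables, total_traps)


def occupancy_statistics_from_tables(
    tables: dict[str, OccupancyTable], total_traps: int
) -> dict:
    """Same summaries computed from already cross-tabulated season tables."""
    if total_traps <= 0:
        raise ValueError("total_traps must be positive")
    positive = {
        sp: sum(t.species_traps(sp) for t in tables.values()) for sp in SPECIES
    }
    if max(positive.values(), default=0) > total_traps:
        raise ValueError("total_traps smaller than the number of positive traps")
    # empty strata get NaN proportions rather than an error
    cooccurrence = {
        season: {
            pair: (
                exclusive_cooccurrence(tables[season], pair)
                if tables[season].n_sites
                else np.nan
            )
            for pair in (("ALB", "AEG"), ("ALB", "CQ"), ("AEG", "CQ"))
        }
        for season in tables
    }
    return {
        "cooccurrence": cooccurrence,
        "trap_occupancy": {sp: positive[sp] / total_traps for sp in SPECIES},
        "positive_traps": positive,
        "total_traps": total_traps,
    }
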