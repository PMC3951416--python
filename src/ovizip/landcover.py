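"""Land-cover covariates from categorical grids.

Sites sit on a categorical land-cover raster (integer class codes on a
regular grid, 30 m pixels by default, NLCD-style legend). For each site the
proportional area of each class is tabulated inside circular buffers of
50 m (local site character) and 200 m (the wider landscape within typical
mosquito dispersal range). A pixel belongs to a buffer when its center lies
within the radius — plain pixel tabulation, no area weighting. Proportions
are then screened for collinearity (a class significantly correlated with
every other class is dropped, as with low-intensity developed cover in
dense urban rasters) and z-scored across sites for use as regression
covariates. Dropped-class proportions are not renormalized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: default NLCD-style legend code -> class name used throughout the package
DEFAULT_LEGEND = {
    1: "high_intensity_developed",
    2: "low_intensity_developed",
    3: "open_space_developed",
    4: "wetland",
}

BUFFER_RADII = (50.0, 200.0)


@dataclass
class CategoricalGrid:
    """A rectangular categorical raster in continuous metre coordinates.

    ``origin`` is the (x, y) position of the *center* of cell [0, 0]; x runs
    along columns, y along rows.
    """

    cells: np.ndarray
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2:
            raise ValueError("grid cells must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        codes = set(np.unique(self.cells).tolist())
        unknown = codes - set(self.legend)
        if unknown:
            raise ValueError(f"class codes missing from legend: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every pixel center."""
        ny, nx = self.cells.shape
        x = self.origin[0] + np.arange(nx) * self.pixel_size
        y = self.origin[1] + np.arange(ny) * self.pixel_size
        return np.meshgrid(x, y)

    @classmethod
    def from_files(cls, array_path, meta_path) -> "CategoricalGrid":
        """Load from a plain CSV array of codes plus a JSON sidecar.

        The sidecar carries ``pixel_size``, ``origin`` and ``legend``
        (code -> class name, JSON keys as strings).
        """
        cells = np.loadtxt(array_path, delimiter=",", dtype=np.int64, ndmin=2)
        meta = json.loads(Path(meta_path).read_text())
        return cls(
            cells=cells,
            pixel_size=float(meta.get("pixel_size", 30.0)),
            origin=tuple(meta.get("origin", (0.0, 0.0))),
            legend={int(k): v for k, v in meta["legend"].items()},
        )

    def to_files(self, array_path, meta_path) -> None:
        np.savetxt(array_path, self.cells, fmt="%d", delimiter=",")
        Path(meta_path).write_text(
            json.dumps(
                {
                    "pixel_size": self.pixel_size,
                    "origin": list(self.origin),
                    "legend": {str(k): v for k, v in self.legend.items()},
                }
            )
        )


def buffer_class_proportions(
    grid: CategoricalGrid, point: tuple[float, float], radius: float
) -> dict[str, float]:
    """Proportional area of each legend class within a circular buffer.

    Membership is center-in-circle: a pixel counts iff its center is within
    Euclidean distance ``radius`` of ``point``. Proportions over the full
    legend sum to 1. A buffer capturing no pixel centers raises.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    gx, gy = grid.pixel_centers()
    mask = (gx - point[0]) ** 2 + (gy - point[1]) ** 2 <= radius**2
    total = int(mask.sum())
    if total == 0:
        raise ValueError(f"buffer of radius {radius} m at {point} contains no pixel centers")
    inside = grid.cells[mask]
    return {
        name: float(np.count_nonzero(inside == code)) / total
        for code, name in grid.legend.items()
    }


def extract_profiles(
    grid: CategoricalGrid,
    sites: pd.DataFrame,
    radii: tuple[float, ...] = BUFFER_RADII,
) -> pd.DataFrame:
    """Buffer proportions for every site at every radius.

    ``sites`` needs columns ``site_id, x, y`` and optionally ``cemetery``
    (kept as a pass-through flag — cemetery status is an input, not inferred
    from land cover). Output columns are ``<class>_<radius>``.
    """
    rows = []
    for site in sites.itertuples(index=False):
        row = {"site_id": site.site_id, "cemetery": bool(getattr(site, "cemetery", False))}
        for radius in radii:
            props = buffer_class_proportions(grid, (site.x, site.y), radius)
            for name, p in props.items():
                row[f"{name}_{int(radius)}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_id")


def prepare_covariates(
    profiles: pd.DataFrame,
    columns: list[str] | None = None,
    drop_rule: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Screen collinear classes and z-score the survivors.

    A column is dropped iff its Pearson correlation is significant
    (two-sided p < ``drop_rule``) with *every* other retained column; when
    several qualify at once, the one with the largest mean absolute
    correlation goes first and the rule is re-evaluated. Zero-variance
    columns are dropped with a warning (they cannot be z-scored). Retained
    columns are standardized to mean 0, sd 1 (ddof 0) across sites.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles to screen correlations")
    if columns is None:
        columns = [c for c in profiles.columns if c != "cemetery"]
    data = profiles[columns].astype(float)

    dropped: list[str] = []
    for col in list(data.columns):
        if np.isclose(data[col].std(ddof=0), 0.0):
            warnings.warn(f"zero-variance covariate {col!r} dropped", stacklevel=2)
            dropped.append(col)
            data = data.drop(columns=col)

    def fully_correlated(cols: list[str]) -> list[tuple[float, str]]:
        out = []
        for col in cols:
            others = [c for c in cols if c != col]
            if not others:
                continue
            tests = [stats.pearsonr(data[col], data[c]) for c in others]
            if all(t.pvalue < drop_rule for t in tests):
                out.append((float(np.mean([abs(t.statistic) for t in tests])), col))
        return sorted(out, reverse=True)

    while True:
        offenders = fully_correlated(list(data.columns))
        if not offenders:
            break
        _, worst = offenders[0]
        dropped.append(worst)
        data = data.drop(columns=worst)

    standardized = (data - data.mean()) / data.std(ddof=0)
    return standardized, dropped
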