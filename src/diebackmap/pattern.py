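"""Marked point patterns in rectangular plots: data model, geometry, file I/O.

A stem map is a record of every individual plant in a rectangular survey plot
(here 10 x 10 m, coordinates in centimetres, origin at the lower-left corner):
planar coordinates plus marks — species label, live/dead status, and crown
diameter. This module holds the containers the rest of the pipeline operates
on, together with the two geometric primitives that the edge corrections need
(distance to the plot boundary, and toroidal translation of a pattern).

Conventions
-----------
* The window is closed on all sides: plants exactly on the border belong to
  the plot.
* Plant ids are row indices (0..n-1), assigned in file order; every
  tie-break elsewhere in the package uses these ids, so the pipeline is
  deterministic.
* Duplicate coordinates are legal (two plants recorded at the same stake)
  but logged as a warning.
* Live/dead status is recorded for the focal species only; other species
  carry status ``na``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATUS_VALUES = ("live", "dead", "na")

#: Columns of the stem-map CSV dialect, in order.
STEM_MAP_COLUMNS = ["site_id", "x_cm", "y_cm", "species", "status", "crown_cm"]

#: Columns of the site-metadata CSV dialect.
METADATA_COLUMNS = ["site_id", "group", "elevation_m", "aspect", "mat_c"]


@dataclass(frozen=True)
class Window:
    """Rectangular observation window, dimensions in cm."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"window dimensions must be positive, got {self.width} x {self.height}"
            )

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x, y) -> np.ndarray:
        """Vectorised containment test (closed window)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)


#: Default plot: 10 x 10 m recorded in cm.
DEFAULT_WINDOW = Window(1000.0, 1000.0)


@dataclass(frozen=True)
class Plant:
    """A single mapped individual (row view into a :class:`PointPattern`)."""

    id: int
    x: float
    y: float
    species: str
    status: str
    crown: float  # cm; NaN when not measured


class PointPattern:
    """A marked point pattern: coordinates plus species/status/crown marks.

    Parameters
    ----------
    window : Window
    x, y : array-like of float
        Coordinates in cm, inside the (closed) window.
    species : array-like of str
    status : array-like of str, optional
        Each ``live``, ``dead`` or ``na``; defaults to all ``na``.
    crown : array-like of float, optional
        Crown diameters in cm; NaN marks a missing measurement. Defaults to
        all NaN.
    """

    def __init__(self, window: Window, x, y, species, status=None, crown=None):
        self.window = window
        self.x = np.ascontiguousarray(x, dtype=float)
        self.y = np.ascontiguousarray(y, dtype=float)
        n = self.x.size
        if self.y.size != n:
            raise ValueError("x and y must have equal length")
        self.species = np.asarray(species, dtype=object)
        if self.species.size != n:
            raise ValueError("species must have the same length as coordinates")
        if status is None:
            status = np.full(n, "na", dtype=object)
        self.status = np.asarray(status, dtype=object)
        if crown is None:
            crown = np.full(n, np.nan, dtype=float)
        self.crown = np.asarray(crown, dtype=float)
        if self.status.size != n or self.crown.size != n:
            raise ValueError("marks must have the same length as coordinates")
        self._validate()

    def _validate(self) -> None:
        inside = self.window.contains(self.x, self.y)
        if not inside.all():
            i = int(np.flatnonzero(~inside)[0])
            raise ValueError(
                f"plant {i} at ({self.x[i]:g}, {self.y[i]:g}) lies outside the "
                f"{self.window.width:g} x {self.window.height:g} window"
            )
        bad = set(self.status) - set(STATUS_VALUES)
        if bad:
            raise ValueError(f"unknown status token(s): {sorted(bad)}")
        with np.errstate(invalid="ignore"):
            if np.any(self.crown[~np.isnan(self.crown)] <= 0):
                raise ValueError("crown diameters must be positive where present")
        if self.n > 1:
            coords = np.column_stack([self.x, self.y])
            uniq = np.unique(coords, axis=0)
            if uniq.shape[0] < self.n:
                logger.warning(
                    "pattern contains %d duplicated coordinate(s)",
                    self.n - uniq.shape[0],
                )

    @property
    def n(self) -> int:
        return self.x.size

    def __len__(self) -> int:
        return self.n

    def plants(self) -> Iterator[Plant]:
        for i in range(self.n):
            yield Plant(
                i,
                float(self.x[i]),
                float(self.y[i]),
                str(self.species[i]),
                str(self.status[i]),
                float(self.crown[i]),
            )

    def subset(self, mask) -> "PointPattern":
        """New pattern keeping rows where ``mask`` is true (ids renumbered)."""
        mask = np.asarray(mask, dtype=bool)
        return PointPattern(
            self.window,
            self.x[mask],
            self.y[mask],
            self.species[mask],
            self.status[mask],
            self.crown[mask],
        )

    def with_marks(self, species=None, status=None, crown=None) -> "PointPattern":
        """Copy of the pattern with some mark columns replaced."""
        return PointPattern(
            self.window,
            self.x,
            self.y,
            self.species if species is None else species,
            self.status if status is None else status,
            self.crown if crown is None else crown,
        )

    def to_frame(self, site_id: int = 1) -> pd.DataFrame:
        """Stem-map rows for this pattern in the documented CSV dialect."""
        return pd.DataFrame(
            {
                "site_id": site_id,
                "x_cm": self.x,
                "y_cm": self.y,
                "species": self.species,
                "status": self.status,
                "crown_cm": self.crown,
            }
        )

    def equals(self, other: "PointPattern") -> bool:
        """Field-by-field equality (NaN crowns compare equal)."""
        if self.n != other.n or self.window != other.window:
            return False
        crown_eq = np.all(
            (self.crown == other.crown)
            | (np.isnan(self.crown) & np.isnan(other.crown))
        )
        return bool(
            np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.species, other.species)
            and np.array_equal(self.status, other.status)
            and crown_eq
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"PointPattern(n={self.n}, window={self.window.width:g}x"
            f"{self.window.height:g} cm)"
        )


@dataclass
class SiteRecord:
    """One survey site: stem map plus soil profile and metadata."""

    site_id: int
    group: str
    pattern: PointPattern
    soil: pd.DataFrame | None = None  # soil-sample rows, see soil module
    metadata: dict = field(default_factory=dict)


@dataclass
class SurveyDataset:
    """A multi-site survey (the study design uses 12 sites in 3 groups)."""

    sites: list[SiteRecord]
    focal_species: str = "A. verus"

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("a survey needs at least one site")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site_ids must be unique")

    def site(self, site_id: int) -> SiteRecord:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(f"no site {site_id} in survey")

    @property
    def groups(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for s in self.sites:
            out.setdefault(s.group, []).append(s.site_id)
        return out


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def boundary_distance(x, y, window: Window):
    """Distance from a point (or array of points) to the nearest window edge.

    Raises if any point lies outside the (closed) window.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not window.contains(x, y).all():
        raise ValueError("point outside window")
    d = np.minimum(
        np.minimum(x, window.width - x), np.minimum(y, window.height - y)
    )
    return float(d) if d.ndim == 0 else d


def toroidal_shift(pattern: PointPattern, dx: float, dy: float) -> PointPattern:
    """Translate a pattern modulo the window dimensions (wrap-around).

    Used to simulate the independence null for bivariate analyses: shifting
    one component of a pattern on the torus preserves its internal structure
    while randomising its position relative to the other component.
    """
    w, h = pattern.window.width, pattern.window.height
    x = np.mod(pattern.x + dx, w)
    y = np.mod(pattern.y + dy, h)
    return PointPattern(
        pattern.window, x, y, pattern.species, pattern.status, pattern.crown
    )


def toroidal_distance(pattern: PointPattern) -> np.ndarray:
    """All-pairs distance matrix on the torus defined by the window."""
    w, h = pattern.window.width, pattern.window.height
    dx = np.abs(pattern.x[:, None] - pattern.x[None, :])
    dy = np.abs(pattern.y[:, None] - pattern.y[None, :])
    dx = np.minimum(dx, w - dx)
    dy = np.minimum(dy, h - dy)
    return np.hypot(dx, dy)


# ---------------------------------------------------------------------------
# File I/O — stem-map CSV dialect
# ---------------------------------------------------------------------------


def read_stem_map(
    path,
    window: Window = DEFAULT_WINDOW,
    site_id: int | None = None,
) -> PointPattern:
    """Read one site's stem map from the documented CSV dialect.

    The file holds columns ``site_id,x_cm,y_cm,species,status,crown_cm``
    (UTF-8, header required) and may contain many sites; ``site_id`` selects
    one (may be omitted when the file holds a single site). Row order within
    a site defines plant ids.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in STEM_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stem map {path} lacks column(s) {missing}")
    if site_id is not None:
        df = df[df["site_id"] == site_id]
        if df.empty:
            raise ValueError(f"no rows for site {site_id} in {path}")
    elif df["site_id"].nunique() > 1:
        raise ValueError(
            f"{path} holds multiple sites; pass site_id to select one"
        )
    for col in ("x_cm", "y_cm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(df.index[vals.isna()][0]) + 2  # header + 1-based
            raise ValueError(f"malformed {col} value at line {line} of {path}")
        df[col] = vals
    return PointPattern(
        window,
        df["x_cm"].to_numpy(),
        df["y_cm"].to_numpy(),
        df["species"].astype(str).to_numpy(),
        df["status"].astype(str).str.strip().to_numpy(),
        pd.to_numeric(df["crown_cm"], errors="coerce").to_numpy(),
    )


def write_stem_map(patterns: Mapping[int, PointPattern], path) -> None:
    """Write one or more sites' patterns to a stem-map CSV."""
    frames = [p.to_frame(site_id=sid) for sid, p in patterns.items()]
    out = pd.concat(frames, ignore_index=True)
    # shortest round-trip float representation keeps read/write lossless
    out.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_site_metadata(path) -> pd.DataFrame:
    """Read the site-metadata CSV (``site_id,group,elevation_m,aspect,mat_c``)."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks column(s) {missing}")
    return df
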