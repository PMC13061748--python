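"""Nearest-neighbour structural indices: mingling, dominance, uniform angle.

For each reference plant and its k = 4 nearest neighbours (the Gadow–Hui
structural group), three indices summarise the local neighbourhood, each
taking values in {0, 0.25, 0.5, 0.75, 1}:

Mingling M
    fraction of neighbours belonging to a different species than the
    reference — 0 for a purely conspecific neighbourhood, 1 for complete
    interspecific mixing.
Dominance U
    size differentiation from crown diameters. The indicator counts a
    neighbour as 1 when it is *not smaller* than the reference (ties count
    as not smaller), so high U means the reference plant is dominated by its
    neighbours. A ``larger_counts_as`` flag flips the convention for users
    who want U = proportion of smaller neighbours.
Uniform angle W
    regularity of the angular arrangement: the neighbours' azimuths are
    sorted and the four successive gaps (including the wrap-around gap)
    partition 360 degrees; W is the fraction of gaps strictly smaller than
    the standard angle alpha_0 = 360/(k+1) = 72 degrees. Under CSR the W
    distribution is unimodal at 0.5 — the classical calibration of alpha_0.
    A perfect cross (gaps all 90 degrees) gives W = 0.

Edge handling uses the NN1 correction of Pommerening & Stoyan: a plant is
retained as a *reference* only if its distance to the nearest plot boundary
is at least the distance to its k-th nearest neighbour (so the true
neighbourhood cannot extend beyond the plot); every plant remains eligible
as a *neighbour*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pattern import PointPattern, boundary_distance

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborSet",
    "StructuralRecord",
    "StructuralSummary",
    "k_nearest_neighbors",
    "mingling",
    "dominance",
    "uniform_angle",
    "nn1_reference_filter",
    "structural_summary",
]

#: Index values on the j/4 lattice.
INDEX_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class NeighborSet:
    """The k nearest neighbours of a reference plant, ordered by distance.

    Exact distance ties are broken by ascending plant id, which makes
    neighbour selection deterministic.
    """

    reference_id: int
    neighbor_ids: tuple[int, ...]
    distances: tuple[float, ...]


@dataclass(frozen=True)
class StructuralRecord:
    reference_id: int
    m: float
    u: float
    w: float


@dataclass
class StructuralSummary:
    """Per-reference records plus marginal and bivariate frequency tables."""

    subgroup: str
    records: pd.DataFrame  # columns reference_id, m, u, w
    marginal: dict[str, pd.Series]  # index -> frequency over INDEX_LEVELS
    surfaces: dict[tuple[str, str], pd.DataFrame]  # 5x5 counts
    n_references: int


def k_nearest_neighbors(
    pattern: PointPattern, reference_id: int, k: int = 4
) -> NeighborSet:
    """The k closest plants to a reference, ties broken by ascending id."""
    if pattern.n < k + 1:
        raise ValueError(f"pattern has {pattern.n} plants; need at least {k + 1}")
    d = np.hypot(
        pattern.x - pattern.x[reference_id], pattern.y - pattern.y[reference_id]
    )
    ids = np.arange(pattern.n)
    mask = ids != reference_id
    order = np.lexsort((ids[mask], d[mask]))
    chosen = ids[mask][order[:k]]
    return NeighborSet(
        reference_id,
        tuple(int(i) for i in chosen),
        tuple(float(v) for v in d[chosen]),
    )


def mingling(pattern: PointPattern, neighbors: NeighborSet) -> float:
    """Fraction of neighbours of a different species than the reference."""
    ref_sp = pattern.species[neighbors.reference_id]
    diff = [pattern.species[j] != ref_sp for j in neighbors.neighbor_ids]
    return sum(diff) / len(diff)


def dominance(
    pattern: PointPattern,
    neighbors: NeighborSet,
    larger_counts_as: float = 1.0,
) -> float:
    """Crown-size dominance U from crown diameters.

    With the default convention a neighbour scores ``larger_counts_as`` = 1
    when its crown is >= the reference crown (strictly smaller scores 0), so
    U = 1 means the reference is the smallest plant in its structural group.
    Pass ``larger_counts_as=0`` for the complementary reading (U =
    proportion of smaller neighbours).

    Raises ValueError when any participant lacks a crown measurement;
    callers that summarise whole patterns skip such records with a warning.
    """
    ref = pattern.crown[neighbors.reference_id]
    crowns = [pattern.crown[j] for j in neighbors.neighbor_ids]
    if np.isnan(ref) or any(np.isnan(c) for c in crowns):
        raise ValueError(
            f"missing crown diameter in structural group of plant "
            f"{neighbors.reference_id}"
        )
    score_not_smaller = larger_counts_as
    score_smaller = 1.0 - larger_counts_as
    return (
        sum(score_not_smaller if c >= ref else score_smaller for c in crowns)
        / len(crowns)
    )


def uniform_angle(pattern: PointPattern, neighbors: NeighborSet) -> float:
    """Uniform angle index W from successive azimuthal gaps.

    The k gaps between sorted neighbour azimuths (wrap-around included) sum
    to 360 degrees; W is the fraction strictly smaller than
    alpha_0 = 360/(k+1).
    """
    i = neighbors.reference_id
    dx = np.array([pattern.x[j] - pattern.x[i] for j in neighbors.neighbor_ids])
    dy = np.array([pattern.y[j] - pattern.y[i] for j in neighbors.neighbor_ids])
    if np.any((dx == 0) & (dy == 0)):
        raise ValueError(
            f"neighbour coincident with reference plant {i}; angles undefined"
        )
    az = np.mod(np.degrees(np.arctan2(dy, dx)), 360.0)
    az.sort()
    gaps = np.diff(np.concatenate([az, [az[0] + 360.0]]))
    alpha0 = 360.0 / (len(az) + 1)
    return float(np.sum(gaps < alpha0)) / len(az)


def nn1_reference_filter(pattern: PointPattern, k: int = 4) -> np.ndarray:
    """Ids of plants retained as references under the NN1 edge correction.

    A plant qualifies iff its boundary distance is >= the distance to its
    k-th nearest neighbour.
    """
    bdist = boundary_distance(pattern.x, pattern.y, pattern.window)
    retained = []
    for i in range(pattern.n):
        ns = k_nearest_neighbors(pattern, i, k)
        if bdist[i] >= ns.distances[-1]:
            retained.append(i)
    if not retained:
        raise ValueError(
            "NN1 filter retained no reference plants; use a larger plot or "
            "smaller k"
        )
    return np.asarray(retained, dtype=int)


def _frequency(values, levels=INDEX_LEVELS) -> pd.Series:
    counts = pd.Series(0, index=list(levels), dtype=int)
    for v in values:
        counts.loc[round(v * 4) / 4] += 1
    return counts


def structural_summary(
    pattern: PointPattern,
    subgroup: str = "all",
    focal_species: str = "A. verus",
    k: int = 4,
    larger_counts_as: float = 1.0,
) -> StructuralSummary:
    """M/U/W records and frequency surfaces for focal-species references.

    ``subgroup`` restricts the *references* to focal individuals that are
    ``all`` (live + dead + unclassified), ``live``, or ``dead``; neighbours
    are always drawn from the full pattern, since mingling with other
    species is precisely what the index measures. References failing the
    NN1 filter, lacking crown data, or with coincident neighbours are
    dropped (the latter two with a warning).
    """
    if subgroup not in ("all", "live", "dead"):
        raise ValueError(f"unknown subgroup {subgroup!r}")
    is_focal = pattern.species == focal_species
    if subgroup == "all":
        eligible = is_focal
    else:
        eligible = is_focal & (pattern.status == subgroup)
    if not eligible.any():
        raise ValueError(
            f"no focal-species plants in subgroup {subgroup!r}"
        )
    retained = set(nn1_reference_filter(pattern, k).tolist())
    rows = []
    for i in np.flatnonzero(eligible):
        if int(i) not in retained:
            continue
        ns = k_nearest_neighbors(pattern, int(i), k)
        try:
            u = dominance(pattern, ns, larger_counts_as)
            w = uniform_angle(pattern, ns)
        except ValueError as exc:
            logger.warning("skipping reference %d: %s", i, exc)
            continue
        rows.append(StructuralRecord(int(i), mingling(pattern, ns), u, w))
    if not rows:
        raise ValueError(
            f"no retained references in subgroup {subgroup!r} after edge "
            "correction"
        )
    records = pd.DataFrame(
        {
            "reference_id": [r.reference_id for r in rows],
            "m": [r.m for r in rows],
            "u": [r.u for r in rows],
            "w": [r.w for r in rows],
        }
    )
    marginal = {c: _frequency(records[c]) for c in ("m", "u", "w")}
    surfaces = {}
    for a, b in (("m", "w"), ("m", "u"), ("w", "u")):
        tab = pd.DataFrame(
            0, index=list(INDEX_LEVELS), columns=list(INDEX_LEVELS), dtype=int
        )
        for va, vb in zip(records[a], records[b]):
            tab.loc[round(va * 4) / 4, round(vb * 4) / 4] += 1
        surfaces[(a, b)] = tab
    return StructuralSummary(subgroup, records, marginal, surfaces, len(rows))
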