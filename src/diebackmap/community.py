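"""Community diversity indices, dieback quantification, group comparisons.

Given per-site species abundance vectors (live and dead individuals of the
focal species both count: they are mapped individuals), the module computes
the classical diversity battery — dominance D = sum p_i^2, Simpson 1 - D,
Shannon H = -sum p_i ln p_i (natural log), evenness e^H / S, Pielou
equitability H / ln S, Brillouin (ln N! - sum ln n_i!) / N, Menhinick
S / sqrt(N), Margalef (S - 1) / ln N, Berger-Parker max n_i / N, Fisher's
log-series alpha (root of S = alpha ln(1 + N / alpha)), and the Chao-1
richness estimator — plus per-site dieback percentages and group summaries.

Site groups are compared non-parametrically: Kruskal-Wallis across the
groups (chi-square approximation with tie correction by default; an exact /
Monte Carlo permutation option is available for small samples) and pairwise
Mann-Whitney tests.

Reported values are rounded half-away-from-zero to the requested number of
decimals; internal computation is always full precision.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .pattern import PointPattern, SurveyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "DiversityProfile",
    "GroupComparison",
    "abundance_from_pattern",
    "diversity_profile",
    "fisher_alpha",
    "chao1",
    "dieback_percentage",
    "site_summary",
    "group_summary",
    "kruskal_wallis",
    "mann_whitney",
    "compare_groups",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed field tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class AbundanceTable:
    """Species -> count map for one site."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("abundance table is empty")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("species counts must be >= 1")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def s(self) -> int:
        return len(self.counts)

    def vector(self) -> np.ndarray:
        return np.asarray(list(self.counts.values()), dtype=float)


@dataclass
class DiversityProfile:
    dominance: float
    simpson: float
    shannon: float
    evenness: float
    brillouin: float
    menhinick: float
    margalef: float
    equitability: float
    fisher_alpha: float
    berger_parker: float
    chao1: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def abundance_from_pattern(pattern: PointPattern) -> AbundanceTable:
    """Species counts from a stem map (all statuses included)."""
    if pattern.n == 0:
        raise ValueError("empty pattern")
    species, counts = np.unique(pattern.species.astype(str), return_counts=True)
    return AbundanceTable(dict(zip(species.tolist(), counts.tolist())))


def fisher_alpha(s: int, n: int) -> float:
    """Fisher's log-series alpha: the positive root of S = a ln(1 + N/a)."""
    if not 1 <= s <= n:
        raise ValueError(f"need 1 <= S <= N, got S={s}, N={n}")
    if s == 1:
        # S = a ln(1 + N/a) -> 1 only in the a -> 0 limit for N > 1.
        return brentq(lambda a: a * math.log1p(n / a) - s, 1e-12, 1e6, xtol=1e-12)
    f = lambda a: a * math.log1p(n / a) - s
    lo, hi = 1e-6, 1e6
    if f(hi) < 0:
        # S close to (or equal to) N: the log-series degenerates and alpha
        # diverges; report infinity rather than a spurious finite root.
        logger.warning("fisher_alpha diverges for S=%d, N=%d", s, n)
        return math.inf
    alpha = brentq(f, lo, hi, xtol=1e-12, maxiter=200)
    assert abs(alpha * math.log1p(n / alpha) - s) <= 1e-8
    return alpha


def chao1(table: AbundanceTable) -> float:
    """Chao-1 richness estimator from singleton/doubleton counts."""
    counts = table.vector()
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    if f2 > 0:
        return table.s + f1 * f1 / (2.0 * f2)
    return table.s + f1 * (f1 - 1) / 2.0


def diversity_profile(table: AbundanceTable) -> DiversityProfile:
    """Full diversity battery for one site's abundances."""
    counts = table.vector()
    n = table.n
    s = table.s
    p = counts / n
    d = float(np.sum(p**2))
    shannon = float(-np.sum(p * np.log(p)))
    if s > 1:
        equit = shannon / math.log(s)
    else:
        logger.warning("single-species site: equitability undefined")
        equit = math.nan
    brill = (math.lgamma(n + 1) - sum(math.lgamma(c + 1) for c in counts)) / n
    return DiversityProfile(
        dominance=d,
        simpson=1.0 - d,
        shannon=shannon,
        evenness=math.exp(shannon) / s,
        brillouin=brill,
        menhinick=s / math.sqrt(n),
        margalef=(s - 1) / math.log(n) if n > 1 else math.nan,
        equitability=equit,
        fisher_alpha=fisher_alpha(s, n),
        berger_parker=float(counts.max()) / n,
        chao1=chao1(table),
    )


def dieback_percentage(n_dead: int, n_total: int, decimals: int = 1) -> float:
    """Per-site dieback: 100 * dead / total focal individuals.

    The denominator is every mapped focal individual (live + dead +
    unclassified).
    """
    if n_total < 1:
        raise ValueError("no focal individuals: dieback undefined")
    if not 0 <= n_dead <= n_total:
        raise ValueError(f"need 0 <= n_dead <= n_total, got {n_dead}/{n_total}")
    return round_half_away(100.0 * n_dead / n_total, decimals)


def site_summary(dataset: SurveyDataset) -> pd.DataFrame:
    """Per-site count table: totals, richness, and focal live/dead counts."""
    rows = []
    for site in dataset.sites:
        pat = site.pattern
        focal = pat.species == dataset.focal_species
        rows.append(
            {
                "site_id": site.site_id,
                "group": site.group,
                "n_total": pat.n,
                "richness": len(set(pat.species.astype(str))),
                "focal_total": int(focal.sum()),
                "focal_live": int((focal & (pat.status == "live")).sum()),
                "focal_dead": int((focal & (pat.status == "dead")).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("site_id")


def group_summary(summary: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per-group arithmetic means of the site-summary count columns.

    ``summary`` is a frame like :func:`site_summary` returns (a ``group``
    column plus count columns); means are reported rounded half-away to
    ``decimals``.
    """
    if "group" not in summary.columns:
        raise ValueError("summary frame needs a 'group' column")
    cols = [c for c in summary.columns if c != "group" and
            pd.api.types.is_numeric_dtype(summary[c])]
    out = {}
    for g, sub in summary.groupby("group"):
        if sub.empty:
            raise ValueError(f"group {g} has no sites")
        out[g] = {c: round_half_away(float(sub[c].mean()), decimals) for c in cols}
    return pd.DataFrame(out).T[cols]


@dataclass
class GroupComparison:
    index: str
    h: float
    p: float
    pairwise: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )  # (U, p) per group pair


def _kw_h(values: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Kruskal-Wallis H (midranks)."""
    n = values.size
    ranks = stats.rankdata(values)
    h = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(values, return_counts=True)
    c = 1.0 - np.sum(t**3 - t) / (n**3 - n) if n > 1 else 1.0
    if c == 0:
        return 0.0  # all values tied
    return h / c


def kruskal_wallis(
    values,
    group_labels,
    p_method: str = "chi2",
    n_perm: int = 10000,
    seed=None,
) -> tuple[float, float]:
    """Kruskal-Wallis H and p across >= 2 groups.

    ``p_method='chi2'`` uses the chi-square approximation (df = groups - 1);
    ``'permutation'`` enumerates all distinct label assignments when the
    total sample is <= 9 and otherwise Monte Carlo samples ``n_perm``
    permutations. All-tied input returns H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.size != labels.size:
        raise ValueError("values and labels must align")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if not np.any(labels == g):
            raise ValueError(f"group {g} is empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h_obs = _kw_h(values, labels)
    if p_method == "chi2":
        # scipy.stats.kruskal applies the same midrank + tie correction.
        p = float(stats.chi2.sf(h_obs, df=groups.size - 1))
        return h_obs, p
    if p_method != "permutation":
        raise ValueError(f"unknown p_method {p_method!r}")
    if values.size <= 9:
        perms = set(itertools.permutations(labels.tolist()))
        count = sum(
            _kw_h(values, np.asarray(pm)) >= h_obs - 1e-12 for pm in perms
        )
        return h_obs, count / len(perms)
    rng = np.random.default_rng(seed)
    count = 1  # include the observed assignment
    for _ in range(n_perm):
        if _kw_h(values, rng.permutation(labels)) >= h_obs - 1e-12:
            count += 1
    return h_obs, count / (n_perm + 1)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (midranks) and two-sided p.

    Exact enumeration p when n1 + n2 <= 12 and the data are tie-free;
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    small = a.size + b.size <= 12
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    values, group_labels, index_name: str = "", p_method: str = "chi2"
) -> GroupComparison:
    """Kruskal-Wallis across groups plus pairwise Mann-Whitney tests."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    h, p = kruskal_wallis(values, labels, p_method=p_method)
    pairwise = {}
    for g1, g2 in itertools.combinations(sorted(np.unique(labels).tolist()), 2):
        u, pu = mann_whitney(values[labels == g1], values[labels == g2])
        pairwise[(g1, g2)] = (u, pu)
    return GroupComparison(index_name, h, p, pairwise)
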