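"""Synthetic stem maps and whole surveys with the structure the analysis
assumes.

The generator emulates the study design the pipeline was built for: twelve
10 x 10 m rangeland plots in three regional groups (five western, three
southern, four eastern sites), plant communities clumped at small scales,
live/dead status recorded for the focal cushion shrub only, per-site
richness between 5 and 18 species, and a single latent soil-stress axis
along which sand and electrical conductivity rise while moisture, silt and
clay fall — and with them focal-species dieback.

Point processes
---------------
``csr``        exactly n uniform points (binomial process).
``thomas``     Poisson(kappa * A) cluster parents, each with
               Poisson(mean_offspring) offspring displaced by an isotropic
               Gaussian (sd ``offspring_sd``); offspring falling outside the
               window are wrapped toroidally so the realised intensity
               equals the nominal kappa * mu.
``hardcore``   n points by dart throwing with a minimum pairwise distance.

Marks
-----
Species labels are i.i.d. from a species-probability map (the survey
generator gives the focal species a per-group share and splits the rest
symmetrically, Dirichlet-multinomial style). Status is assigned to
focal-species plants only: ``random labeling`` (i.i.d. with death
probability p, which makes live and dead sub-patterns independent by
construction) or a ``covariate`` model where P(dead) =
logistic(beta0 + beta1 * g) with g the plant's normalised coordinate along a
spatial gradient axis. Crown diameters are truncated log-normal (canopy
diameters of the focal shrub run roughly 20-70 cm in the field).

Identical seed and configuration give bit-identical output; every site
draws from its own seed stream derived from the master seed and the site
id, so adding a site never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pattern import (
    PointPattern,
    SiteRecord,
    SurveyDataset,
    Window,
    DEFAULT_WINDOW,
)
from .soil import SoilProfile, simulate_site_soil

__all__ = [
    "ProcessSpec",
    "MarkSpec",
    "GroupConfig",
    "SurveyConfig",
    "simulate_pattern",
    "assign_marks",
    "simulate_survey",
    "derive_seed",
]


def derive_seed(master_seed: int, *keys) -> np.random.SeedSequence:
    """Deterministic per-stage seed stream from a master seed and keys.

    String keys are hashed with CRC-32 so streams are stable across runs and
    platforms.
    """
    ints = [
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys
    ]
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *ints])


@dataclass(frozen=True)
class ProcessSpec:
    """A point-process recipe: kind plus its parameters.

    kind = 'csr'       -> n
    kind = 'thomas'    -> parent_intensity (per cm^2), mean_offspring,
                          offspring_sd (cm)
    kind = 'hardcore'  -> n, min_distance (cm), max_attempts
    """

    kind: str
    n: int | None = None
    parent_intensity: float | None = None
    mean_offspring: float | None = None
    offspring_sd: float | None = None
    min_distance: float | None = None
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.kind == "csr":
            if not (self.n and self.n > 0):
                raise ValueError("csr needs n > 0")
        elif self.kind == "thomas":
            if not (
                self.parent_intensity
                and self.parent_intensity > 0
                and self.mean_offspring
                and self.mean_offspring > 0
                and self.offspring_sd
                and self.offspring_sd > 0
            ):
                raise ValueError(
                    "thomas needs positive parent_intensity, mean_offspring, "
                    "offspring_sd"
                )
        elif self.kind == "hardcore":
            if not (
                self.n
                and self.n > 0
                and self.min_distance
                and self.min_distance > 0
                and self.max_attempts > 0
            ):
                raise ValueError(
                    "hardcore needs n > 0, min_distance > 0, max_attempts > 0"
                )
        else:
            raise ValueError(f"unknown process kind {self.kind!r}")


@dataclass(frozen=True)
class MarkSpec:
    """Mark assignment recipe.

    ``status_model`` is ``None`` (all na), ``("random_labeling", p_dead)``
    or ``("covariate", beta0, beta1, axis)`` with axis 'x' or 'y'. Status is
    assigned only to plants of ``focal_species``; all other species keep
    ``na``.
    """

    species_probs: dict
    focal_species: str = "A. verus"
    status_model: tuple | None = None
    crown_meanlog: float = np.log(40.0)
    crown_sdlog: float = 0.35
    crown_bounds: tuple[float, float] = (10.0, 120.0)

    def __post_init__(self) -> None:
        total = sum(self.species_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species_probs sum to {total}, not 1")
        if self.status_model is not None:
            kind = self.status_model[0]
            if kind == "random_labeling":
                p = self.status_model[1]
                if not 0.0 <= p <= 1.0:
                    raise ValueError("p_dead must be in [0, 1]")
            elif kind == "covariate":
                if len(self.status_model) != 4 or self.status_model[3] not in (
                    "x",
                    "y",
                ):
                    raise ValueError(
                        "covariate model is ('covariate', beta0, beta1, 'x'|'y')"
                    )
            else:
                raise ValueError(f"unknown status model {kind!r}")


def simulate_pattern(
    spec: ProcessSpec, window: Window = DEFAULT_WINDOW, seed=None
) -> PointPattern:
    """Draw an unmarked pattern (species 'unassigned', status na)."""
    rng = np.random.default_rng(seed)
    w, h = window.width, window.height
    if spec.kind == "csr":
        x = rng.uniform(0, w, spec.n)
        y = rng.uniform(0, h, spec.n)
    elif spec.kind == "thomas":
        n_parents = rng.poisson(spec.parent_intensity * window.area)
        px = rng.uniform(0, w, n_parents)
        py = rng.uniform(0, h, n_parents)
        counts = rng.poisson(spec.mean_offspring, n_parents)
        cx = np.repeat(px, counts)
        cy = np.repeat(py, counts)
        total = cx.size
        # Toroidal wrap keeps realised intensity at the nominal kappa * mu.
        x = np.mod(cx + spec.offspring_sd * rng.standard_normal(total), w)
        y = np.mod(cy + spec.offspring_sd * rng.standard_normal(total), h)
    else:  # hardcore dart throwing
        xs: list[float] = []
        ys: list[float] = []
        d2 = spec.min_distance**2
        attempts = 0
        while len(xs) < spec.n:
            if attempts >= spec.max_attempts:
                raise ValueError(
                    f"hardcore placement stalled: {len(xs)} of {spec.n} points "
                    f"after {spec.max_attempts} attempts"
                )
            attempts += 1
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            if all((cx - a) ** 2 + (cy - b) ** 2 >= d2 for a, b in zip(xs, ys)):
                xs.append(cx)
                ys.append(cy)
        x = np.asarray(xs)
        y = np.asarray(ys)
    n = x.size
    return PointPattern(
        window, x, y, np.full(n, "unassigned", dtype=object)
    )


def _truncated_lognormal(rng, n, meanlog, sdlog, lo, hi, max_tries=1000):
    out = np.exp(rng.normal(meanlog, sdlog, n))
    for _ in range(max_tries):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = np.exp(rng.normal(meanlog, sdlog, int(bad.sum())))
    return np.clip(out, lo, hi)


def assign_marks(pattern: PointPattern, spec: MarkSpec, seed=None) -> PointPattern:
    """Draw species, status and crown marks for every plant."""
    rng = np.random.default_rng(seed)
    n = pattern.n
    labels = list(spec.species_probs.keys())
    probs = np.asarray([spec.species_probs[k] for k in labels], dtype=float)
    species = np.asarray(labels, dtype=object)[
        rng.choice(len(labels), size=n, p=probs / probs.sum())
    ]
    status = np.full(n, "na", dtype=object)
    focal = species == spec.focal_species
    if spec.status_model is not None and focal.any():
        if spec.status_model[0] == "random_labeling":
            p_dead = spec.status_model[1]
            dead = rng.random(int(focal.sum())) < p_dead
        else:
            _, beta0, beta1, axis = spec.status_model
            coord = pattern.x if axis == "x" else pattern.y
            extent = (
                pattern.window.width if axis == "x" else pattern.window.height
            )
            g = coord[focal] / extent
            p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * g)))
            dead = rng.random(int(focal.sum())) < p
        status[np.flatnonzero(focal)] = np.where(dead, "dead", "live")
    lo, hi = spec.crown_bounds
    crown = _truncated_lognormal(
        rng, n, spec.crown_meanlog, spec.crown_sdlog, lo, hi
    )
    return pattern.with_marks(species=species, status=status, crown=crown)


# ---------------------------------------------------------------------------
# Whole-survey generator
# ---------------------------------------------------------------------------

#: Site -> group assignment of the emulated 12-site design.
DEFAULT_SITE_GROUPS = {
    1: "G1", 5: "G1", 6: "G1", 11: "G1", 12: "G1",
    2: "G2", 3: "G2", 4: "G2",
    7: "G3", 8: "G3", 9: "G3", 10: "G3",
}


@dataclass(frozen=True)
class GroupConfig:
    """Per-group generating conditions.

    ``focal_prob`` is the focal species' share of individuals; ``stress_mean``
    and ``stress_sd`` place the group on the latent soil-stress axis;
    P(dead | site) = logistic(dieback_beta0 + dieback_beta1 * stress).
    Defaults per group are set from the emulated design's group structure
    (western sites: large communities, low stress; southern: small
    communities, intermediate; eastern: large communities, high stress and
    heavy dieback).
    """

    process: ProcessSpec
    focal_prob: float
    stress_mean: float
    stress_sd: float = 0.4
    richness_range: tuple[int, int] = (5, 18)
    elevation_range: tuple[float, float] = (2300.0, 2700.0)
    mat_c: float = 14.0


def _default_groups() -> dict[str, GroupConfig]:
    thomas = lambda kappa_a: ProcessSpec(
        "thomas",
        parent_intensity=kappa_a / 1_000_000.0,  # parents per cm^2 in 100 m^2
        mean_offspring=4.0,
        offspring_sd=50.0,
    )
    return {
        "G1": GroupConfig(thomas(53.0), focal_prob=0.30, stress_mean=-0.8),
        "G2": GroupConfig(thomas(34.0), focal_prob=0.37, stress_mean=0.0),
        "G3": GroupConfig(thomas(54.0), focal_prob=0.12, stress_mean=1.0),
    }


@dataclass(frozen=True)
class SurveyConfig:
    site_groups: dict = field(default_factory=lambda: dict(DEFAULT_SITE_GROUPS))
    groups: dict = field(default_factory=_default_groups)
    focal_species: str = "A. verus"
    window: Window = DEFAULT_WINDOW
    soil_profile: SoilProfile = field(default_factory=SoilProfile)
    dieback_beta0: float = 0.0
    dieback_beta1: float = 1.2
    min_focal: int = 10
    min_per_status: int = 2
    max_retries: int = 200

    def __post_init__(self) -> None:
        missing = set(self.site_groups.values()) - set(self.groups)
        if missing:
            raise ValueError(f"no GroupConfig for group(s) {sorted(missing)}")


def _site_species_probs(rng, group: GroupConfig, focal: str) -> dict:
    lo, hi = group.richness_range
    richness = int(rng.integers(lo, hi + 1))
    n_other = max(richness - 1, 1)
    # Symmetric Dirichlet split of the non-focal share: no abundance model is
    # implied by the emulated design, so all companions are exchangeable.
    shares = rng.dirichlet(np.ones(n_other)) * (1.0 - group.focal_prob)
    probs = {focal: group.focal_prob}
    for i, s in enumerate(shares):
        probs[f"sp{i + 1:02d}"] = float(s)
    return probs


def simulate_survey(config: SurveyConfig | None = None, seed=0) -> SurveyDataset:
    """Generate a full multi-site survey dataset.

    Each site gets a clumped community pattern, marks, a latent stress value
    and a matching two-depth soil profile. Sites are redrawn (bounded
    retries) until the realised richness lies in the configured range, the
    focal count reaches ``min_focal``, and both live and dead focal plants
    number at least ``min_per_status``.
    """
    if config is None:
        config = SurveyConfig()
    sites = []
    for site_id, gname in sorted(config.site_groups.items()):
        group = config.groups[gname]
        lo, hi = group.richness_range
        ss = derive_seed(seed, "site", site_id)
        rng = np.random.default_rng(ss)
        for attempt in range(config.max_retries):
            stress = group.stress_mean + group.stress_sd * rng.standard_normal()
            p_dead = 1.0 / (
                1.0
                + np.exp(-(config.dieback_beta0 + config.dieback_beta1 * stress))
            )
            pattern = simulate_pattern(group.process, config.window, rng)
            if pattern.n < config.min_focal + 4:
                continue
            probs = _site_species_probs(rng, group, config.focal_species)
            spec = MarkSpec(
                species_probs=probs,
                focal_species=config.focal_species,
                status_model=("random_labeling", float(p_dead)),
            )
            marked = assign_marks(pattern, spec, rng)
            focal = marked.species == config.focal_species
            n_live = int((marked.status == "live").sum())
            n_dead = int((marked.status == "dead").sum())
            richness = len(set(marked.species.astype(str)))
            if (
                lo <= richness <= hi
                and focal.sum() >= config.min_focal
                and n_live >= config.min_per_status
                and n_dead >= config.min_per_status
            ):
                break
        else:
            raise ValueError(
                f"site {site_id}: constraints unattainable after "
                f"{config.max_retries} retries"
            )
        soil = simulate_site_soil(
            config.soil_profile, stress, seed=rng, site_id=site_id
        )
        e_lo, e_hi = group.elevation_range
        metadata = {
            "elevation_m": float(np.round(rng.uniform(e_lo, e_hi), 0)),
            "aspect": str(
                rng.choice(["N", "NE", "E", "SE", "S", "SW", "W", "NW"])
            ),
            "mat_c": group.mat_c,
            "stress": float(stress),
        }
        sites.append(
            SiteRecord(
                site_id=site_id,
                group=gname,
                pattern=marked,
                soil=soil,
                metadata=metadata,
            )
        )
    return SurveyDataset(sites=sites, focal_species=config.focal_species)


def survey_to_tables(dataset: SurveyDataset):
    """Stems / soil / metadata frames in the documented CSV dialects."""
    stems = pd.concat(
        [s.pattern.to_frame(site_id=s.site_id) for s in dataset.sites],
        ignore_index=True,
    )
    soil = pd.concat([s.soil for s in dataset.sites], ignore_index=True)
    meta = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "group": s.group,
                "elevation_m": s.metadata.get("elevation_m"),
                "aspect": s.metadata.get("aspect"),
                "mat_c": s.metadata.get("mat_c"),
            }
            for s in dataset.sites
        ]
    )
    return stems, soil, meta
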