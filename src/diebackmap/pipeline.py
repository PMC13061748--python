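"""Full-pipeline orchestration: one config in, a reproducible report out.

``run_pipeline`` executes the stages in order — data model / IO, community
statistics, neighbourhood structure, Ripley envelopes, soil gradient — for
every site of a survey (read from CSVs or simulated), and writes the result
tables as CSV plus a JSON run manifest (seed, config hash, package version)
sufficient to reproduce every number. Identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import (
    abundance_from_pattern,
    compare_groups,
    dieback_percentage,
    diversity_profile,
    group_summary,
    site_summary,
)
from .pattern import (
    DEFAULT_WINDOW,
    PointPattern,
    SiteRecord,
    SurveyDataset,
    Window,
    read_site_metadata,
    read_stem_map,
)
from .ripley import DistanceGrid, envelope_to_frame, monte_carlo_envelope
from .soil import dieback_soil_correlation, pca_soil, read_soil_table, site_predictors
from .structure import structural_summary
from .synthetic import SurveyConfig, derive_seed, simulate_survey

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs (CSV paths) or a simulation spec, plus analysis settings."""

    stems_path: str | None = None
    soil_path: str | None = None
    metadata_path: str | None = None
    simulate: bool = False
    survey_config: SurveyConfig | None = None
    focal_species: str = "A. verus"
    window: tuple[float, float] = (1000.0, 1000.0)
    r_max: float = 500.0
    dr: float = 10.0
    n_sims: int = 500
    level: float = 95.0
    k_neighbors: int = 4
    seed: int = 0
    out_dir: str = "diebackmap_out"

    def validate(self) -> None:
        if not self.simulate and self.stems_path is None:
            raise ValueError(
                "configuration needs input paths or simulate=true"
            )
        if self.simulate and self.stems_path is not None:
            raise ValueError("give either input paths or simulate, not both")
        if self.n_sims < 20:
            raise ValueError("n_sims must be >= 20")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # output location does not affect results
        return hashlib.sha256(
            json.dumps(payload, default=str, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    diversity: pd.DataFrame
    site_table: pd.DataFrame
    group_means: pd.DataFrame
    comparisons: pd.DataFrame
    envelopes: pd.DataFrame
    structure: pd.DataFrame
    soil_loadings: pd.DataFrame | None
    soil_scores: pd.DataFrame | None
    soil_explained: pd.Series | None
    dieback_correlations: pd.Series | None
    manifest: dict = field(default_factory=dict)


def _load_survey(config: PipelineConfig) -> SurveyDataset:
    if config.simulate:
        sc = config.survey_config or SurveyConfig()
        return simulate_survey(sc, seed=config.seed)
    window = Window(*config.window)
    stems = pd.read_csv(config.stems_path)
    meta = (
        read_site_metadata(config.metadata_path)
        if config.metadata_path
        else None
    )
    soil = read_soil_table(config.soil_path) if config.soil_path else None
    sites = []
    for sid in sorted(stems["site_id"].unique()):
        pattern = read_stem_map(config.stems_path, window, site_id=int(sid))
        group = "G1"
        metadata = {}
        if meta is not None:
            row = meta[meta["site_id"] == sid]
            if not row.empty:
                group = str(row["group"].iloc[0])
                metadata = row.iloc[0].to_dict()
        site_soil = (
            soil[soil["site_id"] == sid].reset_index(drop=True)
            if soil is not None
            else None
        )
        sites.append(
            SiteRecord(int(sid), group, pattern, site_soil, metadata)
        )
    return SurveyDataset(sites, focal_species=config.focal_species)


def _site_envelopes(
    site: SiteRecord, focal: str, grid: DistanceGrid, config: PipelineConfig
) -> list[pd.DataFrame]:
    """The three per-site envelope analyses of the study design."""
    frames = []
    analyses = []
    pat = site.pattern
    analyses.append(("all_species_univariate", pat, "univariate", None, None))
    focal_pat = pat.subset(pat.species == focal)
    if focal_pat.n >= 2:
        analyses.append(("focal_univariate", focal_pat, "univariate", None, None))
    has_live = np.any(pat.status == "live")
    has_dead = np.any(pat.status == "dead")
    if has_live and has_dead:
        analyses.append(("live_dead_bivariate", pat, "bivariate", "live", "dead"))
    for name, p, kind, ma, mb in analyses:
        env = monte_carlo_envelope(
            p,
            kind=kind,
            mark_a=ma,
            mark_b=mb,
            grid=grid,
            n_sims=config.n_sims,
            level=config.level,
            seed=derive_seed(config.seed, "ripley", name, site.site_id),
        )
        frame = envelope_to_frame(env)
        frame.insert(0, "analysis", name)
        frame.insert(0, "site_id", site.site_id)
        frames.append(frame)
    return frames


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    t0 = time.perf_counter()
    survey = _load_survey(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- community stage -------------------------------------------------
    logger.info("community statistics for %d sites", len(survey.sites))
    site_table = site_summary(survey)
    site_table["dieback_pct"] = [
        dieback_percentage(r.focal_dead, r.focal_total)
        if r.focal_total > 0
        else np.nan
        for r in site_table.itertuples()
    ]
    div_rows = {}
    for site in survey.sites:
        prof = diversity_profile(abundance_from_pattern(site.pattern))
        div_rows[site.site_id] = prof.as_series()
    diversity = pd.DataFrame(div_rows).T
    diversity.index.name = "site_id"
    diversity.insert(0, "group", site_table["group"])
    group_means = group_summary(
        site_table.drop(columns=["dieback_pct"])
    )
    comp_rows = []
    labels = site_table["group"].to_numpy()
    for index_name in diversity.columns.drop("group"):
        gc = compare_groups(
            diversity[index_name].to_numpy(dtype=float), labels, index_name
        )
        row = {"index": index_name, "H": gc.h, "p": gc.p}
        for (g1, g2), (u, pu) in gc.pairwise.items():
            row[f"U_{g1}_{g2}"] = u
            row[f"p_{g1}_{g2}"] = pu
        comp_rows.append(row)
    comparisons = pd.DataFrame(comp_rows).set_index("index")

    # --- neighbourhood structure -----------------------------------------
    logger.info("structural indices (k = %d)", config.k_neighbors)
    struct_frames = []
    for site in survey.sites:
        for subgroup in ("all", "live", "dead"):
            try:
                summ = structural_summary(
                    site.pattern,
                    subgroup,
                    survey.focal_species,
                    k=config.k_neighbors,
                )
            except ValueError as exc:
                logger.warning(
                    "site %d subgroup %s skipped: %s", site.site_id, subgroup, exc
                )
                continue
            rec = summ.records.copy()
            rec.insert(0, "subgroup", subgroup)
            rec.insert(0, "site_id", site.site_id)
            struct_frames.append(rec)
    structure = (
        pd.concat(struct_frames, ignore_index=True)
        if struct_frames
        else pd.DataFrame(columns=["site_id", "subgroup", "reference_id", "m", "u", "w"])
    )

    # --- Ripley envelopes --------------------------------------------------
    logger.info("Monte Carlo envelopes (%d sims per analysis)", config.n_sims)
    grid = DistanceGrid.regular(config.r_max, config.dr)
    env_frames = []
    for site in survey.sites:
        env_frames.extend(
            _site_envelopes(site, survey.focal_species, grid, config)
        )
    envelopes = pd.concat(env_frames, ignore_index=True)

    # --- soil gradient -----------------------------------------------------
    soil_loadings = soil_scores = soil_explained = dieback_corr = None
    soil_tables = [s.soil for s in survey.sites if s.soil is not None]
    if soil_tables:
        soil = pd.concat(soil_tables, ignore_index=True)
        predictors = site_predictors(soil)
        dieback = site_table["dieback_pct"].reindex(predictors.index)
        pca = pca_soil(predictors, dieback=dieback)
        soil_loadings = pca.loadings
        soil_scores = pca.scores
        soil_explained = pd.Series(
            pca.explained_pct, index=pca.loadings.columns, name="explained_pct"
        )
        if pca.supplementary is not None:
            soil_loadings = soil_loadings.copy()
            soil_loadings.loc["dieback_supplementary"] = pca.supplementary
        if len(predictors) >= 4:
            dieback_corr = dieback_soil_correlation(predictors, dieback)
        else:
            logger.warning(
                "fewer than 4 sites: skipping dieback-soil rank correlations"
            )

    manifest = {
        "package": "diebackmap",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_sites": len(survey.sites),
        "elapsed_s": round(time.perf_counter() - t0, 2),
    }

    report = RunReport(
        diversity, site_table, group_means, comparisons, envelopes,
        structure, soil_loadings, soil_scores, soil_explained, dieback_corr,
        manifest,
    )
    _write_report(report, out_dir)
    return report


def _write_report(report: RunReport, out_dir: Path) -> None:
    fmt = "%.10g"
    report.diversity.to_csv(out_dir / "diversity.csv", float_format=fmt)
    report.site_table.to_csv(out_dir / "sites.csv", float_format=fmt)
    report.group_means.to_csv(out_dir / "group_means.csv", float_format=fmt)
    report.comparisons.to_csv(out_dir / "group_comparisons.csv", float_format=fmt)
    report.envelopes.to_csv(out_dir / "envelopes.csv", index=False, float_format=fmt)
    report.structure.to_csv(out_dir / "structure.csv", index=False, float_format=fmt)
    if report.soil_loadings is not None:
        report.soil_loadings.to_csv(out_dir / "soil_pca_loadings.csv", float_format=fmt)
        report.soil_scores.to_csv(out_dir / "soil_pca_scores.csv", float_format=fmt)
        report.soil_explained.to_csv(out_dir / "soil_pca_explained.csv", float_format=fmt)
        if report.dieback_correlations is not None:
            report.dieback_correlations.to_csv(
                out_dir / "dieback_soil_correlations.csv", float_format=fmt,
                header=["spearman_rho"],
            )
    manifest = dict(report.manifest)
    manifest.pop("elapsed_s", None)  # keep manifest byte-stable across runs
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
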