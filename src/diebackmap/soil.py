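"""Soil predictors, correlation PCA with a supplementary dieback variable,
and dieback-soil correlation screening.

Each site contributes soil samples from two depth layers (0-25 and 25-50
cm): saturated percentage SP (moisture), texture fractions (sand, silt,
clay, summing to 100), pH and electrical conductivity EC (dS/m). Layer
values are combined into one value per site by thickness-weighted means
(equal layers -> arithmetic mean).

The ordination is a correlation-matrix PCA: soil variables are standardised
to zero mean / unit variance (they live on incommensurate scales — %, pH
units, dS/m), the correlation matrix is eigen-decomposed, and sites are
scored on the axes. Dieback percentage enters as a *supplementary* (passive)
variable: it is projected onto the axes afterwards, as its Pearson
correlation with the site scores, and never influences the decomposition —
including the response in the ordination would make the recovered "soil
gradient" circular. A flag allows active inclusion for comparison.

Dieback-soil screening uses Spearman rank correlations (12 sites warrant no
distributional assumptions).

The module also houses the latent-axis soil simulator used by the synthetic
survey generator: a single site-level stress axis pushes sand and EC up and
SP, silt and clay down, with independent noise on pH; texture closure is
enforced by renormalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SOIL_VARIABLES",
    "SoilProfile",
    "PcaResult",
    "depth_weighted_mean",
    "pca_soil",
    "dieback_soil_correlation",
    "simulate_site_soil",
    "read_soil_table",
]

#: Soil predictor columns, in canonical order.
SOIL_VARIABLES = ["sp_pct", "sand_pct", "silt_pct", "clay_pct", "ph", "ec_dsm"]

#: Columns of the soil CSV dialect.
SOIL_COLUMNS = ["site_id", "depth_top_cm", "depth_bottom_cm"] + SOIL_VARIABLES

TEXTURE = ["sand_pct", "silt_pct", "clay_pct"]


def _check_soil_frame(df: pd.DataFrame) -> None:
    missing = [c for c in SOIL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"soil table lacks column(s) {missing}")
    tex = df[TEXTURE].sum(axis=1)
    if np.any(np.abs(tex - 100.0) > 0.5):
        raise ValueError("texture fractions must sum to 100 +/- 0.5")
    if np.any(df["depth_top_cm"] >= df["depth_bottom_cm"]):
        raise ValueError("need depth_top_cm < depth_bottom_cm")
    if np.any(df["ec_dsm"] < 0):
        raise ValueError("EC must be non-negative")


def read_soil_table(path) -> pd.DataFrame:
    """Read and validate the soil CSV dialect."""
    df = pd.read_csv(path)
    _check_soil_frame(df)
    return df


def depth_weighted_mean(samples: pd.DataFrame) -> pd.Series:
    """Thickness-weighted mean of one site's soil layers.

    ``samples`` holds one row per depth layer. Layers may not overlap.
    Equal-thickness layers reduce to the arithmetic mean.
    """
    if samples.empty:
        raise ValueError("no soil samples for site")
    intervals = sorted(
        zip(samples["depth_top_cm"], samples["depth_bottom_cm"])
    )
    for (t1, b1), (t2, b2) in zip(intervals, intervals[1:]):
        if t2 < b1:
            raise ValueError(
                f"overlapping depth intervals [{t1}, {b1}] and [{t2}, {b2}]"
            )
    thickness = (samples["depth_bottom_cm"] - samples["depth_top_cm"]).to_numpy(
        dtype=float
    )
    weights = thickness / thickness.sum()
    return pd.Series(
        {
            v: float(np.dot(weights, samples[v].to_numpy(dtype=float)))
            for v in SOIL_VARIABLES
        }
    )


def site_predictors(soil: pd.DataFrame) -> pd.DataFrame:
    """Depth-weighted predictors for every site in a soil table."""
    _check_soil_frame(soil)
    rows = {
        int(sid): depth_weighted_mean(sub)
        for sid, sub in soil.groupby("site_id")
    }
    out = pd.DataFrame(rows).T.sort_index()
    out.index.name = "site_id"
    return out


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    loadings: pd.DataFrame  # variables x axes, orthonormal columns
    scores: pd.DataFrame  # sites x axes
    supplementary: pd.Series | None = None  # dieback correlation per axis
    variables: list[str] = field(default_factory=list)


def pca_soil(
    predictors: pd.DataFrame,
    dieback: pd.Series | None = None,
    include_dieback: bool = False,
) -> PcaResult:
    """Correlation-matrix PCA of site-level soil predictors.

    ``dieback`` (percent per site, indexed like ``predictors``) is projected
    post hoc as a supplementary variable unless ``include_dieback`` is set,
    in which case it joins the decomposition. Axis signs follow a
    deterministic convention: the largest-magnitude loading on each axis is
    positive.
    """
    x = predictors.copy()
    if include_dieback:
        if dieback is None:
            raise ValueError("include_dieback requires a dieback series")
        x = x.assign(dieback=dieback.reindex(x.index))
    if x.shape[0] < 3:
        raise ValueError("correlation PCA needs at least 3 sites")
    if x.shape[1] < 2:
        raise ValueError("correlation PCA needs at least 2 variables")
    sd = x.std(ddof=1)
    constant = sd[sd == 0]
    if not constant.empty:
        raise ValueError(
            f"constant variable(s) {constant.index.tolist()}: correlation "
            "undefined"
        )
    z = (x - x.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    # Deterministic signs: largest-|loading| entry positive per axis.
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1
    axes = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=x.columns, columns=axes)
    scores = pd.DataFrame(
        z.to_numpy() @ eigvec, index=x.index, columns=axes
    )
    supp = None
    if dieback is not None and not include_dieback:
        d = dieback.reindex(x.index).to_numpy(dtype=float)
        supp = pd.Series(
            {
                ax: float(np.corrcoef(d, scores[ax].to_numpy())[0, 1])
                for ax in axes
            }
        )
    return PcaResult(
        eigenvalues=eigval,
        explained_pct=100.0 * eigval / eigval.sum(),
        loadings=loadings,
        scores=scores,
        supplementary=supp,
        variables=x.columns.tolist(),
    )


def dieback_soil_correlation(
    predictors: pd.DataFrame, dieback: pd.Series
) -> pd.Series:
    """Spearman correlation of each soil variable with dieback percent."""
    if predictors.shape[0] < 4:
        raise ValueError("need at least 4 sites for rank correlation")
    d = dieback.reindex(predictors.index).to_numpy(dtype=float)
    out = {}
    for col in predictors.columns:
        v = predictors[col].to_numpy(dtype=float)
        if np.all(v == v[0]):
            logger.warning("variable %s is constant; correlation undefined", col)
            out[col] = np.nan
            continue
        rho = stats.spearmanr(v, d).statistic
        out[col] = float(rho)
    return pd.Series(out)


@dataclass(frozen=True)
class SoilProfile:
    """Latent-axis soil simulator parameters.

    ``means`` are the site-level expectations at latent stress 0; ``slopes``
    move each variable per unit of the (roughly standard-normal) stress
    axis — positive for sand and EC, negative for SP, silt and clay, zero
    for pH; ``noise_sd`` adds independent site noise; ``depth_shift`` is the
    deterministic offset of the deeper layer relative to the site mean.
    """

    means: dict = field(
        default_factory=lambda: {
            "sp_pct": 35.0,
            "sand_pct": 45.0,
            "silt_pct": 30.0,
            "clay_pct": 25.0,
            "ph": 7.8,
            "ec_dsm": 1.2,
        }
    )
    slopes: dict = field(
        default_factory=lambda: {
            "sp_pct": -6.0,
            "sand_pct": 10.0,
            "silt_pct": -6.0,
            "clay_pct": -4.0,
            "ph": 0.0,
            "ec_dsm": 0.6,
        }
    )
    noise_sd: dict = field(
        default_factory=lambda: {
            "sp_pct": 1.5,
            "sand_pct": 2.0,
            "silt_pct": 1.5,
            "clay_pct": 1.5,
            "ph": 0.15,
            "ec_dsm": 0.12,
        }
    )
    depth_shift: dict = field(
        default_factory=lambda: {
            "sp_pct": 1.0,
            "sand_pct": -2.0,
            "silt_pct": 1.0,
            "clay_pct": 1.0,
            "ph": 0.05,
            "ec_dsm": 0.05,
        }
    )
    max_retries: int = 100


def simulate_site_soil(
    profile: SoilProfile,
    latent: float,
    seed=None,
    site_id: int = 1,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Two depth layers (0-25, 25-50 cm) for one site on the latent axis.

    Sand and EC increase, SP/silt/clay decrease with ``latent``; texture is
    renormalised to close at 100. ``noise_scale=0`` gives the deterministic
    limit (profile means shifted by slope * latent). Draws yielding negative
    percentages are resampled up to ``profile.max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    for _ in range(profile.max_retries):
        base = {
            v: profile.means[v]
            + profile.slopes[v] * latent
            + noise_scale * profile.noise_sd[v] * rng.standard_normal()
            for v in SOIL_VARIABLES
        }
        rows = []
        ok = True
        for (top, bottom), sign in (((0.0, 25.0), -0.5), ((25.0, 50.0), +0.5)):
            row = {
                "site_id": site_id,
                "depth_top_cm": top,
                "depth_bottom_cm": bottom,
            }
            for v in SOIL_VARIABLES:
                row[v] = base[v] + sign * profile.depth_shift[v]
            tex = sum(row[v] for v in TEXTURE)
            if tex <= 0 or any(row[v] <= 0 for v in TEXTURE):
                ok = False
                break
            for v in TEXTURE:
                row[v] *= 100.0 / tex
            row["ec_dsm"] = max(row["ec_dsm"], 0.01)
            row["sp_pct"] = max(row["sp_pct"], 1.0)
            rows.append(row)
        if ok:
            return pd.DataFrame(rows)
    raise ValueError(
        f"could not draw a valid soil profile after {profile.max_retries} tries"
    )
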