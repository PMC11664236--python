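"""Models of community trait composition and species abundance vs tree cover.

The tested predictor is the percentage of tree cover around each site;
covariates (log floral resource, latitude, longitude, elevation and the
latitude x longitude interaction) disentangle geophysical and methodological
gradients. All predictors are centred and scaled to unit sd before fitting,
and the tree-cover effect is additionally reported as the % change of the
response per +10 percentage points of tree cover, back-converted through the
stored scaling constants.

Community-weighted means are modelled on the natural-log scale (all traits
are positive), species abundances with a hurdle-Poisson law: a Bernoulli
zero hurdle plus a zero-truncated Poisson for positive counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.truncated_model import TruncatedLFPoisson

from . import community as cm
from .allometry import fit_allometry, relative_traits

__all__ = [
    "ScalingConstants",
    "EnvModelFit",
    "HurdleFit",
    "PipelineConfig",
    "scale_predictors",
    "fit_cwm_model",
    "fit_species_model",
    "fit_richness_model",
    "run_full_pipeline",
]

logger = logging.getLogger(__name__)

PREDICTORS = ["tree_cover", "log_floral", "lat", "lon", "elev", "lat_x_lon"]


@dataclass
class ScalingConstants:
    means: dict[str, float]
    sds: dict[str, float]
    floral_offset: float

    def as_dict(self) -> dict:
        return {"means": self.means, "sds": self.sds, "floral_offset": self.floral_offset}


@dataclass
class EnvModelFit:
    response: str
    family: str
    coefficients: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    significant: dict[str, bool]
    percent_change_per_10: float
    percent_change_per_10_ci: tuple[float, float]
    scaling: ScalingConstants
    n_obs: int

    def as_dict(self) -> dict:
        return {
            "response": self.response,
            "family": self.family,
            "coefficients": self.coefficients,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "significant": self.significant,
            "percent_change_per_10": self.percent_change_per_10,
            "percent_change_per_10_ci": list(self.percent_change_per_10_ci),
            "scaling": self.scaling.as_dict(),
            "n_obs": self.n_obs,
        }


@dataclass
class HurdleFit:
    species: str
    zero_coefficients: dict[str, float]
    count_coefficients: dict[str, float]
    count_ci_low: dict[str, float]
    count_ci_high: dict[str, float]
    direction: str  # '+', '-', or 'ns' from the count-part tree-cover interval
    n_obs: int
    n_present: int
    degenerate_zero_part: bool = False

    def as_dict(self) -> dict:
        return {
            "species": self.species,
            "zero_coefficients": self.zero_coefficients,
            "count_coefficients": self.count_coefficients,
            "count_ci_low": self.count_ci_low,
            "count_ci_high": self.count_ci_high,
            "direction": self.direction,
            "n_obs": self.n_obs,
            "n_present": self.n_present,
            "degenerate_zero_part": self.degenerate_zero_part,
        }


# ---------------------------------------------------------------------------
# predictor scaling


def scale_predictors(env: pd.DataFrame) -> tuple[pd.DataFrame, ScalingConstants]:
    """Build the standardised design matrix from a site environment table.

    Floral resource is log-transformed after adding half the minimum
    positive value (so zeros are representable); every predictor is then
    centred and scaled to unit sd. The latitude x longitude interaction is
    the product of the two *scaled* columns. Rows with missing values are
    dropped with a log message. Scaling constants are returned for
    back-conversion of coefficients to natural units.
    """
    cols = ["tree_cover_pct", "floral_resource_permille", "lat", "lon", "elev_m"]
    missing = [c for c in cols if c not in env.columns]
    if missing:
        raise ValueError(f"environment table is missing columns: {missing}")
    data = env.set_index("site")[cols] if "site" in env.columns else env[cols].copy()
    n0 = len(data)
    data = data.dropna()
    if len(data) < n0:
        logger.info("scale_predictors: dropped %d incomplete row(s)", n0 - len(data))

    floral = data["floral_resource_permille"].to_numpy(dtype=float)
    positive = floral[floral > 0]
    if len(positive) == 0:
        raise ValueError("floral resource is zero everywhere")
    offset = 0.5 * float(positive.min())
    raw = pd.DataFrame(
        {
            "tree_cover": data["tree_cover_pct"],
            "log_floral": np.log(floral + offset),
            "lat": data["lat"],
            "lon": data["lon"],
            "elev": data["elev_m"],
        },
        index=data.index,
    )
    means, sds = {}, {}
    design = pd.DataFrame(index=data.index)
    for col in raw.columns:
        mu = float(raw[col].mean())
        sd = float(raw[col].std(ddof=0))
        if sd == 0:
            raise ValueError(f"predictor '{col}' has zero variance")
        means[col], sds[col] = mu, sd
        design[col] = (raw[col] - mu) / sd
    design["lat_x_lon"] = design["lat"] * design["lon"]
    return design, ScalingConstants(means=means, sds=sds, floral_offset=offset)


def _percent_change_per_10(beta_tc: float, sd_tc: float) -> float:
    """% change of a log-scale response per +10 points of tree cover."""
    return 100.0 * (np.exp(beta_tc * 10.0 / sd_tc) - 1.0)


def _fit_to_env_model(
    res, response: str, family: str, design: pd.DataFrame, scaling: ScalingConstants
) -> EnvModelFit:
    names = ["const"] + list(design.columns)
    params = np.asarray(res.params, dtype=float)
    ci = np.asarray(res.conf_int(alpha=0.05), dtype=float)
    coeff = dict(zip(names, params))
    lo = dict(zip(names, ci[:, 0]))
    hi = dict(zip(names, ci[:, 1]))
    # tolerance guards against perfect-fit degeneracy where the interval
    # collapses to float noise around zero
    sig = {k: bool((lo[k] > 1e-10) or (hi[k] < -1e-10)) for k in names}
    sd_tc = scaling.sds["tree_cover"]
    return EnvModelFit(
        response=response,
        family=family,
        coefficients=coeff,
        ci_low=lo,
        ci_high=hi,
        significant=sig,
        percent_change_per_10=_percent_change_per_10(coeff["tree_cover"], sd_tc),
        percent_change_per_10_ci=(
            _percent_change_per_10(lo["tree_cover"], sd_tc),
            _percent_change_per_10(hi["tree_cover"], sd_tc),
        ),
        scaling=scaling,
        n_obs=int(res.nobs),
    )


def fit_cwm_model(
    cwm_values: pd.Series,
    design: pd.DataFrame,
    scaling: ScalingConstants,
    response_name: str = "cwm",
    min_sites: int = 20,
) -> EnvModelFit:
    """Regress log(CWM) on the scaled design (Gaussian linear model).

    The tree-cover effect is summarised as
    ``100 * (exp(beta_tc * 10 / sd_tc) - 1)`` — the % change of the CWM per
    +10 percentage points of tree cover; significance means the 95% interval
    of the scaled coefficient excludes zero.
    """
    common = cwm_values.index.intersection(design.index)
    if len(common) < min_sites:
        raise ValueError(f"need >= {min_sites} sites, got {len(common)}")
    y = cwm_values.loc[common].to_numpy(dtype=float)
    if np.any(y <= 0) or np.any(~np.isfinite(y)):
        raise ValueError("CWM values must be positive (traits are positive quantities)")
    X = sm.add_constant(design.loc[common].to_numpy(dtype=float))
    res = sm.OLS(np.log(y), X).fit()
    return _fit_to_env_model(res, response_name, "gaussian-log", design, scaling)


def fit_species_model(
    abundance: pd.Series,
    design: pd.DataFrame,
    scaling: ScalingConstants | None = None,
    species: str = "",
    zero_part_design: bool = False,
    min_presences: int = 5,
) -> HurdleFit:
    """Hurdle-Poisson fit of one species' abundance across sites.

    The hurdle (zero) part is an intercept-only Bernoulli by default
    (``zero_part_design=True`` switches to a logistic regression on the full
    design). The positive part is a zero-truncated Poisson, log-linear in
    the full scaled design. The direction flag comes from the count-part
    tree-cover 95% interval.
    """
    common = abundance.index.intersection(design.index)
    y = abundance.loc[common].to_numpy(dtype=float)
    X = design.loc[common]
    present = y > 0
    if present.sum() == 0:
        raise ValueError(f"cannot fit hurdle: species '{species}' is never observed")
    if present.sum() < min_presences:
        raise ValueError(
            f"species '{species}' observed at {int(present.sum())} sites; need >= {min_presences}"
        )

    names = ["const"] + list(X.columns)
    degenerate = not bool((~present).any())
    if degenerate:
        warnings.warn(
            f"species '{species}' is present everywhere; zero part is degenerate and "
            "the fit reduces to a truncated-Poisson regression",
            stacklevel=2,
        )
        zero_coeff = {"const": -np.inf}
    elif zero_part_design:
        logit = sm.Logit((~present).astype(float), sm.add_constant(X.to_numpy(dtype=float)))
        zres = logit.fit(disp=0)
        zero_coeff = dict(zip(names, np.asarray(zres.params, dtype=float)))
    else:
        p0 = float((~present).mean())
        zero_coeff = {"const": float(np.log(p0 / (1.0 - p0)))}

    yc = y[present]
    Xc = sm.add_constant(X.to_numpy(dtype=float)[present])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = TruncatedLFPoisson(yc, Xc, truncation=0)
        cres = model.fit(method="bfgs", maxiter=500, disp=0)
    params = np.asarray(cres.params, dtype=float)
    ci = np.asarray(cres.conf_int(alpha=0.05), dtype=float)
    count_coeff = dict(zip(names, params))
    lo = dict(zip(names, ci[:, 0]))
    hi = dict(zip(names, ci[:, 1]))
    if hi["tree_cover"] < 0:
        direction = "-"
    elif lo["tree_cover"] > 0:
        direction = "+"
    else:
        direction = "ns"
    return HurdleFit(
        species=species,
        zero_coefficients=zero_coeff,
        count_coefficients=count_coeff,
        count_ci_low=lo,
        count_ci_high=hi,
        direction=direction,
        n_obs=len(y),
        n_present=int(present.sum()),
        degenerate_zero_part=degenerate,
    )


def fit_richness_model(
    richness: pd.Series,
    design: pd.DataFrame,
    scaling: ScalingConstants,
    min_sites: int = 20,
) -> EnvModelFit:
    """Log-linear Poisson regression of per-site species richness."""
    common = richness.index.intersection(design.index)
    if len(common) < min_sites:
        raise ValueError(f"need >= {min_sites} sites, got {len(common)}")
    y = richness.loc[common].to_numpy(dtype=float)
    X = sm.add_constant(design.loc[common].to_numpy(dtype=float))
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return _fit_to_env_model(res, "richness", "poisson", design, scaling)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineConfig:
    trait_names: tuple[str, ...] = ()
    n_imputation_draws: int = 30
    seed: int = 0
    n_common_species: int = 12
    include_relative: bool = True
    zero_part_design: bool = False
    itd_column: str = "itd"

    def __post_init__(self) -> None:
        if self.n_common_species < 1:
            raise ValueError("n_common_species must be >= 1")


def run_full_pipeline(
    inventory: pd.DataFrame,
    environment: pd.DataFrame,
    species_traits: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """Aggregate -> filter -> impute -> CWM -> scale -> fit, end to end.

    ``species_traits`` holds one row per measured species (column
    ``species``, an ITD column when relative traits are wanted, and the
    trait columns). The report is a plain JSON-serialisable dict with one
    entry per fitted CWM model (absolute and size-relative), per common
    species, and for richness.
    """
    cfg = config or PipelineConfig()
    trait_names = list(cfg.trait_names) or [
        c
        for c in species_traits.columns
        if c not in ("species", cfg.itd_column) and pd.api.types.is_numeric_dtype(species_traits[c])
    ]

    matrix = cm.filter_sites(cm.aggregate_inventory(inventory))
    inventoried = list(matrix.columns)
    draws = cm.impute_missing_traits(
        species_traits[["species", cfg.itd_column] + trait_names]
        if cfg.itd_column in species_traits.columns
        else species_traits[["species"] + trait_names],
        inventoried,
        n_draws=cfg.n_imputation_draws,
        seed=cfg.seed,
    )
    design, scaling = scale_predictors(environment)

    report: dict = {
        "config": {
            "trait_names": trait_names,
            "n_imputation_draws": cfg.n_imputation_draws,
            "seed": cfg.seed,
            "n_common_species": cfg.n_common_species,
        },
        "n_sites": int(len(matrix)),
        "n_species": int(len(inventoried)),
        "cwm_models": {},
        "relative_cwm_models": {},
        "species_models": {},
    }

    for trait in trait_names:
        table = cm.cwm_across_draws(matrix, draws, trait)
        fit = fit_cwm_model(table["cwm"], design, scaling, response_name=trait)
        report["cwm_models"][trait] = fit.as_dict()

    if cfg.include_relative and cfg.itd_column in species_traits.columns:
        for trait in trait_names:
            rel_draws = []
            for d in draws:
                tab = d.traits.reset_index()
                afit = fit_allometry(tab, trait, itd_column=cfg.itd_column)
                rel = relative_traits(afit, tab, itd_column=cfg.itd_column)
                rel_tab = pd.DataFrame({f"rel_{trait}": rel.to_numpy()}, index=d.traits.index)
                rel_draws.append(cm.TraitDraw(draw=d.draw, traits=rel_tab, provenance=d.provenance))
            table = cm.cwm_across_draws(matrix, rel_draws, f"rel_{trait}")
            fit = fit_cwm_model(table["cwm"], design, scaling, response_name=f"rel_{trait}")
            report["relative_cwm_models"][trait] = fit.as_dict()

    totals = matrix.sum(axis=0).sort_values(ascending=False)
    common = list(totals.index[: cfg.n_common_species])
    for sp in common:
        try:
            fit = fit_species_model(
                matrix[sp], design, scaling, species=sp, zero_part_design=cfg.zero_part_design
            )
        except ValueError as exc:
            logger.warning("species model for %s skipped: %s", sp, exc)
            continue
        report["species_models"][sp] = fit.as_dict()

    richness = cm.species_richness(matrix)
    report["richness_model"] = fit_richness_model(richness, design, scaling).as_dict()
    return report
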