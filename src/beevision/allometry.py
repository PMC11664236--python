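"""Allometric scaling of visual traits against body size.

Traits and inter-tegular distance (ITD) are modelled on the natural-log
scale: ``log(trait) = alpha + beta * log(ITD) + eps``. An optional
phylogenetic correlation matrix turns the fit into a phylogenetic GLS with
error covariance proportional to the supplied matrix; the identity matrix
degenerates to the ordinary fit.

Size-relative traits are the back-transformed residuals: the multiplicative
ratio ``trait / exp(alpha + beta * log(ITD))``, which is 1 for a species
sitting exactly on the fitted line.

Measurement repeatability is the variance ratio
``sigma2_species / (sigma2_species + sigma2_resid)`` from a linear mixed
model with body size as fixed effect and species as grouping factor
(REML via statsmodels MixedLM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "AllometryFit",
    "RepeatabilityResult",
    "fit_allometry",
    "relative_traits",
    "repeatability",
]


@dataclass
class AllometryFit:
    trait: str
    intercept: float
    slope: float
    residual_sd: float
    slope_ci: tuple[float, float]
    significant: bool
    phylo_controlled: bool
    n_species: int

    def predict(self, itd: np.ndarray | float) -> np.ndarray | float:
        """Predicted trait value (trait space) at a given ITD."""
        return np.exp(self.intercept + self.slope * np.log(itd))

    def as_dict(self) -> dict:
        return {
            "trait": self.trait,
            "intercept": self.intercept,
            "slope": self.slope,
            "residual_sd": self.residual_sd,
            "slope_ci_low": self.slope_ci[0],
            "slope_ci_high": self.slope_ci[1],
            "significant": self.significant,
            "phylo_controlled": self.phylo_controlled,
            "n_species": self.n_species,
        }


@dataclass
class RepeatabilityResult:
    trait: str
    repeatability: float
    var_species: float
    var_residual: float
    n_species: int
    n_specimens: int


def _validate_positive(table: pd.DataFrame, column: str) -> None:
    bad = table.index[~(table[column] > 0) | ~np.isfinite(table[column])]
    if len(bad):
        raise ValueError(
            f"column '{column}' must be positive and finite; offending rows: {list(bad[:5])}"
        )


def fit_allometry(
    species_means: pd.DataFrame,
    trait: str,
    phylo_corr: pd.DataFrame | None = None,
    itd_column: str = "itd",
) -> AllometryFit:
    """Fit the log-log allometry of one trait against ITD across species.

    Parameters
    ----------
    species_means
        One row per species with positive ``itd`` and trait columns. Rows
        with a missing trait value are dropped.
    trait
        Name of the trait column to model.
    phylo_corr
        Optional species-by-species phylogenetic correlation matrix (indexed
        by species name). When given, the model is a phylogenetic GLS with
        error covariance proportional to this matrix.

    The 95% interval for the slope comes from the t sampling distribution of
    the (G)LS estimator; significance means the interval excludes zero.
    """
    data = species_means.dropna(subset=[trait, itd_column])
    if len(data) < 3:
        raise ValueError(f"need >= 3 species with data for '{trait}', got {len(data)}")
    _validate_positive(data, trait)
    _validate_positive(data, itd_column)

    y = np.log(data[trait].to_numpy(dtype=float))
    X = sm.add_constant(np.log(data[itd_column].to_numpy(dtype=float)))

    if phylo_corr is not None:
        species = data["species"].astype(str).tolist()
        missing = [s for s in species if s not in phylo_corr.index]
        if missing:
            raise ValueError(f"species missing from phylogenetic matrix: {missing}")
        C = phylo_corr.loc[species, species].to_numpy(dtype=float)
        cond = np.linalg.cond(C)
        if not np.isfinite(cond) or cond > 1e10:
            raise ValueError("phylogenetic correlation matrix is singular")
        res = sm.GLS(y, X, sigma=C).fit()
    else:
        res = sm.OLS(y, X).fit()

    ci = res.conf_int(alpha=0.05)
    lo, hi = float(ci[1][0]), float(ci[1][1])
    return AllometryFit(
        trait=trait,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        residual_sd=float(np.sqrt(res.scale)),
        slope_ci=(lo, hi),
        significant=not (lo <= 0.0 <= hi),
        phylo_controlled=phylo_corr is not None,
        n_species=len(data),
    )


def relative_traits(
    fit: AllometryFit,
    observations: pd.DataFrame,
    itd_column: str = "itd",
) -> pd.Series:
    """Size-relative trait per species: observed / allometrically predicted.

    Equals ``exp(log-residual)``; species on the fitted line get exactly 1,
    and the geometric mean across the fitted species is ~1 by construction.
    Species with a missing ITD get NaN.
    """
    trait_vals = observations[fit.trait].to_numpy(dtype=float)
    itd = observations[itd_column].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = trait_vals / np.exp(fit.intercept + fit.slope * np.log(itd))
    out = pd.Series(ratio, index=observations.index, name=f"rel_{fit.trait}")
    n_missing = int(np.sum(~np.isfinite(ratio)))
    if n_missing:
        warnings.warn(
            f"{n_missing} species lack ITD or trait values; relative trait set to NaN",
            stacklevel=2,
        )
        out[~np.isfinite(ratio)] = np.nan
    return out


def repeatability(
    specimens: pd.DataFrame,
    trait: str,
    itd_column: str = "itd",
    species_column: str = "species",
) -> RepeatabilityResult:
    """Variance-ratio repeatability of a trait among replicated species.

    Fits ``log(trait) ~ log(ITD)`` with a species random intercept (REML)
    and returns ``R = var_species / (var_species + var_residual)``. Only
    species with at least two specimens enter the model.
    """
    data = specimens.dropna(subset=[trait, itd_column]).copy()
    counts = data[species_column].value_counts()
    replicated = counts[counts >= 2].index
    data = data[data[species_column].isin(replicated)]
    if data[species_column].nunique() < 2:
        raise ValueError("repeatability undefined: need >= 2 species with >= 2 specimens")
    _validate_positive(data, trait)
    _validate_positive(data, itd_column)

    y = np.log(data[trait].to_numpy(dtype=float))
    X = sm.add_constant(np.log(data[itd_column].to_numpy(dtype=float)))
    groups = data[species_column].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-sample REML convergence chatter
        model = MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)
    var_species = float(np.asarray(res.cov_re)[0, 0])
    var_resid = float(res.scale)
    r = var_species / (var_species + var_resid)
    return RepeatabilityResult(
        trait=trait,
        repeatability=float(np.clip(r, 0.0, 1.0)),
        var_species=var_species,
        var_residual=var_resid,
        n_species=int(data[species_column].nunique()),
        n_specimens=len(data),
    )
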