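"""Five-coefficient linear RT/CCS trend models and measured-vs-predicted
database comparison.

The trend model regresses the species-mean response on
``[1, CC, DB, I(alkyl), I(alkenyl)]``. Per-term explained sums of
squares are computed by term deletion (refit without the term; report
the RSS increase), which is order-independent. The database comparison
fits, per linkage subclass, a zero-intercept slope of measured on
predicted CCS with its SD and an AIC of ``n*ln(RSS/n) + 2k`` (k = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from lipidims.shorthand import Linkage, LipidSpecies, parse_shorthand

__all__ = [
    "TrendModel",
    "SubclassFit",
    "species_means",
    "fit_trend",
    "predict",
    "compare_to_predictions",
]

logger = logging.getLogger(__name__)

TERMS = ("intercept", "cc", "db", "alkyl", "alkenyl")


@dataclass(frozen=True)
class TrendModel:
    """Fitted linear model for one response (RT or CCS).

    ``coefficients`` and ``standard_errors`` map term name
    (``intercept``, ``cc``, ``db``, ``alkyl``, ``alkenyl``) to value;
    ``explained_ss`` maps each non-intercept term to its deletion sum
    of squares (RSS without the term minus full-model RSS, >= 0).
    """

    response: str
    log_response: bool
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    residual_ss: float
    explained_ss: dict[str, float]
    n_species: int
    interactions: bool = False
    extra_coefficients: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SubclassFit:
    """Zero-intercept measured-vs-predicted fit for one subclass."""

    subclass: str
    slope: float
    slope_sd: float
    n: int
    aic: float
    rss: float

    def as_dict(self) -> dict:
        return asdict(self)


def species_means(features: pd.DataFrame, response: str) -> pd.Series:
    """Mean response per species across all samples."""
    if response not in features.columns:
        raise KeyError(f"response column {response!r} not in feature table")
    return features.groupby("species")[response].mean()


def _design_row(sp: LipidSpecies, interactions: bool) -> list[float]:
    alkyl = 1.0 if sp.linkage is Linkage.ALKYL else 0.0
    alkenyl = 1.0 if sp.linkage is Linkage.ALKENYL else 0.0
    row = [1.0, float(sp.cc), float(sp.db), alkyl, alkenyl]
    if interactions:
        row.append(float(sp.cc) * float(sp.db))
    return row


def _design_matrix(
    species: list[LipidSpecies], interactions: bool
) -> tuple[np.ndarray, list[str]]:
    names = list(TERMS)
    if interactions:
        names.append("cc_x_db")
    X = np.array([_design_row(sp, interactions) for sp in species])
    return X, names


def fit_trend(
    features: pd.DataFrame,
    response: Literal["rt", "ccs"],
    log_response: bool = False,
    interactions: bool = False,
) -> TrendModel:
    """Fit the 5-coefficient trend model on species-level means.

    Requires >= 6 distinct species spanning >= 2 CC values and >= 2
    linkage types. With ``log_response`` the natural log of the
    species-mean response is modelled, which makes multiplicative
    (relative-%) effects linear — the natural scale for RT.
    """
    means = species_means(features, response)
    species = [parse_shorthand(name).at_species_level() for name in means.index]
    if len(species) < 6:
        raise ValueError(f"need >= 6 distinct species, got {len(species)}")
    if len({sp.cc for sp in species}) < 2 or len({sp.linkage for sp in species}) < 2:
        raise ValueError("species must span >= 2 CC values and >= 2 linkage types")

    y = means.to_numpy(dtype=float)
    if log_response:
        if np.any(y <= 0):
            raise ValueError("log_response requires strictly positive responses")
        y = np.log(y)
    X, names = _design_matrix(species, interactions)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "singular design: species grid does not identify all terms"
        )
    fit = sm.OLS(y, X).fit()
    rss_full = float(fit.ssr)

    explained = {}
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        X_sub = np.delete(X, j, axis=1)
        rss_sub = float(sm.OLS(y, X_sub).fit().ssr)
        explained[name] = max(rss_sub - rss_full, 0.0)

    coefs = dict(zip(names, map(float, fit.params)))
    ses = dict(zip(names, map(float, fit.bse)))
    extra = {k: coefs.pop(k) for k in list(coefs) if k not in TERMS}
    for k in list(ses):
        if k not in TERMS:
            ses.pop(k)
    return TrendModel(
        response=response,
        log_response=log_response,
        coefficients=coefs,
        standard_errors=ses,
        residual_ss=rss_full,
        explained_ss=explained,
        n_species=len(species),
        interactions=interactions,
        extra_coefficients=extra,
    )


def predict(model: TrendModel, species: LipidSpecies | str) -> float:
    """Evaluate the trend model for one species.

    Returns the response on its original scale (exponentiates when the
    model was fitted on the log response).
    """
    sp = species if isinstance(species, LipidSpecies) else parse_shorthand(species)
    sp = sp.at_species_level()
    coefs = dict(model.coefficients)
    coefs.update(model.extra_coefficients)
    row = _design_row(sp, model.interactions)
    names = list(TERMS) + (["cc_x_db"] if model.interactions else [])
    value = float(sum(coefs[n] * v for n, v in zip(names, row)))
    return float(np.exp(value)) if model.log_response else value


def _species_level_means(table: pd.DataFrame, value_col: str) -> pd.Series:
    """Collapse molecular-species rows to species-level means."""
    level = table["species"].map(
        lambda s: parse_shorthand(str(s)).at_species_level().name
    )
    return table.assign(_species=level).groupby("_species")[value_col].mean()


def compare_to_predictions(
    features: pd.DataFrame,
    predicted: pd.DataFrame,
    zero_intercept: bool = True,
) -> dict[str, SubclassFit]:
    """Measured-vs-predicted CCS regression per linkage subclass.

    ``predicted`` needs columns ``species`` and ``predicted_ccs``;
    molecular-species entries are averaged to species level before
    matching. Default is a zero-intercept fit so that a slope of 1
    means perfect proportional agreement; set ``zero_intercept=False``
    for a free intercept.

    Subclasses with fewer than 3 matched species are skipped with a
    logged warning.
    """
    measured = species_means(features, "ccs")
    pred = _species_level_means(predicted, "predicted_ccs")
    shared = measured.index.intersection(pred.index)

    groups: dict[str, list[str]] = {}
    for name in shared:
        linkage = parse_shorthand(name).linkage.value
        groups.setdefault(linkage, []).append(name)

    fits: dict[str, SubclassFit] = {}
    for subclass in ("acyl", "alkyl", "alkenyl"):
        names = groups.get(subclass, [])
        if len(names) < 3:
            logger.warning(
                "SUBCLASS-SKIPPED %s: only %d matched species (need >= 3)",
                subclass, len(names),
            )
            continue
        p = pred.loc[names].to_numpy(dtype=float)
        m = measured.loc[names].to_numpy(dtype=float)
        n = len(names)
        if zero_intercept:
            X = p[:, None]
        else:
            X = np.column_stack([np.ones(n), p])
        fit = sm.OLS(m, X).fit()
        slope = float(fit.params[-1])
        slope_sd = float(fit.bse[-1])
        rss = float(fit.ssr)
        k = X.shape[1]
        aic = n * np.log(rss / n) + 2 * k if rss > 0 else float("-inf")
        fits[subclass] = SubclassFit(
            subclass=subclass, slope=slope, slope_sd=slope_sd,
            n=n, aic=float(aic), rss=rss,
        )
    return fits
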