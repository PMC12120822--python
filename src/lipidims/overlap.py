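"""Gaussian two-peak overlap analytics in the CCS dimension.

Conventions (fixed throughout): peaks are equal-variance Gaussians with
standard deviation ``sigma``; ``fwhm = 2*sqrt(2*ln 2)*sigma``;
two-peak resolution ``Rs = delta/(4*sigma)`` (base-width convention);
resolving power ``Rp = mean_ccs/fwhm``. For a 1:1 mixture of two such
peaks classified at the midpoint between the centers, the
misclassification probability is ``Phi(-delta/(2*sigma))`` with ``Phi``
the standard normal CDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "SIGMA_TO_FWHM",
    "OverlapResult",
    "overlap_from_resolving_power",
    "overlap_from_sigma",
    "required_resolving_power",
    "resolving_power_for_resolution",
    "error_probability_curve",
    "weighted_sd",
    "mean_isobar_separation",
    "simulate_misclassification",
]

#: FWHM of a Gaussian divided by its standard deviation.
SIGMA_TO_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class OverlapResult:
    """Geometry and error statistics of a two-Gaussian CCS overlap.

    Attributes
    ----------
    delta_ccs : float
        Peak-center separation, A^2.
    mean_ccs : float
        Mean CCS of the pair (sets the resolving-power scale), A^2.
    sigma : float
        Common Gaussian standard deviation, A^2.
    fwhm : float
        Full width at half maximum, A^2.
    resolution : float
        ``delta_ccs / (4 * sigma)``.
    resolving_power : float
        ``mean_ccs / fwhm``.
    error_probability : float
        Misclassification probability for the 1:1 mixture, in [0, 0.5].
    p_correct : float
        ``1 - error_probability``.
    """

    delta_ccs: float
    mean_ccs: float
    sigma: float
    fwhm: float
    resolution: float
    resolving_power: float
    error_probability: float
    p_correct: float

    def as_dict(self) -> dict:
        return asdict(self)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0 and math.isfinite(value)):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


def overlap_from_sigma(delta_ccs: float, mean_ccs: float, sigma: float) -> OverlapResult:
    """Build an :class:`OverlapResult` from an explicit peak width."""
    _require_positive(delta_ccs=delta_ccs, mean_ccs=mean_ccs, sigma=sigma)
    fwhm = SIGMA_TO_FWHM * sigma
    err = float(norm.cdf(-delta_ccs / (2.0 * sigma)))
    return OverlapResult(
        delta_ccs=delta_ccs,
        mean_ccs=mean_ccs,
        sigma=sigma,
        fwhm=fwhm,
        resolution=delta_ccs / (4.0 * sigma),
        resolving_power=mean_ccs / fwhm,
        error_probability=err,
        p_correct=1.0 - err,
    )


def overlap_from_resolving_power(
    delta_ccs: float, mean_ccs: float, resolving_power: float
) -> OverlapResult:
    """Overlap geometry at a given IMS resolving power.

    ``sigma`` is derived from the peak width implied by the resolving
    power: ``fwhm = mean_ccs / resolving_power``.
    """
    _require_positive(
        delta_ccs=delta_ccs, mean_ccs=mean_ccs, resolving_power=resolving_power
    )
    sigma = (mean_ccs / resolving_power) / SIGMA_TO_FWHM
    return overlap_from_sigma(delta_ccs, mean_ccs, sigma)


def required_resolving_power(
    delta_ccs: float, mean_ccs: float, target_error: float
) -> OverlapResult:
    """Resolving power needed to reach a target misclassification rate.

    Closed-form inversion of the midpoint-boundary error model:
    ``sigma = delta/(2 * Phi^-1(1 - target_error))``. Round-trips with
    :func:`overlap_from_resolving_power` to machine precision.
    """
    _require_positive(delta_ccs=delta_ccs, mean_ccs=mean_ccs)
    if not 0.0 < target_error < 0.5:
        raise ValueError(
            f"target_error must lie in (0, 0.5), got {target_error!r}"
        )
    sigma = delta_ccs / (2.0 * float(norm.ppf(1.0 - target_error)))
    return overlap_from_sigma(delta_ccs, mean_ccs, sigma)


def resolving_power_for_resolution(
    delta_ccs: float, mean_ccs: float, target_resolution: float
) -> OverlapResult:
    """Resolving power at which the pair reaches a target resolution."""
    _require_positive(
        delta_ccs=delta_ccs, mean_ccs=mean_ccs, target_resolution=target_resolution
    )
    sigma = delta_ccs / (4.0 * target_resolution)
    return overlap_from_sigma(delta_ccs, mean_ccs, sigma)


def error_probability_curve(
    delta_ccs: float, mean_ccs: float, resolving_powers: Iterable[float]
):
    """Error probability over a grid of resolving powers.

    Returns a pandas DataFrame with columns ``resolving_power``,
    ``resolution`` and ``error_probability`` (one row per grid point).
    """
    import pandas as pd

    rows = [
        overlap_from_resolving_power(delta_ccs, mean_ccs, rp) for rp in resolving_powers
    ]
    return pd.DataFrame(
        {
            "resolving_power": [r.resolving_power for r in rows],
            "resolution": [r.resolution for r in rows],
            "error_probability": [r.error_probability for r in rows],
        }
    )


def weighted_sd(values: Sequence[float], weights: Sequence[float]) -> float:
    """Frequency-weighted population standard deviation.

    ``sqrt( sum(w * (x - xbar_w)^2) / sum(w) )`` with ``xbar_w`` the
    weighted mean — the convention of R's ``descriptio::weighted.sd``.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("values and weights must have the same length")
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    wsum = w.sum()
    if wsum == 0:
        raise ValueError("weights must not all be zero")
    mean = float(np.sum(w * x) / wsum)
    return float(math.sqrt(np.sum(w * (x - mean) ** 2) / wsum))


def mean_isobar_separation(deltas: Sequence[float]) -> float:
    """Unweighted mean of absolute per-pair CCS differences.

    Summarizes alkenyl-vs-alkyl isobar pair deltas into the single
    peak separation fed to the overlap model.
    """
    arr = np.asarray(deltas, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one pair delta")
    return float(np.mean(np.abs(arr)))


def simulate_misclassification(
    delta_ccs: float,
    sigma: float,
    n_draws: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo misclassification rate for the 1:1 two-Gaussian mixture.

    Draws ``n_draws`` observations (components chosen with equal
    probability, centers 0 and ``delta_ccs``) and classifies at the
    midpoint. Serves as an independent stochastic oracle for
    ``error_probability``.
    """
    _require_positive(delta_ccs=delta_ccs, sigma=sigma)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    component = rng.integers(0, 2, size=n_draws)
    x = rng.normal(loc=component * delta_ccs, scale=sigma)
    predicted = (x > delta_ccs / 2.0).astype(int)
    return float(np.mean(predicted != component))
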