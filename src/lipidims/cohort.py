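"""Synthetic 4D-lipidomics cohort generator.

Emulates the study design the downstream analytics assume: three
tissues x two genotypes x n replicates, a PE species grid over
cumulative carbons and double bonds, plasmalogen (P-) species present
only in wild-type samples and 1-O-alkyl (O-) species only in
desaturase-deficient samples. RT effects are multiplicative
(log-linear) so relative deltas are scale-free; CCS effects are
additive in A^2. Every sample carries its own affine CCS distortion
(what the calibration stage must undo) and a mild affine RT distortion
(what RT alignment must undo). All randomness flows from the design
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from lipidims.overlap import SIGMA_TO_FWHM
from lipidims.shorthand import Linkage, LipidSpecies, mz_deprotonated, parse_shorthand

__all__ = [
    "CohortDesign",
    "GenerativeModel",
    "SimulationResult",
    "species_grid",
    "true_rt",
    "true_ccs",
    "simulate",
    "generate_cohort",
    "reference_ccs_table",
    "predicted_ccs_table",
    "render_mobilogram",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "species",
    "sample_id",
    "tissue",
    "genotype",
    "rt",
    "mz",
    "raw_mobility",
    "ccs",
    "intensity",
]

WILDTYPE = "WT"
KNOCKOUT = "dPeds1"


@dataclass(frozen=True)
class CohortDesign:
    """Study layout: tissues, genotypes, replicates and the species grid."""

    tissues: tuple[str, ...] = ("heart", "cerebellum", "cerebrum")
    genotypes: tuple[str, ...] = (WILDTYPE, KNOCKOUT)
    replicates_per_group: int = 3
    cc_grid: tuple[int, ...] = (34, 36, 38, 40)
    db_grid: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be >= 1")
        if not self.tissues or not self.cc_grid or not len(self.db_grid):
            raise ValueError("tissues, cc_grid and db_grid must be non-empty")

    @property
    def n_samples(self) -> int:
        return len(self.tissues) * len(self.genotypes) * self.replicates_per_group


@dataclass(frozen=True)
class GenerativeModel:
    """Coefficients and noise scales of the RT/CCS generator.

    RT (minutes) is log-linear:
    ``ln RT = rt_log_intercept + rt_log_per_carbon*CC
    + rt_log_per_db*DB_downstream + rt_log_delta1*[Delta-1 present]
    + rt_log_ether*[ether linkage]``
    with per-double-bond and Delta-1 factors defaulting to
    ``ln(1 - 0.117)`` and ``ln(1 - 0.020)``.

    CCS (A^2) is additive: ``ccs_intercept + ccs_per_carbon*CC
    + ccs_per_db*DB_downstream + ccs_delta1*[Delta-1]
    + ccs_ether*[ether]``, with defaults +2.7 per carbon, -1.0 per
    downstream DB and +0.3 for the vinyl-ether bond. Molecular species
    containing a chain with >= ``high_db_chain_threshold`` double bonds
    get an extra fixed CCS offset (bimodal high-DB behavior);
    species-level names never trigger it.
    """

    rt_log_intercept: float = math.log(8.0)
    rt_log_per_carbon: float = math.log(1.025)
    rt_log_per_db: float = math.log(1.0 - 0.117)
    rt_log_delta1: float = math.log(1.0 - 0.020)
    rt_log_ether: float = 0.03

    ccs_intercept: float = 172.0
    ccs_per_carbon: float = 2.7
    ccs_per_db: float = -1.0
    ccs_delta1: float = 0.3
    ccs_ether: float = 0.0
    high_db_chain_ccs_offset: float = 1.5
    high_db_chain_threshold: int = 4

    rt_noise_sd: float = 0.05
    mz_noise_ppm: float = 1.5
    ccs_noise_sd: float = 0.3

    ccs_scale_range: tuple[float, float] = (0.97, 1.03)
    ccs_offset_range: tuple[float, float] = (-5.0, 5.0)
    rt_scale_range: tuple[float, float] = (0.995, 1.005)
    rt_offset_range: tuple[float, float] = (-0.05, 0.05)

    base_intensity: float = 1.0e5
    intensity_log_sd: float = 0.5
    tissue_weights: Optional[dict] = None

    resolving_power: float = 87.0

    def __post_init__(self) -> None:
        for name in ("rt_noise_sd", "mz_noise_ppm", "ccs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.resolving_power <= 0:
            raise ValueError("resolving_power must be > 0")
        for name in (
            "rt_log_intercept", "rt_log_per_carbon", "rt_log_per_db",
            "rt_log_delta1", "rt_log_ether", "ccs_intercept",
            "ccs_per_carbon", "ccs_per_db", "ccs_delta1", "ccs_ether",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulationResult:
    """Feature table plus the ground truth used to generate it."""

    features: pd.DataFrame
    sample_truth: pd.DataFrame  # per-sample affine distortions
    design: CohortDesign
    model: GenerativeModel


def species_grid(design: CohortDesign) -> list[LipidSpecies]:
    """All species on the design grid, for all three linkages."""
    out = []
    for linkage in (Linkage.ACYL, Linkage.ALKYL, Linkage.ALKENYL):
        for cc in design.cc_grid:
            for db in design.db_grid:
                out.append(LipidSpecies("PE", linkage, cc, db))
    return out


def true_rt(species: LipidSpecies, model: GenerativeModel) -> float:
    """Noise-free retention time in minutes."""
    is_ether = species.linkage is not Linkage.ACYL
    is_plasmalogen = species.linkage is Linkage.ALKENYL
    log_rt = (
        model.rt_log_intercept
        + model.rt_log_per_carbon * species.cc
        + model.rt_log_per_db * species.db
        + (model.rt_log_delta1 if is_plasmalogen else 0.0)
        + (model.rt_log_ether if is_ether else 0.0)
    )
    return math.exp(log_rt)


def true_ccs(species: LipidSpecies, model: GenerativeModel) -> float:
    """Noise-free collision cross section in A^2."""
    is_ether = species.linkage is not Linkage.ACYL
    is_plasmalogen = species.linkage is Linkage.ALKENYL
    ccs = (
        model.ccs_intercept
        + model.ccs_per_carbon * species.cc
        + model.ccs_per_db * species.db
        + (model.ccs_delta1 if is_plasmalogen else 0.0)
        + (model.ccs_ether if is_ether else 0.0)
    )
    if species.molecular_chains is not None and any(
        d >= model.high_db_chain_threshold for _, d in species.molecular_chains
    ):
        ccs += model.high_db_chain_ccs_offset
    return ccs


def _species_for_genotype(
    grid: Sequence[LipidSpecies], genotype: str
) -> list[LipidSpecies]:
    # 1-acyl everywhere; P- only in WT; O- only in the knockout.
    keep = {
        WILDTYPE: (Linkage.ACYL, Linkage.ALKENYL),
        KNOCKOUT: (Linkage.ACYL, Linkage.ALKYL),
    }[genotype]
    return [s for s in grid if s.linkage in keep]


def simulate(design: CohortDesign, model: GenerativeModel) -> SimulationResult:
    """Generate the full cohort with ground truth attached.

    One row per (species, sample) respecting genotype occupancy.
    ``raw_mobility = (observed CCS - offset_s) / scale_s`` with
    per-sample affine distortion; the ``ccs`` column is left NaN until
    calibration fills it.
    """
    rng = np.random.default_rng(design.seed)
    grid = species_grid(design)
    mz_by_species = {s.name: mz_deprotonated(s) for s in grid}

    sample_rows = []
    feature_rows = []
    for tissue in design.tissues:
        tissue_w = 1.0
        if model.tissue_weights:
            tissue_w = float(model.tissue_weights.get(tissue, 1.0))
        for genotype in design.genotypes:
            for rep in range(1, design.replicates_per_group + 1):
                sample_id = f"{tissue}_{genotype}_r{rep}"
                ccs_scale = rng.uniform(*model.ccs_scale_range)
                ccs_offset = rng.uniform(*model.ccs_offset_range)
                rt_scale = rng.uniform(*model.rt_scale_range)
                rt_offset = rng.uniform(*model.rt_offset_range)
                sample_rows.append(
                    {
                        "sample_id": sample_id,
                        "tissue": tissue,
                        "genotype": genotype,
                        "ccs_scale": ccs_scale,
                        "ccs_offset": ccs_offset,
                        "rt_scale": rt_scale,
                        "rt_offset": rt_offset,
                    }
                )
                for sp in _species_for_genotype(grid, genotype):
                    rt = true_rt(sp, model) * rt_scale + rt_offset
                    rt += rng.normal(0.0, model.rt_noise_sd) if model.rt_noise_sd else 0.0
                    ccs_obs = true_ccs(sp, model)
                    if model.ccs_noise_sd:
                        ccs_obs += rng.normal(0.0, model.ccs_noise_sd)
                    raw = (ccs_obs - ccs_offset) / ccs_scale
                    mz = mz_by_species[sp.name]
                    if model.mz_noise_ppm:
                        mz *= 1.0 + rng.normal(0.0, model.mz_noise_ppm) * 1e-6
                    intensity = (
                        model.base_intensity
                        * tissue_w
                        * math.exp(rng.normal(0.0, model.intensity_log_sd))
                    )
                    feature_rows.append(
                        {
                            "species": sp.name,
                            "sample_id": sample_id,
                            "tissue": tissue,
                            "genotype": genotype,
                            "rt": rt,
                            "mz": mz,
                            "raw_mobility": raw,
                            "ccs": np.nan,
                            "intensity": intensity,
                        }
                    )
    features = pd.DataFrame(feature_rows, columns=FEATURE_COLUMNS)
    sample_truth = pd.DataFrame(sample_rows)
    return SimulationResult(features, sample_truth, design, model)


def generate_cohort(design: CohortDesign, model: GenerativeModel) -> pd.DataFrame:
    """Feature table only (see :func:`simulate` for ground truth)."""
    return simulate(design, model).features


def reference_ccs_table(design: CohortDesign, model: GenerativeModel) -> pd.DataFrame:
    """1-acyl reference CCS table (species -> true CCS), emulating a
    curated reference database used for calibration anchoring."""
    rows = [
        {"species": sp.name, "ccs_a2": true_ccs(sp, model)}
        for sp in species_grid(design)
        if sp.linkage is Linkage.ACYL
    ]
    return pd.DataFrame(rows)


def predicted_ccs_table(
    design: CohortDesign,
    model: GenerativeModel,
    subclass_bias: Optional[dict] = None,
) -> pd.DataFrame:
    """Predicted-CCS table emulating an in-silico database.

    ``subclass_bias`` maps linkage value ("acyl", "alkyl", "alkenyl")
    to the proportional bias of the *measured* values relative to the
    predictions: predicted = true / bias, so regressing measured on
    predicted recovers the bias as the slope.
    """
    subclass_bias = subclass_bias or {}
    rows = []
    for sp in species_grid(design):
        bias = float(subclass_bias.get(sp.linkage.value, 1.0))
        rows.append(
            {"species": sp.name, "predicted_ccs": true_ccs(sp, model) / bias}
        )
    return pd.DataFrame(rows)


def render_mobilogram(
    features: pd.DataFrame,
    resolving_power: float,
    grid_step: float = 0.02,
    pad_fwhm: float = 4.0,
) -> pd.DataFrame:
    """Sum-of-Gaussians CCS trace for a set of co-isolated features.

    Each feature contributes a Gaussian centered at its ``ccs`` with
    ``FWHM = ccs / resolving_power`` and area equal to its intensity.
    Returns a DataFrame with columns ``ccs`` and ``intensity``.
    """
    if resolving_power <= 0:
        raise ValueError("resolving_power must be > 0")
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    centers = features["ccs"].to_numpy(dtype=float)
    if len(centers) == 0 or np.any(~np.isfinite(centers)):
        raise ValueError("all features need a finite calibrated ccs")
    areas = features["intensity"].to_numpy(dtype=float)
    sigmas = (centers / resolving_power) / SIGMA_TO_FWHM
    lo = centers.min() - pad_fwhm * sigmas.max() * SIGMA_TO_FWHM
    hi = centers.max() + pad_fwhm * sigmas.max() * SIGMA_TO_FWHM
    grid = np.arange(lo, hi + grid_step, grid_step)
    trace = np.zeros_like(grid)
    for mu, sigma, area in zip(centers, sigmas, areas):
        trace += (
            area
            / (sigma * math.sqrt(2.0 * math.pi))
            * np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
        )
    return pd.DataFrame({"ccs": grid, "intensity": trace})
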