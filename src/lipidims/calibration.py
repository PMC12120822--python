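"""Per-sample CCS calibration against 1-acyl references and linear RT
alignment across samples.

Calibration regresses reference CCS on the sample's raw mobility values
over 1-acyl anchor species only (ether species are never anchors) and
applies the fitted affine map to all rows of the sample. RT alignment
regresses the reference sample's retention times on each sample's over
shared species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from lipidims.shorthand import Linkage, parse_shorthand

__all__ = [
    "CalibrationError",
    "CalibrationModel",
    "RtAlignment",
    "fit_ccs_calibration",
    "apply_calibration",
    "calibrate_cohort",
    "align_rt",
]

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when a calibration or alignment fit is impossible."""


@dataclass(frozen=True)
class CalibrationModel:
    """Affine raw-mobility -> CCS map for one sample."""

    sample_id: str
    slope: float
    intercept: float
    n_anchors: int
    residual_sd: float
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_anchors < 2:
            raise CalibrationError(
                f"{self.sample_id}: need >= 2 anchors, got {self.n_anchors}"
            )
        if not self.slope > 0:
            raise CalibrationError(
                f"{self.sample_id}: non-positive calibration slope {self.slope}"
            )

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RtAlignment:
    """Affine sample-RT -> reference-RT map for one sample."""

    sample_id: str
    slope: float
    intercept: float
    n_anchors: int

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CalibrationError(
                f"{self.sample_id}: non-positive alignment slope {self.slope}"
            )

    def as_dict(self) -> dict:
        return asdict(self)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Slope, intercept, residual SD and their SEs for y ~ x (plain OLS)."""
    if np.ptp(x) == 0:
        raise CalibrationError("zero variance in predictor: degenerate fit")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    n = len(x)
    dof = max(n - 2, 1)
    resid_sd = float(np.sqrt(resid @ resid / dof))
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope_se = resid_sd / np.sqrt(sxx)
    intercept_se = resid_sd * np.sqrt(1.0 / n + x.mean() ** 2 / sxx)
    return float(slope), float(intercept), resid_sd, float(slope_se), float(intercept_se)


def fit_ccs_calibration(
    features: pd.DataFrame, reference: pd.DataFrame
) -> CalibrationModel:
    """Fit the per-sample affine CCS calibration.

    Parameters
    ----------
    features : DataFrame
        Feature rows of a *single* sample (columns ``species``,
        ``sample_id``, ``raw_mobility``).
    reference : DataFrame
        1-acyl reference table with columns ``species`` and ``ccs_a2``.

    Only 1-acyl species found in both tables act as anchors. When a
    species was measured multiple times in the sample its raw mobility
    values are averaged first.
    """
    sample_ids = features["sample_id"].unique()
    if len(sample_ids) != 1:
        raise CalibrationError(
            f"expected a single sample, got {sorted(map(str, sample_ids))}"
        )
    sample_id = str(sample_ids[0])

    ref = reference.set_index("species")["ccs_a2"]
    acyl_mask = features["species"].map(
        lambda s: parse_shorthand(s).linkage is Linkage.ACYL
    )
    anchors = (
        features.loc[acyl_mask]
        .groupby("species")["raw_mobility"]
        .mean()
    )
    shared = anchors.index.intersection(ref.index)
    if len(shared) < 2:
        raise CalibrationError(
            f"{sample_id}: only {len(shared)} 1-acyl anchor(s) shared with the "
            "reference table; need >= 2"
        )
    x = anchors.loc[shared].to_numpy(dtype=float)
    y = ref.loc[shared].to_numpy(dtype=float)
    slope, intercept, resid_sd, slope_se, intercept_se = _ols_line(x, y)
    return CalibrationModel(
        sample_id, slope, intercept, len(shared), resid_sd, slope_se, intercept_se
    )


def apply_calibration(
    features: pd.DataFrame, model: CalibrationModel
) -> pd.DataFrame:
    """Fill the ``ccs`` column of one sample's rows from its model."""
    if set(map(str, features["sample_id"].unique())) != {model.sample_id}:
        raise CalibrationError(
            f"calibration model is for sample {model.sample_id!r}, "
            "but features belong to a different sample"
        )
    out = features.copy()
    out["ccs"] = model.slope * out["raw_mobility"].to_numpy(dtype=float) + model.intercept
    return out


def calibrate_cohort(
    features: pd.DataFrame, reference: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, CalibrationModel]]:
    """Fit and apply CCS calibration for every sample in the table."""
    parts = []
    models: dict[str, CalibrationModel] = {}
    for sample_id, group in features.groupby("sample_id", sort=True):
        model = fit_ccs_calibration(group, reference)
        models[str(sample_id)] = model
        parts.append(apply_calibration(group, model))
    calibrated = pd.concat(parts).sort_index()
    return calibrated, models


def align_rt(
    features: pd.DataFrame, reference_sample: str | None = None
) -> tuple[pd.DataFrame, dict[str, RtAlignment]]:
    """Linearly align retention times of all samples to one reference.

    Per sample, ordinary least squares of the reference sample's RT on
    the sample's RT over shared species; the aligned RT replaces the
    raw RT. If ``reference_sample`` is None, the sample with the most
    annotated species is used.
    """
    per_sample_rt = {
        str(sid): grp.groupby("species")["rt"].mean()
        for sid, grp in features.groupby("sample_id")
    }
    if reference_sample is None:
        reference_sample = max(per_sample_rt, key=lambda s: len(per_sample_rt[s]))
    if reference_sample not in per_sample_rt:
        raise CalibrationError(f"unknown reference sample {reference_sample!r}")
    ref_rt = per_sample_rt[reference_sample]

    alignments: dict[str, RtAlignment] = {}
    parts = []
    for sample_id, group in features.groupby("sample_id", sort=True):
        sid = str(sample_id)
        if sid == reference_sample:
            alignments[sid] = RtAlignment(sid, 1.0, 0.0, len(ref_rt))
            parts.append(group)
            continue
        rt = per_sample_rt[sid]
        shared = rt.index.intersection(ref_rt.index)
        if len(shared) < 2:
            raise CalibrationError(
                f"{sid}: only {len(shared)} species shared with reference "
                f"{reference_sample!r}; need >= 2"
            )
        slope, intercept, *_ = _ols_line(
            rt.loc[shared].to_numpy(dtype=float),
            ref_rt.loc[shared].to_numpy(dtype=float),
        )
        alignments[sid] = RtAlignment(sid, slope, intercept, len(shared))
        aligned = group.copy()
        aligned["rt"] = slope * aligned["rt"].to_numpy(dtype=float) + intercept
        parts.append(aligned)
    aligned_table = pd.concat(parts).sort_index()
    logger.info("RT alignment reference sample: %s", reference_sample)
    return aligned_table, alignments
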