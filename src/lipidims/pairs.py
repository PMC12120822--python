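"""Matched species pairs under structural transformations and their
averaged RT (relative %) and CCS (absolute A^2) differences.

Four transformations are supported: chain elongation by two carbons,
one extra double bond downstream in the radyl chains, the Delta-1
vinyl-ether double bond (alkyl -> alkenyl at fixed n:d), and the
isobaric alkenyl-vs-alkyl comparison (``P-n:d`` vs ``O-n:(d+1)``,
identical elemental formulas). Pairs are ordered (reference,
transformed); deltas are transformed minus reference.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from lipidims.shorthand import Linkage, LipidSpecies, parse_shorthand

__all__ = [
    "Transformation",
    "PairDelta",
    "enumerate_pairs",
    "compute_deltas",
    "summarize_deltas",
]

logger = logging.getLogger(__name__)


class Transformation(str, enum.Enum):
    """Structural transformation relating the two members of a pair."""

    PLUS_2CH2 = "plus2CH2"
    PLUS_DB_DOWNSTREAM = "plusDB_downstream"
    PLUS_DB_DELTA1 = "plusDB_delta1"
    ALKENYL_VS_ALKYL_ISOBAR = "alkenyl_vs_alkyl_isobar"


@dataclass(frozen=True)
class PairDelta:
    """Averaged differences for one matched species pair."""

    species_a: str
    species_b: str
    transformation: Transformation
    delta_rt_pct: float
    delta_ccs: float
    n_samples_used: int

    def as_dict(self) -> dict:
        d = asdict(self)
        d["transformation"] = self.transformation.value
        return d


def _as_species(species_set: Iterable) -> list[LipidSpecies]:
    out = []
    for s in species_set:
        sp = s if isinstance(s, LipidSpecies) else parse_shorthand(str(s))
        out.append(sp.at_species_level())
    # deterministic order, dedup
    uniq = {sp.name: sp for sp in out}
    return [uniq[k] for k in sorted(uniq)]


def enumerate_pairs(
    species_set: Iterable, transformation: Transformation
) -> list[tuple[LipidSpecies, LipidSpecies]]:
    """All ordered (reference, transformed) pairs under a transformation.

    Matching rules:

    - ``plus2CH2``: same class, linkage and DB; transformed has CC+2.
    - ``plusDB_downstream``: same class, linkage and CC; transformed
      has DB+1.
    - ``plusDB_delta1``: reference ``O-n:d``, transformed ``P-n:d``
      (adds only the Delta-1 bond; transformed is 2 H lighter).
    - ``alkenyl_vs_alkyl_isobar``: reference ``O-n:(d+1)``, transformed
      ``P-n:d`` (identical formulas).
    """
    species = _as_species(species_set)
    index = {(sp.linkage, sp.cc, sp.db): sp for sp in species}
    pairs = []
    for a in species:
        key = None
        if transformation is Transformation.PLUS_2CH2:
            key = (a.linkage, a.cc + 2, a.db)
        elif transformation is Transformation.PLUS_DB_DOWNSTREAM:
            key = (a.linkage, a.cc, a.db + 1)
        elif transformation is Transformation.PLUS_DB_DELTA1:
            if a.linkage is Linkage.ALKYL:
                key = (Linkage.ALKENYL, a.cc, a.db)
        elif transformation is Transformation.ALKENYL_VS_ALKYL_ISOBAR:
            if a.linkage is Linkage.ALKYL and a.db >= 1:
                key = (Linkage.ALKENYL, a.cc, a.db - 1)
        if key is not None and key in index:
            pairs.append((a, index[key]))
    return pairs


def _per_sample_means(features: pd.DataFrame) -> pd.DataFrame:
    """(species, sample) mean RT/CCS with tissue/genotype labels."""
    return (
        features.groupby(["species", "sample_id", "tissue", "genotype"], sort=True)[
            ["rt", "ccs"]
        ]
        .mean()
        .reset_index()
    )


def _pair_deltas_for(
    means: pd.DataFrame, a: LipidSpecies, b: LipidSpecies
) -> tuple[np.ndarray, np.ndarray, int] | None:
    """Per-observation (rt_pct, ccs) deltas for a pair, or None.

    Pairs within common samples when possible; otherwise bridges via
    per-tissue, per-genotype species means (needed for pairs whose
    members never co-occur in a sample, e.g. genotype-exclusive ether
    species).
    """
    ma = means[means["species"] == a.name]
    mb = means[means["species"] == b.name]
    if ma.empty or mb.empty:
        return None
    merged = ma.merge(mb, on="sample_id", suffixes=("_a", "_b"))
    if not merged.empty:
        rt_a = merged["rt_a"].to_numpy()
        rt_b = merged["rt_b"].to_numpy()
        ccs_a = merged["ccs_a"].to_numpy()
        ccs_b = merged["ccs_b"].to_numpy()
        n = len(merged)
    else:
        ta = ma.groupby("tissue")[["rt", "ccs"]].mean()
        tb = mb.groupby("tissue")[["rt", "ccs"]].mean()
        shared = ta.index.intersection(tb.index)
        if len(shared) == 0:
            return None
        rt_a = ta.loc[shared, "rt"].to_numpy()
        rt_b = tb.loc[shared, "rt"].to_numpy()
        ccs_a = ta.loc[shared, "ccs"].to_numpy()
        ccs_b = tb.loc[shared, "ccs"].to_numpy()
        n = int(len(ma) + len(mb))
    rt_pct = 100.0 * (rt_b - rt_a) / rt_a
    ccs = ccs_b - ccs_a
    return rt_pct, ccs, n


def compute_deltas(
    features: pd.DataFrame,
    pairs: Sequence[tuple[LipidSpecies, LipidSpecies]],
    transformation: Transformation,
) -> list[PairDelta]:
    """Per-pair averaged RT/CCS deltas from a calibrated, aligned table.

    Deltas are first computed within common samples (cancelling sample
    effects), then averaged per pair. Pairs with no usable observations
    are dropped with a logged warning.
    """
    means = _per_sample_means(features)
    out = []
    for a, b in pairs:
        res = _pair_deltas_for(means, a, b)
        if res is None:
            logger.warning(
                "PAIR-DROPPED %s: no common observations for (%s, %s)",
                transformation.value, a.name, b.name,
            )
            continue
        rt_pct, ccs, n = res
        out.append(
            PairDelta(
                species_a=a.name,
                species_b=b.name,
                transformation=transformation,
                delta_rt_pct=float(np.mean(rt_pct)),
                delta_ccs=float(np.mean(ccs)),
                n_samples_used=n,
            )
        )
    return out


def summarize_deltas(deltas: Sequence[PairDelta]) -> pd.DataFrame:
    """Mean +/- SD across pairs, per transformation and dimension.

    Returns a DataFrame with columns ``transformation``, ``dimension``
    (``rt_pct`` or ``ccs``), ``mean``, ``sd`` and ``n_pairs``. The SD
    is the sample SD across pairs (unweighted).
    """
    rows = []
    by_kind: dict[Transformation, list[PairDelta]] = {}
    for d in deltas:
        by_kind.setdefault(d.transformation, []).append(d)
    for kind in sorted(by_kind, key=lambda t: t.value):
        group = by_kind[kind]
        for dim, attr in (("rt_pct", "delta_rt_pct"), ("ccs", "delta_ccs")):
            vals = np.array([getattr(d, attr) for d in group], dtype=float)
            rows.append(
                {
                    "transformation": kind.value,
                    "dimension": dim,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "n_pairs": len(vals),
                }
            )
    return pd.DataFrame(rows, columns=["transformation", "dimension", "mean", "sd", "n_pairs"])
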