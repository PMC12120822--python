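"""Plain-text table and report I/O.

Feature tables travel as CSV or TSV (chosen by file extension) with a
single ``#``-prefixed metadata header line embedding the package
version and a config hash. Rows with unparseable species names or
non-finite numerics are rejected individually with logged counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from lipidims import __version__
from lipidims.shorthand import ShorthandError, parse_shorthand

__all__ = [
    "config_hash",
    "metadata_line",
    "read_feature_table",
    "write_feature_table",
    "read_reference_table",
    "read_predicted_table",
    "write_table",
    "write_json_report",
]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ["species", "sample_id", "rt", "mz", "raw_mobility", "intensity"]
NUMERIC_COLUMNS = ["rt", "mz", "raw_mobility", "intensity"]


def config_hash(config: Optional[dict] = None) -> str:
    """Stable sha256 of a configuration mapping (first 12 hex chars)."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def metadata_line(config: Optional[dict] = None) -> str:
    return f"# lipidims={__version__} config_sha256={config_hash(config)}"


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_table(
    table: pd.DataFrame, path: str | Path, config: Optional[dict] = None
) -> None:
    """Write any DataFrame as CSV/TSV with the metadata header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(metadata_line(config) + "\n")
        table.to_csv(fh, sep=_sep_for(path), index=False, float_format="%.6f")


def write_feature_table(
    features: pd.DataFrame, path: str | Path, config: Optional[dict] = None
) -> None:
    write_table(features, path, config)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table, validating schema and species names.

    Returns only rows whose species parse and whose numeric fields are
    finite; rejected rows are counted in a logged warning.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), comment="#")
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    if "ccs" not in table.columns:
        table["ccs"] = np.nan

    def _valid_species(name: object) -> bool:
        try:
            parse_shorthand(str(name))
            return True
        except ShorthandError:
            return False

    ok_species = table["species"].map(_valid_species)
    n_bad_species = int((~ok_species).sum())
    if n_bad_species:
        logger.warning(
            "ROWS-REJECTED %s: %d row(s) with unparseable species names",
            path.name, n_bad_species,
        )
    numeric = table[NUMERIC_COLUMNS].apply(pd.to_numeric, errors="coerce")
    ok_numeric = np.isfinite(numeric).all(axis=1)
    n_bad_numeric = int((ok_species & ~ok_numeric).sum())
    if n_bad_numeric:
        logger.warning(
            "ROWS-REJECTED %s: %d row(s) with non-finite numerics",
            path.name, n_bad_numeric,
        )
    out = table.loc[ok_species & ok_numeric].copy()
    out[NUMERIC_COLUMNS] = numeric.loc[out.index]
    return out.reset_index(drop=True)


def read_reference_table(path: str | Path) -> pd.DataFrame:
    """Read a reference CCS table (columns ``species``, ``ccs_a2``)."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), comment="#")
    for col in ("species", "ccs_a2"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    return table


def read_predicted_table(path: str | Path) -> pd.DataFrame:
    """Read a predicted CCS table (columns ``species``, ``predicted_ccs``)."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), comment="#")
    for col in ("species", "predicted_ccs"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    return table


def write_json_report(
    payload: dict[str, Any], path: str | Path, config: Optional[dict] = None
) -> None:
    """Write a JSON report with embedded package/config metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "meta": {"package": "lipidims", "version": __version__,
                 "config_sha256": config_hash(config)},
        **payload,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
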