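"""Pipeline configuration: YAML loading and block -> dataclass mapping."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Optional

import yaml

from lipidims.cohort import CohortDesign, GenerativeModel

__all__ = ["PipelineConfig", "load_config", "design_from_dict", "model_from_dict"]


def _from_dict(cls, block: Optional[dict], what: str):
    block = dict(block or {})
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ValueError(f"unknown {what} option(s): {sorted(unknown)}")
    for name in ("tissues", "genotypes", "cc_grid", "db_grid"):
        if name in block and isinstance(block[name], list):
            block[name] = tuple(block[name])
    for name in ("ccs_scale_range", "ccs_offset_range", "rt_scale_range",
                 "rt_offset_range"):
        if name in block and isinstance(block[name], list):
            block[name] = tuple(block[name])
    return cls(**block)


def design_from_dict(block: Optional[dict] = None, seed: Optional[int] = None) -> CohortDesign:
    design = _from_dict(CohortDesign, block, "cohort design")
    if seed is not None:
        design = dataclasses.replace(design, seed=int(seed))
    return design


def model_from_dict(block: Optional[dict] = None) -> GenerativeModel:
    return _from_dict(GenerativeModel, block, "generative model")


@dataclasses.dataclass
class PipelineConfig:
    """Fully resolved configuration for the end-to-end report."""

    seed: int = 0
    outdir: Path = Path("lipidims_out")
    design: CohortDesign = dataclasses.field(default_factory=CohortDesign)
    model: GenerativeModel = dataclasses.field(default_factory=GenerativeModel)
    features_path: Optional[Path] = None
    reference_path: Optional[Path] = None
    predicted_path: Optional[Path] = None
    transformations: tuple[str, ...] = (
        "plus2CH2", "plusDB_downstream", "plusDB_delta1", "alkenyl_vs_alkyl_isobar",
    )
    log_level: str = "INFO"
    raw: dict = dataclasses.field(default_factory=dict)

    def as_dict(self) -> dict[str, Any]:
        # outdir deliberately excluded: it is plumbing, not analysis config
        return {
            "seed": self.seed,
            "design": dataclasses.asdict(self.design),
            "model": dataclasses.asdict(self.model),
            "transformations": list(self.transformations),
        }


def load_config(path: str | Path | None = None, seed: Optional[int] = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (all keys optional).

    CLI-provided ``seed`` overrides the file's seed and flows into the
    cohort design.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg_seed = int(raw.get("seed", 0)) if seed is None else int(seed)
    design = design_from_dict(raw.get("design"), seed=cfg_seed)
    model = model_from_dict(raw.get("model"))
    paths = raw.get("paths", {}) or {}
    return PipelineConfig(
        seed=cfg_seed,
        outdir=Path(raw.get("outdir", "lipidims_out")),
        design=design,
        model=model,
        features_path=Path(paths["features"]) if "features" in paths else None,
        reference_path=Path(paths["reference"]) if "reference" in paths else None,
        predicted_path=Path(paths["predicted"]) if "predicted" in paths else None,
        transformations=tuple(raw.get("transformations", PipelineConfig.transformations)),
        log_level=str(raw.get("log_level", "INFO")),
        raw=raw,
    )
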