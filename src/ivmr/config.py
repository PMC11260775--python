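"""Run configuration: one declarative object drives the whole pipeline.

Every threshold the workflow applies is an explicit, validated field with
the conventional default (genome-wide significance 5e-8, clumping r² 0.001
in a ±10,000 kb window, proxy r² >= 0.8, palindromic-MAF ambiguity
threshold 0.3), so a run log can state every value actually used.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .simulate import DEFAULT_CATEGORIES

#: default display codes for the exclusion analyses (AX<category>)
DEFAULT_RUN_LABELS = {
    "proxy": "AXP",
    "blood": "AXB",
    "body_composition": "AXBC",
    "inflammation": "AXI",
    "lipid": "AXL",
    "type_2_diabetes": "AXT2D",
}


class Paths(BaseModel):
    exposure: Path
    outcome: Path
    panel_dosages: Optional[Path] = None
    panel_meta: Optional[Path] = None
    annotations: Optional[Path] = None
    out_dir: Path = Path("ivmr_out")


class Thresholds(BaseModel):
    p_select: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    proxy_min_r2: float = 0.8
    palindromic_maf: float = 0.3

    @field_validator("p_select", "clump_r2", "proxy_min_r2", "palindromic_maf")
    @classmethod
    def _unit_interval(cls, v):
        if not 0 < v <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        return v


class EstimatorSettings(BaseModel):
    ivw_model: str = "multiplicative_random"
    n_boot: int = Field(1000, ge=2)
    bandwidth_factor: float = Field(1.0, gt=0)


class SensitivitySettings(BaseModel):
    presso_n_sim: int = Field(1000, ge=100)
    presso_significance: float = 0.05
    categories: list[str] = ["lipid", "blood", "inflammation",
                             "body_composition", "type_2_diabetes"]
    keep_only_categories: list[str] = ["blood", "inflammation"]
    category_vocabulary: list[str] = list(DEFAULT_CATEGORIES)
    exclude_proxies_run: bool = True


class PowerSettings(BaseModel):
    n_case: int = 9_358
    n_control: int = 15_482
    alpha: float = 0.05
    target_power: float = 0.8
    or_grid: list[float] = [0.5, 0.67, 0.8, 0.92, 1.0, 1.1, 1.25, 1.5, 2.0]


class RunConfig(BaseModel):
    paths: Paths
    thresholds: Thresholds = Thresholds()
    estimators: EstimatorSettings = EstimatorSettings()
    sensitivity: SensitivitySettings = SensitivitySettings()
    power: PowerSettings = PowerSettings()
    strength_formula: str = "standard"
    run_labels: dict[str, str] = dict(DEFAULT_RUN_LABELS)
    exposure_dialect: Optional[dict[str, str]] = None
    outcome_dialect: Optional[dict[str, str]] = None
    n_exposure: int = 114_999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_log_dict(self) -> dict:
        """Every configuration value actually used, for the run log."""
        return self.model_dump(mode="json")
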