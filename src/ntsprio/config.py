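"""Workflow configuration: every tunable threshold with its published
default, serializable to/from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Union

import yaml

from .features import CascadeConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """End-to-end workflow thresholds.

    Defaults are the workflow's standard operating point: intensity
    thresholds 100,000 (positive) / 50,000 (negative), replicate RSD 50%,
    blank factor 3, precursor isolation window 0.4 Da and RT window 5 s
    (full widths), 5% relative MS2 intensity floor, +/-2 mDa suspect mass
    tolerance, +/-120 s RT plausibility window, cosine > 0.5, > 2 matched
    MS2 peaks, Tanimoto > 0.8, and >= 5 calibration levels.
    """

    intensity_threshold_positive: float = 100_000.0
    intensity_threshold_negative: float = 50_000.0
    max_rsd_pct: float = 50.0
    blank_factor: float = 3.0
    componentize_rt_tol_s: float = 5.0
    componentize_mz_tol_mda: float = 2.0
    precursor_window_da: float = 0.4
    rt_window_s: float = 5.0
    min_rel_intensity_pct: float = 5.0
    frag_tol_mda: float = 5.0
    suspect_tol_mda: float = 2.0
    rt_filter_window_s: float = 120.0
    min_cosine: float = 0.5
    min_matched_peaks: int = 3
    min_tanimoto: float = 0.8
    min_calibration_levels: int = 5
    toxicity_predictor: str = "lookup"
    seed: int = 0

    def cascade_config(self) -> CascadeConfig:
        return CascadeConfig(
            intensity_thresholds={
                "positive": self.intensity_threshold_positive,
                "negative": self.intensity_threshold_negative,
            },
            max_rsd_pct=self.max_rsd_pct,
            blank_factor=self.blank_factor,
            componentize_rt_tol=self.componentize_rt_tol_s,
            componentize_mz_tol_mda=self.componentize_mz_tol_mda,
            precursor_window=self.precursor_window_da,
            rt_window=self.rt_window_s,
            min_rel_intensity=self.min_rel_intensity_pct,
            frag_tol_mda=self.frag_tol_mda,
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data: Dict = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)
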