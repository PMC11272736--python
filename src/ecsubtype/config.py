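"""Pipeline configuration: every published threshold in one place, JSON round-trip."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .qc import QcThresholds
from .variants import PoleRuleParams, VariantFilterParams


@dataclass
class PipelineConfig:
    cohort_dir: str = "."
    model_path: str = "cn_model.json"
    out_dir: str = "out"
    variant_filter: VariantFilterParams = field(default_factory=VariantFilterParams)
    pole_rule: PoleRuleParams = field(default_factory=PoleRuleParams)
    msi_threshold: float = 0.3
    gain_cutoff: float = 2.5
    loss_cutoff: float = 1.5
    qc_thresholds: QcThresholds = field(default_factory=QcThresholds)
    tcga_reference: str = "CN_low"
    surrogate_reference: str = "NSMP"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "variant_filter" in d:
            d["variant_filter"] = VariantFilterParams(**d["variant_filter"])
        if "pole_rule" in d:
            d["pole_rule"] = PoleRuleParams(**d["pole_rule"])
        if "qc_thresholds" in d:
            d["qc_thresholds"] = QcThresholds(**d["qc_thresholds"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
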