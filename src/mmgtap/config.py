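"""Pipeline configuration: one object aggregating every stage's parameters.

The YAML schema is versioned and every evaluation report embeds the resolved
configuration, so a report is reproducible from (config, input files, seed)
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .classify import ClassifierSpec
from .detect import DetectorSpec
from .preprocess import FilterSpec

__all__ = ["PipelineConfig", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunables of the recognition pipeline, with the standard defaults.

    ``segment_length`` must be a positive multiple of ``2**level`` so the
    wavelet packet tree divides it evenly; ``k_per_channel`` selects how many
    top-ranked singular-value features per channel reach the classifier.
    """

    filter: FilterSpec = field(default_factory=FilterSpec)
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    segment_length: int = 1024
    wavelet: str = "db4"
    level: int = 5
    k_per_channel: int = 4
    ranking_convention: str = "fisher"
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    folds: int = 5
    seed: int = 0
    fder_tol: int = 500
    baseline_interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.segment_length <= 0 or self.segment_length % (2**self.level):
            raise ValueError(
                f"segment_length {self.segment_length} must be a positive "
                f"multiple of 2**{self.level}"
            )
        n_leaves = 2**self.level
        if not (1 <= self.k_per_channel <= n_leaves):
            raise ValueError(
                f"k_per_channel must be in 1..{n_leaves}, got {self.k_per_channel}"
            )
        if self.ranking_convention not in ("fisher", "as_printed"):
            raise ValueError(
                f"unknown ranking convention {self.ranking_convention!r}"
            )
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def to_dict(self) -> dict:
        d = self.detector
        c = self.classifier
        f = self.filter
        return {
            "schema_version": SCHEMA_VERSION,
            "filter": {
                "order": f.order,
                "low_cutoff": f.low_cutoff,
                "high_cutoff": f.high_cutoff,
                "zero_phase": f.zero_phase,
            },
            "detector": {
                "algorithm": d.algorithm,
                "window": d.window,
                "alpha": d.alpha,
                "rectify": d.rectify,
                "min_event_duration": d.min_event_duration,
                "merge_gap": d.merge_gap,
                "channel_combination": d.channel_combination,
                "recenter": d.recenter,
            },
            "segment_length": self.segment_length,
            "wavelet": self.wavelet,
            "level": self.level,
            "k_per_channel": self.k_per_channel,
            "ranking_convention": self.ranking_convention,
            "classifier": {
                "kind": c.kind,
                "knn_k": c.knn_k,
                "svm_c": c.svm_c,
                "svm_gamma": c.svm_gamma,
                "svm_coef0": c.svm_coef0,
                "svm_degree": c.svm_degree,
                "standardize": c.standardize,
            },
            "folds": self.folds,
            "seed": self.seed,
            "fder_tol": self.fder_tol,
            "baseline_interval": list(self.baseline_interval)
            if self.baseline_interval
            else None,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema version {version} "
                f"(this build reads version {SCHEMA_VERSION})"
            )
        kwargs: dict = {}
        if "filter" in data:
            kwargs["filter"] = FilterSpec(**data.pop("filter"))
        if "detector" in data:
            kwargs["detector"] = DetectorSpec(**data.pop("detector"))
        if "classifier" in data:
            kwargs["classifier"] = ClassifierSpec(**data.pop("classifier"))
        if data.get("baseline_interval") is not None:
            data["baseline_interval"] = tuple(data["baseline_interval"])
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
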