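"""Single-file pipeline configuration (YAML) with exact round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .synthetic import SimulationConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis in one serializable record."""

    # inputs: either paths to tidy CSVs, or a simulation
    intensity_csv: str | None = None
    annotation_csv: str | None = None
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    # normalization
    k_mad: float = 3.0
    lowess_span: float = 0.3
    lowess_iterations: int = 3
    detrend_covariates: tuple[str, ...] = ("injection_index", "od600")

    # profiles
    reference_mutant: str = "WT"
    welch: bool = False
    mean_of_ratios: bool = False
    fc_cut: float = 0.5
    p_cut: float = 0.05

    # similarity
    include_self_in_distance: bool = True

    # guilt
    positive_class: str = "positive_regulator"
    summary: str = "median"
    target_fpr: float = 0.2
    n_randomizations: int = 10_000
    permutation_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["timepoints_min"] = list(self.simulation.timepoints_min)
        d["detrend_covariates"] = list(self.detrend_covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            if "timepoints_min" in sim:
                sim["timepoints_min"] = tuple(sim["timepoints_min"])
            sim = SimulationConfig(**sim)
        if "detrend_covariates" in d:
            d["detrend_covariates"] = tuple(d["detrend_covariates"])
        return cls(simulation=sim, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
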