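"""Synthetic dataset generator for dynamic metabolome screens.

Emits tidy intensity tables with the statistical structure the downstream
analysis assumes: a wild-type treatment response shared by all strains, a
planted cluster of co-responding "positive regulator" mutants, an
anti-responding "negative regulator" set, neutral mutants with small
idiosyncratic effects, multiplicative acquisition-order drift, an OD600
confounder, and lognormal replicate noise.  A ground-truth record
accompanies every table so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_growth_curves",
]

#: canonical column order of the tidy intensity table
INTENSITY_COLUMNS = [
    "sample_id",
    "mutant",
    "timepoint_min",
    "replicate",
    "injection_index",
    "od600",
    "treatment",
    "metabolite_id",
    "intensity",
]

CLASS_POSITIVE = "positive_regulator"
CLASS_NEGATIVE = "negative_regulator"
CLASS_RECEPTOR = "receptor_related"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-structure simulator.

    Effect sizes are in log2 units unless noted; ``replicate_noise_sd`` is
    on the natural-log scale.  Drift and OD effects act multiplicatively on
    raw intensities.
    """

    n_metabolites: int = 100
    n_positive: int = 6
    n_negative: int = 6
    n_neutral: int = 48
    timepoints_min: tuple[float, ...] = (0.0, 5.0, 30.0, 60.0, 90.0)
    n_replicates: int = 4
    wt_response_amplitude: float = 0.8
    rising_fraction: float = 0.5
    response_tau_min: float = 10.0
    shared_signature_sd: float = 0.5
    signature_basal_fraction: float = 0.1
    amplification_factor: float = 1.6
    neutral_effect_sd: float = 0.1
    replicate_noise_sd: float = 0.25
    sample_scale_sd: float = 0.25
    drift_amplitude: float = 0.15
    od_effect_slope: float = 0.5
    od_mean: float = 0.7
    od_noise_sd: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_metabolites": self.n_metabolites,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_neutral": self.n_neutral,
            "n_replicates": self.n_replicates,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        sds = {
            "wt_response_amplitude": self.wt_response_amplitude,
            "shared_signature_sd": self.shared_signature_sd,
            "neutral_effect_sd": self.neutral_effect_sd,
            "replicate_noise_sd": self.replicate_noise_sd,
            "sample_scale_sd": self.sample_scale_sd,
            "od_noise_sd": self.od_noise_sd,
        }
        for name, value in sds.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if 0.0 not in [float(t) for t in self.timepoints_min]:
            raise ValueError("timepoints_min must include the untreated 0 min point")
        if self.n_replicates == 0 and self.replicate_noise_sd > 0:
            raise ValueError(
                "n_replicates == 0 with nonzero replicate_noise_sd: profiles undefined"
            )
        if not 0.0 <= self.rising_fraction <= 1.0:
            raise ValueError("rising_fraction must be in [0, 1]")
        if self.response_tau_min <= 0:
            raise ValueError("response_tau_min must be > 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth paired with a generated intensity table."""

    classes: dict[str, str]
    metabolites: list[str]
    wt_amplitude: dict[str, float]
    response_tau_min: float
    signature: dict[str, float]
    signature_basal_fraction: float
    response_scale: dict[str, float]
    neutral_effects: dict[str, dict[str, float]]
    drift: dict[int, float]
    baseline: dict[str, float]
    seed: int
    config: dict = field(default_factory=dict)

    def response_activation(self, timepoint_min: float) -> float:
        """Saturating activation of the treatment response, in [0, 1)."""
        return 1.0 - float(np.exp(-timepoint_min / self.response_tau_min))

    def expected_log2_fc(self, mutant: str, timepoint_min: float) -> pd.Series:
        """Noise-free log2 fold-change of ``mutant`` vs WT at a timepoint."""
        g = self.response_activation(timepoint_min)
        sig_act = self.signature_basal_fraction + (1 - self.signature_basal_fraction) * g
        amp = np.array([self.wt_amplitude[m] for m in self.metabolites])
        sig = np.array([self.signature[m] for m in self.metabolites])
        scale = self.response_scale[mutant]
        fc = (scale - 1.0) * amp * g
        cls = self.classes.get(mutant)
        if cls == CLASS_POSITIVE:
            fc = fc + sig * sig_act
        elif cls == CLASS_NEGATIVE:
            fc = fc - sig * sig_act
        elif mutant in self.neutral_effects:
            fc = fc + np.array(
                [self.neutral_effects[mutant][m] for m in self.metabolites]
            )
        return pd.Series(fc, index=self.metabolites)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=float)


def _mutant_names(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    names, classes = [], {}
    for i in range(config.n_positive):
        name = f"pos{i + 1:02d}"
        names.append(name)
        classes[name] = CLASS_POSITIVE
    for i in range(config.n_negative):
        name = f"neg{i + 1:02d}"
        names.append(name)
        classes[name] = CLASS_NEGATIVE
    for i in range(config.n_neutral):
        name = f"neu{i + 1:02d}"
        names.append(name)
        classes[name] = CLASS_RECEPTOR
    return names, classes


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate an intensity table, an annotation table, and the truth.

    Raw intensity for sample *s* and metabolite *j* is

        baseline_j * 2**fc(mutant, j, t) * drift(injection) * od_scale * exp(eps)

    with ``eps ~ Normal(0, replicate_noise_sd)``.  Positive-regulator
    mutants share one signature vector (scaled up as treatment takes hold)
    plus an amplified wild-type response; negative regulators carry the
    negated signature; neutral mutants carry independent small static
    effects.  Identical config + seed reproduces the output bit-for-bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    metabolites = [f"m{j + 1:03d}" for j in range(config.n_metabolites)]
    mutants, classes = _mutant_names(config)
    strains = ["WT"] + mutants

    n_met = config.n_metabolites
    n_rising = int(round(config.rising_fraction * n_met))
    signs = np.concatenate([np.ones(n_rising), -np.ones(n_met - n_rising)])
    rng.shuffle(signs)
    wt_amp = signs * config.wt_response_amplitude * rng.uniform(0.5, 1.5, n_met)
    signature = rng.normal(0.0, config.shared_signature_sd, n_met)
    baseline = 10.0 ** rng.uniform(4.0, 6.0, n_met)

    response_scale = {s: 1.0 for s in strains}
    for m, cls in classes.items():
        if cls == CLASS_POSITIVE:
            response_scale[m] = config.amplification_factor
    neutral_effects = {
        m: rng.normal(0.0, config.neutral_effect_sd, n_met)
        for m, cls in classes.items()
        if cls == CLASS_RECEPTOR
    }

    timepoints = [float(t) for t in config.timepoints_min]
    meta = pd.DataFrame(
        [
            (s, t, r)
            for s in strains
            for t in timepoints
            for r in range(1, config.n_replicates + 1)
        ],
        columns=["mutant", "timepoint_min", "replicate"],
    )
    n_samples = len(meta)
    meta["treatment"] = np.where(meta["timepoint_min"] > 0, "rapamycin", "control")
    meta["injection_index"] = rng.permutation(n_samples) + 1
    meta["od600"] = config.od_mean * np.exp(
        rng.normal(0.0, config.od_noise_sd, n_samples)
    )
    meta["sample_id"] = [
        f"{m}_t{t:g}_r{r}"
        for m, t, r in zip(meta["mutant"], meta["timepoint_min"], meta["replicate"])
    ]

    # smooth low-frequency drift: linear term plus one slow sinusoid
    if n_samples > 1:
        x = (meta["injection_index"].to_numpy() - 1) / (n_samples - 1)
    else:
        x = np.zeros(n_samples)
    drift_log = config.drift_amplitude * (2.0 * (x - 0.5) + 0.5 * np.sin(2 * np.pi * x))
    drift = np.exp(drift_log)
    od_scale = np.exp(
        config.od_effect_slope * (meta["od600"].to_numpy() - config.od_mean)
    )

    g = 1.0 - np.exp(-np.array(timepoints) / config.response_tau_min)
    g_by_tp = dict(zip(timepoints, g))
    sig_act = {
        t: config.signature_basal_fraction
        + (1 - config.signature_basal_fraction) * g_by_tp[t]
        for t in timepoints
    }

    # per-strain, per-timepoint log2 effect matrices, noise-free
    fc_lookup: dict[tuple[str, float], np.ndarray] = {}
    for s in strains:
        cls = classes.get(s)
        for t in timepoints:
            fc = response_scale[s] * wt_amp * g_by_tp[t]
            if cls == CLASS_POSITIVE:
                fc = fc + signature * sig_act[t]
            elif cls == CLASS_NEGATIVE:
                fc = fc - signature * sig_act[t]
            elif cls == CLASS_RECEPTOR:
                fc = fc + neutral_effects[s]
            fc_lookup[(s, t)] = fc

    fc_matrix = np.stack(
        [fc_lookup[(m, t)] for m, t in zip(meta["mutant"], meta["timepoint_min"])]
    )  # n_samples x n_met
    # per-sample technical scale (extraction/injection efficiency); shifts a
    # sample's whole log-intensity vector, so fold-change profiles pick it up
    # only as a constant offset that Pearson correlation removes
    sample_scale = np.exp(rng.normal(0.0, config.sample_scale_sd, n_samples))
    noise = rng.normal(0.0, config.replicate_noise_sd, (n_samples, n_met))
    intensity = (
        baseline[None, :]
        * 2.0 ** fc_matrix
        * drift[:, None]
        * od_scale[:, None]
        * sample_scale[:, None]
        * np.exp(noise)
    )

    table = meta.loc[meta.index.repeat(n_met)].reset_index(drop=True)
    table["metabolite_id"] = np.tile(metabolites, n_samples)
    table["intensity"] = intensity.ravel()
    table = table[INTENSITY_COLUMNS]

    annotation = pd.DataFrame(
        {"mutant": mutants, "class": [classes[m] for m in mutants]}
    )

    truth = SyntheticTruth(
        classes=classes,
        metabolites=metabolites,
        wt_amplitude=dict(zip(metabolites, wt_amp.tolist())),
        response_tau_min=config.response_tau_min,
        signature=dict(zip(metabolites, signature.tolist())),
        signature_basal_fraction=config.signature_basal_fraction,
        response_scale=response_scale,
        neutral_effects={
            m: dict(zip(metabolites, eff.tolist()))
            for m, eff in neutral_effects.items()
        },
        drift=dict(
            zip(meta["injection_index"].astype(int).tolist(), drift.tolist())
        ),
        baseline=dict(zip(metabolites, baseline.tolist())),
        seed=config.seed,
        config=asdict(config),
    )
    return table, annotation, truth


def generate_growth_curves(
    n_strains: int,
    sampling_interval_min: float = 5.0,
    rate_per_h: float | list[float] = 0.3,
    lag_h: float | list[float] = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_h: float = 12.0,
    od0: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate lag-then-exponential OD600 curves with multiplicative noise.

    Returns ``(curves, truth)``: a tidy frame of (strain, time_h, od600) and
    a per-strain truth frame with the planted rate and lag.
    """
    if sampling_interval_min <= 0:
        raise ValueError("sampling_interval_min must be > 0")
    rates = np.broadcast_to(np.asarray(rate_per_h, dtype=float), (n_strains,))
    lags = np.broadcast_to(np.asarray(lag_h, dtype=float), (n_strains,))
    for r, l in zip(rates, lags):
        if r < 0 and np.isfinite(l) and l > 0:
            raise ValueError("negative growth rate with a finite lag requested")

    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 1e-9, sampling_interval_min / 60.0)
    frames = []
    for i in range(n_strains):
        if rates[i] == 0:
            od = np.full(t.size, od0)
        else:
            od = np.where(t < lags[i], od0, od0 * np.exp(rates[i] * (t - lags[i])))
        if noise_sd > 0:
            od = od * np.exp(rng.normal(0.0, noise_sd, t.size))
        frames.append(
            pd.DataFrame(
                {"strain": f"strain{i + 1:02d}", "time_h": t, "od600": od}
            )
        )
    curves = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        {
            "strain": [f"strain{i + 1:02d}" for i in range(n_strains)],
            "rate_per_h": rates,
            "lag_h": lags,
        }
    )
    return curves, truth
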