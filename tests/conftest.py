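import numpy as np
import pandas as pd
import pytest

from metaboguilt import SimulationConfig, generate_dataset


def make_intensity_table(
    n_mutants=3,
    n_metabolites=4,
    n_replicates=4,
    timepoints=(0.0, 30.0),
    seed=0,
    noise_sd=0.1,
):
    """Minimal hand-rolled tidy intensity table (no planted structure)."""
    rng = np.random.default_rng(seed)
    mutants = ["WT"] + [f"mut{i}" for i in range(1, n_mutants)]
    rows = []
    idx = 1
    for m in mutants:
        for t in timepoints:
            for r in range(1, n_replicates + 1):
                od = 0.7 * float(np.exp(rng.normal(0, 0.05)))
                for j in range(n_metabolites):
                    rows.append(
                        {
                            "sample_id": f"{m}_t{t:g}_r{r}",
                            "mutant": m,
                            "timepoint_min": t,
                            "replicate": r,
                            "injection_index": idx,
                            "od600": od,
                            "treatment": "control" if t == 0 else "rapamycin",
                            "metabolite_id": f"m{j}",
                            "intensity": 1e5
                            * float(np.exp(rng.normal(0, noise_sd))),
                        }
                    )
                idx += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_metabolites=30,
        n_positive=4,
        n_negative=4,
        n_neutral=10,
        n_replicates=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(SimulationConfig(seed=42))
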