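import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tracerscreen.feature_table import FeatureTable
from tracerscreen.simulate import SimulationConfig, generate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A reduced study layout for fast unit tests."""
    defaults = dict(
        seed=seed,
        n_features_pos=150,
        n_features_neg=100,
        n_planted_pairs_pos=4,
        n_planted_pairs_neg=2,
        n_cobehave_up=4,
        n_cobehave_down=3,
        n_adduct_triplets=1,
        n_decoy_ppm=8,
        n_decoy_rt=6,
        n_decoy_control=6,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    return generate(small_config())


@pytest.fixture(scope="session")
def default_sim():
    """The full study-scale simulation (shared across tests; treat as
    read-only)."""
    return generate(SimulationConfig(seed=20260101))


def make_table(intensities, mz=None, rt=None, ion_mode=None,
               times=(3.0, 9.0, 24.0), replicates=1) -> FeatureTable:
    """Hand-built table: ``intensities`` is a feature x sample array
    whose columns follow control, unlabeled, labeled blocks each with
    len(times) x replicates samples ordered by (time, replicate)."""
    mat = np.asarray(intensities, dtype=float)
    n_feat = mat.shape[0]
    design_rows = []
    for trt, code in (("control", "C"), ("unlabeled_tracer", "U"), ("labeled_tracer", "L")):
        for t in times:
            for r in range(1, replicates + 1):
                design_rows.append({
                    "sample_id": f"{code}{t:g}r{r}", "treatment": trt,
                    "time_h": t, "replicate": r, "batch": "b1",
                })
    design = pd.DataFrame(design_rows)
    assert mat.shape[1] == len(design)
    features = pd.DataFrame({
        "id": [f"F{i}" for i in range(n_feat)],
        "mz": mz if mz is not None else np.linspace(200, 300, n_feat),
        "rt": rt if rt is not None else np.full(n_feat, 5.0),
        "ion_mode": ion_mode if ion_mode is not None else ["positive"] * n_feat,
    })
    intens = pd.DataFrame(mat, index=features["id"], columns=design["sample_id"])
    intens.index.name = None
    return FeatureTable(features, design, intens)
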