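import numpy as np
import pandas as pd
import pytest

from brainmix.synthdata import GeneratorConfig, MultiVersionDataset, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A 48-feature configuration small enough for fast model fits."""
    return GeneratorConfig(n_participants=300, n_regions=8, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale cohort (n=1000, p=204), shared across tests."""
    return generate_cohort(GeneratorConfig(n_participants=1000, seed=0))


def toy_dataset(values_by_version: dict, ages=None) -> MultiVersionDataset:
    """Hand-built dataset: values_by_version maps tag -> (n x p) array."""
    first = next(iter(values_by_version.values()))
    n, p = np.asarray(first).shape
    assert p <= 3
    names = [("lh", "bankssts", "thickness"), ("rh", "bankssts", "area"),
             ("lh", "cuneus", "volume")][:p]
    ids = np.arange(1, n + 1)
    if ages is None:
        ages = np.linspace(50, 80, n)
    demo = pd.DataFrame({
        "participant_id": ids,
        "age": ages,
        "sex": np.where(ids % 2 == 0, "F", "M"),
        "site": (ids % 3) + 1,
    })
    features = {
        tag: pd.DataFrame(
            np.asarray(vals, dtype=float),
            index=pd.Index(ids, name="participant_id"),
            columns=["_".join(t) for t in names],
        )
        for tag, vals in values_by_version.items()
    }
    return MultiVersionDataset(
        demographics=demo, features_by_version=features, feature_names=names
    )
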