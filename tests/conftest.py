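import numpy as np
import pandas as pd
import pytest

from penclock import CohortConfig, generate_cohort, generate_drawing


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_participants=150, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def sample_drawing(small_config):
    return generate_drawing("P00003", -0.8, "command", small_config)


def make_scan_inputs(n: int, loadings: dict[str, float], rng: np.random.Generator,
                     n_noise_features: int = 0, test_name: str = "score"):
    """Feature-level simulation for scan tests: latent u drives the listed
    features (raw = loading*u + noise) and the test score (= u + noise)."""
    from penclock import normalize_features

    u = rng.normal(size=n)
    raw = {}
    for name, load in loadings.items():
        raw[name] = load * u + np.sqrt(max(0.0, 1 - load ** 2)) * rng.normal(size=n)
    for j in range(n_noise_features):
        raw[f"noise{j:02d}"] = rng.normal(size=n)
    raw = pd.DataFrame(raw, index=[f"P{i:04d}" for i in range(n)])
    V = normalize_features(raw)
    scores = pd.DataFrame({test_name: u + 0.5 * rng.normal(size=n)}, index=raw.index)
    covars = pd.DataFrame({
        "age": rng.normal(62, 13, size=n),
        "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        "education": rng.choice(
            ["no_high_school", "high_school", "some_college", "college_plus"], size=n),
    }, index=raw.index)
    return V, scores, covars, u
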