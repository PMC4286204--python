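import numpy as np
import pandas as pd
import pytest

from commtrees.community import CommunityMatrix, MorphogroupMap, PredictorTable, VariableSpec


@pytest.fixture
def small_cm() -> CommunityMatrix:
    """3 quadrats x 2 taxa abundance matrix over 2 sites."""
    values = pd.DataFrame(
        {"mossA": [0.1, 0.3, 0.0], "lichenB": [0.2, 0.0, 0.0]},
        index=pd.Index(["q1", "q2", "q3"], name="quadrat_id"),
    )
    sites = pd.Series(["s1", "s1", "s2"], index=values.index)
    return CommunityMatrix(values, sites)


def random_cm(rng, n=12, t=6, n_sites=4, zero_frac=0.35) -> CommunityMatrix:
    values = rng.gamma(1.0, 0.2, size=(n, t))
    values[rng.random((n, t)) < zero_frac] = 0.0
    df = pd.DataFrame(values, index=[f"q{i}" for i in range(n)],
                      columns=[f"t{j}" for j in range(t)])
    sites = pd.Series([f"s{i % n_sites}" for i in range(n)], index=df.index)
    return CommunityMatrix(df, sites)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def two_group_map() -> MorphogroupMap:
    return MorphogroupMap({
        "t0": "tall_moss", "t1": "tall_moss", "t2": "tall_moss",
        "t3": "crust", "t4": "crust", "t5": "crust",
    })


def zero_noise_fixture():
    """Piecewise-constant responses with two true splits and zero noise.

    60 quadrats over 12 sites; pH < 7 vs >= 7 and grazing {low,medium} vs
    {high} define 4 regions, each with a distinct 3-column centroid.
    """
    rng = np.random.default_rng(7)
    n = 60
    sites = [f"s{i // 5}" for i in range(n)]
    ph = np.where(np.arange(n) % 2 == 0, 6.5, 7.5) + rng.uniform(-0.2, 0.2, n)
    grazing = np.array(["low", "medium", "high"])[np.arange(n) % 3]
    region = (ph < 7).astype(int) * 2 + (grazing == "high").astype(int)
    centroids = np.array([[1.0, 0.0, 0.0],
                          [0.0, 1.0, 0.0],
                          [0.0, 0.0, 1.0],
                          [1.0, 1.0, 1.0]])
    Y = centroids[region]
    X = pd.DataFrame({
        "ph": ph,
        "grazing": pd.Categorical(grazing, categories=["low", "medium", "high"],
                                  ordered=True),
    }, index=[f"q{i}" for i in range(n)])
    return Y, X, sites, region
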