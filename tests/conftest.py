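import numpy as np
import pandas as pd
import pytest

from transdrug.io import DrugResponseTable, OmicsBundle
from transdrug.synth import PlantedModel, SyntheticConfig, generate_bundle, generate_drug_response


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A fast panel: 60 lines x 40 transporter genes, 3 tissues."""
    return SyntheticConfig(
        n_cell_lines=60,
        n_transporter_genes=40,
        tissues=["blood", "skin", "lung"],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg) -> OmicsBundle:
    return generate_bundle(small_cfg)


@pytest.fixture(scope="session")
def small_response(small_bundle) -> DrugResponseTable:
    genes = list(small_bundle.expression.columns)
    planted = [
        PlantedModel("drugA", {genes[0]: -2.0}, noise_sd=0.5),
        PlantedModel("drugB", {genes[1]: -2.0, genes[2]: 2.0}, noise_sd=0.5),
    ]
    return generate_drug_response(small_bundle, planted, seed=11)


@pytest.fixture()
def toy_xy():
    """A deterministic 30x5 regression problem with one strong feature."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 5))
    Xs = (X - X.mean(0)) / X.std(0)
    y = 2.0 * Xs[:, 1] + rng.normal(size=30) * 0.3
    return X, y


def make_xy_frame(n, p, effects, noise_sd, seed):
    """Standardized-feature planted linear response as labeled frames."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    Xs = (X - X.mean(0)) / X.std(0)
    y = rng.normal(scale=noise_sd, size=n)
    for j, coef in effects.items():
        y = y + coef * Xs[:, j]
    Xdf = pd.DataFrame(X, index=[f"c{i:03d}" for i in range(n)], columns=[f"g{j:03d}" for j in range(p)])
    return Xdf, pd.Series(y, index=Xdf.index)
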