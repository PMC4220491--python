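import numpy as np
import pandas as pd
import pytest

from ricenet import (
    ExpressionCompendium,
    SyntheticConfig,
    default_config,
    generate_all,
)


@pytest.fixture(scope="session")
def study_config() -> SyntheticConfig:
    """The default study configuration (seed 17)."""
    return default_config(seed=17)


@pytest.fixture(scope="session")
def study_bundle(study_config):
    """All synthetic artifacts for the default study configuration."""
    return generate_all(study_config)


@pytest.fixture(scope="session")
def gene_sets(study_bundle):
    from ricenet import build_gene_sets

    return build_gene_sets(
        study_bundle.ontology,
        study_bundle.annotations,
        universe=study_bundle.control.gene_ids,
    )


@pytest.fixture(scope="session")
def network_results(study_bundle, gene_sets):
    from ricenet import ConditionalNetworkModel

    model = ConditionalNetworkModel(
        study_bundle.control, study_bundle.stress, study_bundle.tf_ids, gene_sets
    )
    return model.fit()


@pytest.fixture()
def small_compendium() -> ExpressionCompendium:
    """A tiny hand-checkable compendium: 4 genes, 6 samples, 2 datasets."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.normal(size=(4, 6)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    ds = pd.Series(["d0"] * 3 + ["d1"] * 3, index=data.columns)
    return ExpressionCompendium(data, ds, "control")
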