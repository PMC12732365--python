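import numpy as np
import pandas as pd
import pytest

import agescreen as ag
from agescreen.classifier import AgeClassifier
from agescreen.simulate import CausalGene, SyntheticSpec


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by unit tests: 3 donors/group x 40
    cells, 60 genes, 3 up- and 3 down-regulated at fold change 6."""
    causal = [CausalGene(i, "up_in_old", 6.0) for i in range(3)] + [
        CausalGene(i, "down_in_old", 6.0) for i in range(3, 6)
    ]
    spec = SyntheticSpec(n_donors_per_group=3, cells_per_donor=40, n_genes=60,
                         causal_genes=causal, seed=7)
    adata, truth = ag.generate_cohort(spec)
    return adata, truth


@pytest.fixture(scope="session")
def small_binned(small_cohort):
    adata, _ = small_cohort
    return ag.bin_expression(ag.filter_genes(adata))


@pytest.fixture()
def tiny_train_config():
    """A shrunken head configuration for fast fitting in unit tests."""
    return ag.TrainConfig(embed_dim=16, n_hidden_layers=2, hidden_units=32,
                          epochs=3, batch_size=64, seed=0)


class LinearStubModel(AgeClassifier):
    """Deterministic stand-in classifier: logit is a fixed linear function
    of the token matrix. Lets screen/stability tests run without training."""

    backend = "stub"

    def __init__(self, gene_symbols, n_bins, coefs):
        super().__init__(gene_symbols, n_bins)
        self.coefs = np.asarray(coefs, dtype=float)

    def _predict_tokens(self, tokens):
        from scipy.special import expit

        z = tokens.astype(float) @ self.coefs / max(1.0, self.n_bins - 1)
        return expit(z)


@pytest.fixture()
def stub_model_factory():
    return LinearStubModel


@pytest.fixture()
def demo_config_factory():
    """Small full-pipeline run config used for orchestration and
    determinism checks."""
    from agescreen.pipeline import RunConfig

    def factory(tmp_path, db_path, seed=0):
        spec = SyntheticSpec(
            n_donors_per_group=3, cells_per_donor=40, n_genes=40,
            causal_genes=[CausalGene(0, "up_in_old", 6.0),
                          CausalGene(1, "down_in_old", 6.0)],
            seed=seed,
        )
        return RunConfig(
            output_dir=str(tmp_path / "out"),
            simulate=spec,
            db_path=str(db_path),
            backend="mlp",
            train={"embed_dim": 32, "hidden_units": 64, "epochs": 4,
                   "batch_size": 64, "seed": 0},
            screen={"n_per_group": 40},
            n_iterations=3,
            seed=seed,
        )

    return factory


@pytest.fixture()
def aging_db_file(tmp_path):
    rows = [
        ("G0000", "highest"), ("G0001", "high"), ("G0002", "moderate"),
        ("G0003", "low"), ("G0004", "lowest"), ("TP53", "highest"),
        ("IGF1", "high"), ("FOXO3", "highest"), ("SIRT1", "high"),
        ("MTOR", "high"), ("KL", "moderate"), ("CDKN2A", "high"),
        ("TERT", "highest"), ("APOE", "highest"), ("SOD2", "moderate"),
        ("TP63", "low"), ("NFE2L2", "moderate"), ("HSPA1A", "low"),
        ("MT-CO1", "lowest"), ("G0010", "high"),
    ]
    path = tmp_path / "aging_genes.tsv"
    pd.DataFrame(rows, columns=["symbol", "confidence"]).to_csv(path, sep="\t", index=False)
    return path
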