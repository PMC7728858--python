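import numpy as np
import pandas as pd
import pytest

import dilipred as dp
from dilipred.classifiers import BaselineConfig, DnnConfig


def fast_dnn(seed: int = 0, epochs: int = 30, activation: str = "elu",
             optimizer: str = "adam") -> DnnConfig:
    """A small, quickly trainable network for tests (still 7 hidden layers)."""
    return DnnConfig(hidden_layer_widths=(32, 16, 16, 8, 8, 8, 8),
                     epochs=epochs, batch_size=32, learning_rate=1e-3,
                     activation=activation, optimizer=optimizer, seed=seed)


def knn(k: int = 3, seed: int = 0) -> BaselineConfig:
    return BaselineConfig("KNN", (("k", k),), seed)


def small_rf(seed: int = 0) -> BaselineConfig:
    return BaselineConfig("RF", (("n_trees", 100), ("max_depth", 8),
                                 ("min_split", 2), ("min_leaf", 1)), seed)


def small_svm(seed: int = 0) -> BaselineConfig:
    return BaselineConfig("SVM", (("kernel", "rbf"), ("C", 10), ("gamma", 0.01)), seed)


ALL_FAMILY_CONFIGS = {
    "DNN": fast_dnn,
    "KNN": knn,
    "SVM": small_svm,
    "RF": small_rf,
}


@pytest.fixture
def signal_profiles() -> dp.ProfileSet:
    """Labeled synthetic set with a strong planted signal."""
    cfg = dp.SyntheticConfig(n_genes=80, n_drugs=40, positive_fraction=0.5,
                             profiles_per_drug=3, n_signal_genes=20,
                             effect_size=3.0, cell_line_sd=0.2, seed=11)
    return dp.generate_profile_set(cfg)


@pytest.fixture
def null_profiles() -> dp.ProfileSet:
    """Labeled synthetic set with no signal at all."""
    cfg = dp.SyntheticConfig(n_genes=60, n_drugs=40, positive_fraction=0.5,
                             profiles_per_drug=3, n_signal_genes=0,
                             effect_size=0.0, cell_line_sd=0.0, seed=7)
    return dp.generate_profile_set(cfg)


def make_profile_set(values, gene_ids=None, profile_ids=None, labels=None,
                     drug_ids=None) -> dp.ProfileSet:
    """Hand-build a ProfileSet from a genes x profiles array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_profiles = values.shape
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(n_genes)]
    profile_ids = profile_ids or [f"p{i:03d}" for i in range(n_profiles)]
    drug_ids = drug_ids or [f"drug{i:03d}" for i in range(n_profiles)]
    meta = pd.DataFrame(
        {
            "profile_id": profile_ids,
            "drug_id": drug_ids,
            "dose": 1.0,
            "duration": 24.0,
            "cell_line": "CL1",
        }
    ).set_index("profile_id")
    if labels is not None:
        meta["dili_label"] = np.asarray(labels, dtype=int)
    return dp.ProfileSet(values=values, gene_ids=gene_ids,
                         profile_ids=profile_ids, metadata=meta)
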