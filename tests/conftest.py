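"""Shared fixtures: small dictionaries, tiny training setups, and the
standard synthetic workflow (trained once per session)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from potencynet.gsbn import core_forward
from potencynet.interpret import feature_importance
from potencynet.io import dual_representation
from potencynet.pipeline import (
    predict_potency,
    standard_hyperparameters,
    standard_simulation,
    standard_split,
)
from potencynet.simulate import SimulationConfig, generate_potency_dataset, planted_markers
from potencynet.training import Hyperparameters, train_model, weighted_accuracy


@pytest.fixture
def small_dictionary():
    from potencynet.io import build_dictionary

    table = pd.DataFrame(
        {
            "human_symbol": ["GENEA", "GENEB", "GENEC", "GENED"],
            "mouse_symbol": ["Genea", "Geneb", "Genec", None],
            "similarity": [0.95, 0.9, 0.85, np.nan],
        }
    )
    return build_dictionary(table, alias_map={"GENEA-ALT": "GENEA"})


def tiny_simulation(seed: int = 0) -> SimulationConfig:
    """A minimal potency dataset for fast training-mechanics tests."""
    return SimulationConfig(
        n_genes=60,
        phenotypes_per_category=1,
        datasets_per_phenotype=2,
        cells_per_phenotype=6,
        markers_per_category=5,
        marker_effect=6.0,
        dropout_rate=0.1,
        seed=seed,
    )


def tiny_hyperparameters(**overrides) -> Hyperparameters:
    defaults = dict(
        M=2, batch_size=36, max_epochs=3, min_epochs_before_stop=1,
        n_bins=4, n_sample=3,
    )
    defaults.update(overrides)
    return Hyperparameters(**defaults)


def tiny_split(seed: int = 0):
    expr, labels = generate_potency_dataset(tiny_simulation(seed))
    mask = (labels["dataset"] == "ds1").to_numpy()
    out = []
    for m in (mask, ~mask):
        H = dual_representation(
            expr.values[:, m],
            [c for c, keep in zip(expr.cell_ids, m) if keep],
            feature_list=expr.gene_ids,
        )
        out += [H, labels.loc[m].reset_index(drop=True)]
    return tuple(out)


@pytest.fixture(scope="session")
def standard_run():
    """Train the standard desk-scale model once and postprocess held-out data.

    Returns a dict with the trained model, splits, predictions, planted
    markers and the feature-importance matrix, shared across tests.
    """
    seed = 1
    H_train, labels_train, H_val, labels_val = standard_split(seed)
    model = train_model(
        (H_train, labels_train),
        (H_val, labels_val),
        hp=standard_hyperparameters(),
        seed=seed,
    )
    _, pred = core_forward(model, H_val)
    table = predict_potency(H_val, model)
    return {
        "seed": seed,
        "model": model,
        "H_train": H_train,
        "labels_train": labels_train,
        "H_val": H_val,
        "labels_val": labels_val,
        "prediction": pred,
        "val_accuracy": weighted_accuracy(pred.y_hat, labels_val),
        "table": table,
        "markers": planted_markers(standard_simulation(seed)),
        "importance": feature_importance([model]),
    }
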