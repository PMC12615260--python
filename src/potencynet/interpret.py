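"""Model interpretation: gene-set polarity, feature importance, Q^pos.

Because the gene-selection layer is binary, each hidden unit is literally
a gene set; the sign of its enrichment-layer weights says whether the set
marks the module's potency category positively or negatively.  Summing
signed selections across gene sets and ensemble members yields the
genes x categories feature-importance matrix ``F``, from which ranked
marker lists per category are extracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CATEGORIES, N_CATEGORIES
from .gsbn import CoreModel, binarize, module_scores
from .io import HarmonizedExpression


@dataclass
class FeatureImportance:
    """Signed selection-frequency matrix F (genes x categories)."""

    F: np.ndarray
    model_count: int
    feature_list: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        index = self.feature_list if self.feature_list is not None else None
        return pd.DataFrame(self.F, index=index, columns=list(CATEGORIES))


def gene_set_polarity(V: np.ndarray, j: int) -> int:
    """Sign of the mean of gene set j's two enrichment weights.

    ``V`` holds 2M weights, the rank-based weight of set j at position j
    and the expression-based weight at position M + j.  Returns +1, -1 or
    0 (exact cancellation contributes nothing to importance).
    """
    V = np.asarray(V, dtype=float)
    M = V.size // 2
    return int(np.sign((V[j] + V[M + j]) / 2.0))


def feature_importance(models) -> FeatureImportance:
    """Signed selection counts summed over models and gene sets.

    ``F[i, p] = sum_l sum_j W_B[i, j] * polarity(V, j)`` over ensemble
    members l and gene sets j of category module p.
    """
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    n = models[0].n_features
    F = np.zeros((n, N_CATEGORIES))
    for model in models:
        if model.n_features != n:
            raise ValueError("models disagree on the feature space")
        for p, module in enumerate(model.modules):
            W_B = binarize(module.W)
            for j in range(module.n_gene_sets):
                F[:, p] += W_B[:, j] * gene_set_polarity(module.V, j)
    return FeatureImportance(
        F=F, model_count=len(models), feature_list=models[0].feature_list
    )


def positive_score_matrix(model: CoreModel, H: HarmonizedExpression) -> np.ndarray:
    """Per-module scores using only positive enrichment-layer weights.

    Multiplying the normalized enrichment scores by ``max(V, 0)`` isolates
    the positively weighted gene programs; columns are concatenated across
    the six modules, giving a C x 6 matrix per model (C x 6L for an
    ensemble when called per member and stacked).
    """
    cols = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for module in model.modules:
            K_norm = module_scores(module, H, model.background, mode="infer")
            cols.append(K_norm @ np.maximum(module.V, 0.0))
    return np.column_stack(cols)


def rank_markers(
    fi: FeatureImportance | np.ndarray,
    category: int | str,
    direction: str = "positive",
    top_n: int = 500,
) -> np.ndarray:
    """Top marker gene indices for a category by feature importance.

    ``direction="positive"`` sorts the category's importance column
    descending, ``"negative"`` ascending (signed values); ties break by
    feature index.  Returns indices into the feature list.
    """
    F = fi.F if isinstance(fi, FeatureImportance) else np.asarray(fi)
    if isinstance(category, str):
        category = CATEGORIES.index(category) + 1
    col = F[:, category - 1]
    if direction == "positive":
        order = np.argsort(-col, kind="stable")
    elif direction == "negative":
        order = np.argsort(col, kind="stable")
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    if top_n > F.shape[0]:
        warnings.warn(f"top_n={top_n} exceeds {F.shape[0]} features; clipping",
                      stacklevel=2)
        top_n = F.shape[0]
    return order[:top_n]
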