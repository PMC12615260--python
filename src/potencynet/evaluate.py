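"""Evaluation metrics for potency predictions.

Concordance with known developmental order is measured with a weighted
Kendall correlation over all cell pairs, with a tau-b style tie
correction; ground-truth ranks ascend with maturity (1 = least mature =
most potent), so predictions are reversed internally before comparison.
Categorical performance uses a mean one-vs-rest F1 across ground-truth
categories and a mean absolute error on the 1..6 category codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats
from sklearn.metrics import f1_score

from .constants import N_CATEGORIES, category_codes


@dataclass
class OrderEvaluation:
    """Weighted Kendall correlation with a normal-approximation p-value."""

    tau: float
    p_value: float
    n_cells: int
    weighting_scheme: str = "unit"


def _balanced_weights(truth_ranks: np.ndarray) -> np.ndarray:
    """Equal total weight per ground-truth level, uniform within levels."""
    levels, counts = np.unique(truth_ranks, return_counts=True)
    per_level = 1.0 / len(levels)
    lookup = {lv: per_level / c for lv, c in zip(levels, counts)}
    return np.array([lookup[r] for r in truth_ranks])


def weighted_kendall(
    pred_scores: np.ndarray,
    truth_ranks: np.ndarray,
    weights: np.ndarray | str | None = "balanced",
) -> OrderEvaluation:
    """Weighted Kendall tau between predictions and maturity ranks.

    ``truth_ranks`` ascend with maturity while higher ``pred_scores``
    denote higher potency, so predictions are negated before comparison:
    perfectly anti-monotone predictions yield tau = 1.  Pair weights are
    products of per-cell weights; ties are handled tau-b style.  Weights
    may be an explicit vector, ``"balanced"`` (equal mass per truth level)
    or ``"unit"``/None.
    """
    x = -np.asarray(pred_scores, dtype=float)  # higher potency -> lower rank
    y = np.asarray(truth_ranks, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("prediction and truth lengths differ")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Kendall correlation undefined for constant inputs")
    if weights is None or (isinstance(weights, str) and weights == "unit"):
        w, scheme = np.ones(n), "unit"
    elif isinstance(weights, str) and weights == "balanced":
        w, scheme = _balanced_weights(y), "balanced"
    else:
        w, scheme = np.asarray(weights, dtype=float), "custom"
        if (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative and not all zero")

    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    W = np.outer(w, w)
    iu = np.triu_indices(n, k=1)
    conc = float(np.sum(W[iu] * dx[iu] * dy[iu]))
    denom_x = float(np.sum(W[iu] * (dx[iu] != 0)))
    denom_y = float(np.sum(W[iu] * (dy[iu] != 0)))
    tau = conc / np.sqrt(denom_x * denom_y)

    # normal approximation with the effective sample size of the weights
    n_eff = w.sum() ** 2 / np.sum(w**2)
    z = 3.0 * tau * np.sqrt(n_eff * (n_eff - 1)) / np.sqrt(2.0 * (2.0 * n_eff + 5.0))
    p = 2.0 * spstats.norm.sf(abs(z))
    return OrderEvaluation(tau=float(tau), p_value=float(p), n_cells=n,
                           weighting_scheme=scheme)


def mean_multiclass_f1(pred_categories, truth_categories) -> float:
    """Mean one-vs-rest F1 over the categories present in the truth."""
    truth = _as_codes(truth_categories)
    pred = _as_codes(pred_categories)
    labels = np.unique(truth)
    scores = f1_score(truth, pred, labels=labels, average=None, zero_division=0)
    return float(np.mean(scores))


def mae_potency(pred_categories, truth_categories) -> float:
    """Mean absolute error on category codes, averaged per truth category.

    Codes run from 1 (differentiated) to 6 (totipotent); the per-category
    mean absolute difference is averaged across truth categories.
    """
    truth = _as_codes(truth_categories)
    pred = _as_codes(pred_categories)
    per_cat = [
        np.abs(pred[truth == c] - c).mean() for c in np.unique(truth)
    ]
    return float(np.mean(per_cat))


def _as_codes(categories) -> np.ndarray:
    arr = np.asarray(categories)
    if arr.dtype.kind in "iu":
        codes = arr.astype(int)
        if ((codes < 1) | (codes > N_CATEGORIES)).any():
            raise ValueError(f"category codes must lie in 1..{N_CATEGORIES}")
        return codes
    return category_codes(arr)
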