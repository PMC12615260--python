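"""Postprocessing: diffusion smoothing, category binning, adaptive k-NN.

Raw per-cell potency scores are refined in three steps that exploit the
assumption that transcriptionally similar cells occupy related
differentiation states:

1. **Markov diffusion** — a cell-cell Pearson similarity matrix over the
   top-dispersion genes (negatives clipped, rows normalized) drives the
   fixed-point iteration ``s <- alpha * P_M s + (1 - alpha) * RPS``; the
   result is a convex combination of raw scores, hence bounded by them.
2. **Category-preserving binning** — within each predicted category the
   smoothed scores are rank-mapped uniformly into that category's
   sixth of the unit interval, keeping the categorical call intact while
   preserving within-category order.
3. **Adaptive k-NN smoothing** — per cell, the neighborhood size is grown
   until two successive nearest-neighbor groups imply the same category,
   then the binned scores are averaged with ``(1 - d)^2`` distance
   weights in 30-PC space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .constants import N_CATEGORIES


@dataclass
class DiffusionConfig:
    """Markov-diffusion settings (``alpha`` is the smoothing strength)."""

    alpha: float = 0.9
    n_dispersion_genes: int = 1000
    tolerance: float = 1e-5
    max_iterations: int = 10_000
    subsample_threshold: int = 10_000

    def __post_init__(self):
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")


@dataclass
class KnnConfig:
    """Adaptive k-NN smoothing settings."""

    n_pcs: int = 30
    max_neighborhood: int = 30
    max_group: int = 15
    fallback_k: int = 3
    min_cells: int = 100

    def __post_init__(self):
        if self.fallback_k > self.max_neighborhood:
            raise ValueError("fallback_k cannot exceed max_neighborhood")


def score_to_category(score: float) -> int:
    """Map a potency score in [0, 1] to a category code 1..6.

    Intervals are left-closed, right-open: code ``p`` covers
    ``[(p-1)/6, p/6)``; a score of exactly 1 maps to totipotent.
    """
    s = np.asarray(score, dtype=float)
    if (s < 0).any() or (s > 1).any():
        raise ValueError("potency scores must lie in [0, 1]")
    codes = np.minimum(np.floor(s * N_CATEGORIES).astype(int) + 1, N_CATEGORIES)
    return int(codes) if np.isscalar(score) or codes.ndim == 0 else codes


def _dispersion_genes(L: np.ndarray, n_genes: int) -> np.ndarray:
    """Indices of the top genes by dispersion (variance / mean) of L."""
    mean = L.mean(axis=1)
    var = L.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(-disp, kind="stable")
    return order[: min(n_genes, L.shape[0])]


def markov_diffusion(
    L: np.ndarray, RPS: np.ndarray, cfg: DiffusionConfig | None = None
) -> np.ndarray:
    """Diffuse raw potency scores over the cell-cell similarity graph.

    Similarity is the Pearson correlation between cells over the
    top-dispersion genes, with negative entries zeroed and rows normalized
    to a stochastic matrix.  Convergence uses Jacobi iteration with an
    L-infinity tolerance.  Degenerate similarity (constant expression)
    falls back to the identity, returning the raw scores unchanged.
    """
    cfg = cfg or DiffusionConfig()
    RPS = np.asarray(RPS, dtype=float)
    L = np.asarray(L, dtype=float)
    n = RPS.size
    if n < 2:
        raise ValueError("diffusion needs at least two cells")
    sub = L[_dispersion_genes(L, cfg.n_dispersion_genes)]
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.corrcoef(sub.T)
    bad = ~np.isfinite(sim).all(axis=1)
    if bad.any():
        warnings.warn(
            f"{bad.sum()} cells have undefined correlation; using identity rows",
            stacklevel=2,
        )
        sim[bad] = 0.0
        sim[:, bad] = 0.0
        sim[bad, bad] = 1.0
    np.clip(sim, 0.0, None, out=sim)
    rowsum = sim.sum(axis=1, keepdims=True)
    P_M = sim / rowsum

    s = RPS.copy()
    for _ in range(cfg.max_iterations):
        s_new = cfg.alpha * (P_M @ s) + (1.0 - cfg.alpha) * RPS
        if np.max(np.abs(s_new - s)) < cfg.tolerance:
            return s_new
        s = s_new
    warnings.warn("diffusion did not converge within max_iterations", stacklevel=2)
    return s


def bin_scores(SPS: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    """Rank-map smoothed scores into each predicted category's interval.

    Within category ``p`` (codes 1..6), cells are ranked ascending by
    score (rank ``r`` of ``r_max``, ties broken by cell index) and placed
    at ``(p - 1)/6 + (r / (r_max + 1)) / 6`` — strictly inside the
    category's sixth of the unit interval, so the categorical call is
    recoverable exactly and within-category order is preserved.
    """
    SPS = np.asarray(SPS, dtype=float)
    y_hat = np.asarray(y_hat, dtype=int)
    out = np.empty_like(SPS)
    for p in range(1, N_CATEGORIES + 1):
        members = np.where(y_hat == p)[0]
        if members.size == 0:
            continue
        order = np.argsort(SPS[members], kind="stable")
        ranks = np.empty(members.size)
        ranks[order] = np.arange(1, members.size + 1)
        out[members] = (p - 1) / N_CATEGORIES + (
            ranks / (members.size + 1)
        ) / N_CATEGORIES
    return out


def _pca_embed(L: np.ndarray, n_pcs: int) -> np.ndarray:
    """Cell embedding: per-cell standardization then deterministic PCA."""
    X = np.asarray(L, dtype=float).T  # cells x genes
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    X = X / np.where(sd > 0, sd, 1.0)
    k = min(n_pcs, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    Z = pca.fit_transform(X)
    # sign convention: largest-magnitude loading positive
    for j in range(k):
        comp = pca.components_[j]
        if comp[np.argmax(np.abs(comp))] < 0:
            Z[:, j] = -Z[:, j]
    return Z


def adaptive_knn_smooth(
    L: np.ndarray,
    SPS_binned: np.ndarray,
    cfg: KnnConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adaptive neighborhood smoothing of binned potency scores.

    Returns ``(final_score, y_hat_star, k_used)``.  For datasets of at
    most ``cfg.min_cells`` cells the scores pass through unchanged
    (``k_used = 0``).  Otherwise, for each center cell the candidate set
    is its ``max_neighborhood`` nearest neighbors in PC space with
    distances rescaled to unit maximum; the neighborhood grows until the
    mean scores of group ``{w, c_1..c_m}`` and group ``{c_{m+1}..c_{2m+1}}``
    map to the same category (then ``k = 2m + 1``), falling back to
    ``k = fallback_k`` when no agreement is reached by group size
    ``max_group``.  The final score is the ``(1 - d)^2``-weighted mean of
    binned scores over the neighborhood including the center at d = 0.
    """
    cfg = cfg or KnnConfig()
    scores = np.asarray(SPS_binned, dtype=float)
    n = scores.size
    if n <= cfg.min_cells:
        return scores.copy(), score_to_category(scores), np.zeros(n, dtype=int)
    if n - 1 < 4:
        warnings.warn("too few cells for k-NN smoothing; passing through", stacklevel=2)
        return scores.copy(), score_to_category(scores), np.zeros(n, dtype=int)

    Z = _pca_embed(L, cfg.n_pcs)
    final = np.empty(n)
    k_used = np.empty(n, dtype=int)
    n_candidates = min(cfg.max_neighborhood, n - 1)
    for w in range(n):
        d = np.linalg.norm(Z - Z[w], axis=1)
        d[w] = np.inf
        nearest = np.argsort(d, kind="stable")[:n_candidates]
        dist = d[nearest]
        dmax = dist[-1]
        rescaled = dist / dmax if dmax > 0 else np.zeros_like(dist)

        k = cfg.fallback_k
        m = 1
        while 2 * m + 1 <= n_candidates and m + 1 <= cfg.max_group:
            group_a = np.concatenate(([scores[w]], scores[nearest[:m]]))
            group_b = scores[nearest[m : 2 * m + 1]]
            if score_to_category(float(np.clip(group_a.mean(), 0, 1))) == \
               score_to_category(float(np.clip(group_b.mean(), 0, 1))):
                k = 2 * m + 1
                break
            m += 1
        k = min(k, n_candidates)
        neigh = nearest[:k]
        wts = np.concatenate(([1.0], (1.0 - rescaled[:k]) ** 2))
        vals = np.concatenate(([scores[w]], scores[neigh]))
        final[w] = np.dot(wts, vals) / wts.sum()
        k_used[w] = k
    final = np.clip(final, 0.0, 1.0)
    return final, score_to_category(final), k_used


def postprocess_scores(
    L: np.ndarray,
    RPS: np.ndarray,
    y_hat: np.ndarray,
    diffusion: DiffusionConfig | None = None,
    knn: KnnConfig | None = None,
) -> dict[str, np.ndarray]:
    """Run the full three-step postprocessing chain.

    Returns a dict with ``SPS`` (diffused), ``SPS_binned``, ``final_score``,
    ``y_hat_star`` and ``k_used``.
    """
    SPS = markov_diffusion(L, RPS, diffusion)
    binned = bin_scores(SPS, y_hat)
    final, y_star, k_used = adaptive_knn_smooth(L, binned, knn)
    return {
        "SPS": SPS,
        "SPS_binned": binned,
        "final_score": final,
        "y_hat_star": y_star,
        "k_used": k_used,
    }
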