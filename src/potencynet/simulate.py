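"""Potency-structured synthetic scRNA-seq data and robustness perturbations.

The generator emulates the hierarchical structure of a curated potency
atlas: six ordered categories, each containing several standardized
phenotypes observed across datasets.  Counts follow a negative-binomial
model with log-normal library sizes and optional extra dropout; each
category carries a disjoint block of planted marker genes whose mean
expression is up-shifted by a configurable fold change, so the categories
form distinct, recoverable programs.

The perturbation operations reproduce the robustness protocols used to
stress potency predictors: Gaussian rank-distance label noise calibrated
to target perturbation levels, per-cell gene-count and UMI downsampling,
and rarity titration of a selected phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .constants import CATEGORIES, N_CATEGORIES, category_codes
from .io import RawExpression, validate_labels


@dataclass
class SimulationConfig:
    """Settings of the synthetic potency-atlas generator.

    ``cells_per_phenotype`` counts cells per phenotype *per dataset*;
    ``marker_effect`` is the fold change applied to a category's marker
    genes in cells of that category.
    """

    n_genes: int = 500
    phenotypes_per_category: int = 2
    datasets_per_phenotype: int = 2
    cells_per_phenotype: int = 50
    markers_per_category: int = 20
    marker_effect: float = 5.0
    library_size_mean: float = 2000.0
    library_size_sigma: float = 0.3
    nb_dispersion: float = 0.5      # var = mu + dispersion * mu^2
    dropout_rate: float = 0.2
    phenotype_effect: float = 2.0   # fold change of phenotype-specific genes
    phenotype_genes: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.markers_per_category * N_CATEGORIES > self.n_genes:
            raise ValueError("marker allocation exceeds the number of genes")
        for name in ("phenotypes_per_category", "datasets_per_phenotype",
                     "cells_per_phenotype", "markers_per_category"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_cells(self) -> int:
        return (N_CATEGORIES * self.phenotypes_per_category
                * self.datasets_per_phenotype * self.cells_per_phenotype)


def planted_markers(cfg: SimulationConfig) -> dict[str, np.ndarray]:
    """Gene indices of the disjoint marker block of each category."""
    k = cfg.markers_per_category
    return {
        name: np.arange(i * k, (i + 1) * k) for i, name in enumerate(CATEGORIES)
    }


def generate_potency_dataset(
    cfg: SimulationConfig | None = None,
) -> tuple[RawExpression, pd.DataFrame]:
    """Generate a synthetic potency-structured counts matrix with labels.

    Deterministic given ``cfg`` (including its seed).  Returns the counts
    and a label table with ``cell_id``, ``broad_category``,
    ``granular_level``, ``phenotype`` and ``dataset`` columns.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n_genes = cfg.n_genes
    markers = planted_markers(cfg)

    # baseline relative expression, shared across categories
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    # phenotype-specific nuisance programs (distinct genes per phenotype)
    phen_factors: dict[tuple[str, int], np.ndarray] = {}
    for cat in CATEGORIES:
        for ph in range(cfg.phenotypes_per_category):
            genes = rng.choice(n_genes, size=cfg.phenotype_genes, replace=False)
            f = np.ones(n_genes)
            f[genes] = cfg.phenotype_effect
            phen_factors[(cat, ph)] = f

    counts = np.zeros((n_genes, cfg.n_cells))
    records = []
    col = 0
    theta = 1.0 / cfg.nb_dispersion if cfg.nb_dispersion > 0 else np.inf
    for ci, cat in enumerate(CATEGORIES):
        profile_cat = base.copy()
        profile_cat[markers[cat]] *= cfg.marker_effect
        for ph in range(cfg.phenotypes_per_category):
            profile = profile_cat * phen_factors[(cat, ph)]
            probs = profile / profile.sum()
            phenotype = f"{cat}_ph{ph + 1}"
            granular = (N_CATEGORIES - 1 - ci) * cfg.phenotypes_per_category + ph + 1
            for d in range(cfg.datasets_per_phenotype):
                dataset = f"ds{d + 1}"
                for _ in range(cfg.cells_per_phenotype):
                    lib = rng.lognormal(
                        mean=np.log(cfg.library_size_mean), sigma=cfg.library_size_sigma
                    )
                    mu = lib * probs
                    if np.isfinite(theta):
                        lam = rng.gamma(shape=theta, scale=mu / theta)
                    else:
                        lam = mu
                    x = rng.poisson(lam).astype(float)
                    if cfg.dropout_rate > 0:
                        x *= rng.random(n_genes) >= cfg.dropout_rate
                    counts[:, col] = x
                    records.append(
                        {
                            "cell_id": f"cell{col:05d}",
                            "broad_category": cat,
                            "granular_level": granular,
                            "phenotype": phenotype,
                            "dataset": dataset,
                        }
                    )
                    col += 1
    labels = validate_labels(pd.DataFrame.from_records(records))
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    expr = RawExpression(counts, gene_ids, labels["cell_id"].tolist(), is_counts=True)
    return expr, labels


# ---------------------------------------------------------------------------
# label-noise transition matrices
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """Row-stochastic 6x6 label-noise matrix with Gaussian rank kernel."""

    P_trans: np.ndarray
    sigma: float

    def __post_init__(self):
        self.P_trans = np.asarray(self.P_trans, dtype=float)
        if self.P_trans.shape != (N_CATEGORIES, N_CATEGORIES):
            raise ValueError("transition matrix must be 6x6")
        if not np.allclose(self.P_trans.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows must sum to 1")


def build_transition_matrix(sigma: float) -> TransitionMatrix:
    """Gaussian rank-distance kernel, rows normalized to unit sum.

    ``P[j, i] ∝ exp(-(j - i)^2 / (2 sigma^2))`` over categories 1..6.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    idx = np.arange(N_CATEGORIES)
    kernel = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2.0 * sigma**2))
    return TransitionMatrix(kernel / kernel.sum(axis=1, keepdims=True), sigma)


def expected_perturbation_fraction(sigma: float, pi: np.ndarray | None = None) -> float:
    """Expected changed-label fraction ``1 - sum_j pi_j P[j, j]``."""
    T = build_transition_matrix(sigma)
    pi = np.full(N_CATEGORIES, 1 / N_CATEGORIES) if pi is None else np.asarray(pi)
    return float(1.0 - np.dot(pi, np.diag(T.P_trans)))


def calibrate_sigma(
    target: float,
    pi: np.ndarray | None = None,
    tol: float = 1e-4,
) -> float:
    """Find sigma whose expected perturbation fraction equals ``target``.

    The fraction increases monotonically in sigma up to the flat-kernel
    ceiling of 5/6 under a uniform label distribution; targets at or above
    the ceiling for the given ``pi`` are rejected.
    """
    if not 0 < target < 1:
        raise ValueError("target must lie in (0, 1)")
    lo, hi = 1e-3, 1e3
    ceiling = expected_perturbation_fraction(hi, pi)
    if target >= ceiling - tol:
        raise ValueError(
            f"target {target} unreachable; the uniform-kernel ceiling is "
            f"{ceiling:.4f} (5/6 for uniform labels)"
        )
    f = lambda s: expected_perturbation_fraction(s, pi) - target
    if f(lo) > 0:
        return lo
    sigma = optimize.brentq(f, lo, hi, xtol=1e-10)
    assert abs(expected_perturbation_fraction(sigma, pi) - target) < tol
    return float(sigma)


#: Perturbation levels used for label-noise titration.
TITRATION_LEVELS = (0.05, 0.10, 0.20, 0.50, 0.80)


def perturb_labels(
    labels: pd.DataFrame,
    T: TransitionMatrix,
    level: str = "cell",
    seed: int = 0,
) -> pd.DataFrame:
    """Resample potency labels from the transition matrix.

    ``level="cell"`` perturbs each cell independently from its category's
    row; ``level="phenotype"`` draws once per phenotype and applies the
    outcome to all of its cells.
    """
    labels = labels.copy()
    rng = np.random.default_rng(seed)
    codes = category_codes(labels["broad_category"]) - 1
    if level == "cell":
        new = np.array(
            [rng.choice(N_CATEGORIES, p=T.P_trans[c]) for c in codes]
        )
    elif level == "phenotype":
        if "phenotype" not in labels.columns:
            raise ValueError("phenotype-level perturbation needs a phenotype column")
        new = codes.copy()
        for ph in pd.unique(labels["phenotype"]):
            mask = (labels["phenotype"] == ph).to_numpy()
            drawn = rng.choice(N_CATEGORIES, p=T.P_trans[codes[mask][0]])
            new[mask] = drawn
    else:
        raise ValueError("level must be 'cell' or 'phenotype'")
    labels["broad_category"] = [CATEGORIES[c] for c in new]
    return labels


# ---------------------------------------------------------------------------
# downsampling perturbations
# ---------------------------------------------------------------------------

def downsample_gene_counts(expr: RawExpression, g: int, seed: int = 0) -> RawExpression:
    """Keep each cell's top ``g`` genes by expression, zeroing the rest.

    Ties at the inclusion threshold are resolved at random (seeded).
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    rng = np.random.default_rng(seed)
    out = expr.values.copy()
    for k in range(expr.n_cells):
        col = out[:, k]
        nz = np.where(col > 0)[0]
        if nz.size <= g:
            continue
        vals = col[nz]
        order = np.argsort(-vals, kind="stable")
        threshold = vals[order[g - 1]]
        above = nz[vals > threshold]
        at = nz[vals == threshold]
        need = g - above.size
        keep = np.concatenate([above, rng.choice(at, size=need, replace=False)])
        mask = np.ones(expr.n_genes, dtype=bool)
        mask[keep] = False
        col[mask] = 0.0
    return RawExpression(out, expr.gene_ids, expr.cell_ids, is_counts=expr.is_counts)


def downsample_umis(expr: RawExpression, u: int, seed: int = 0) -> RawExpression:
    """Multinomially downsample each cell to ``u`` total transcripts.

    Cells whose total is at most ``u`` are unaltered.  Requires integer
    counts.
    """
    values = expr.values
    if not np.allclose(values, np.round(values)):
        raise ValueError("UMI downsampling requires integer counts")
    rng = np.random.default_rng(seed)
    out = values.copy()
    totals = values.sum(axis=0)
    for k in range(expr.n_cells):
        if totals[k] <= u:
            continue
        p = values[:, k] / totals[k]
        out[:, k] = rng.multinomial(u, p)
    return RawExpression(out, expr.gene_ids, expr.cell_ids, is_counts=True)


def titrate_rarity(
    expr: RawExpression,
    labels: pd.DataFrame,
    phenotype: str,
    n_keep: int,
    seed: int = 0,
) -> tuple[RawExpression, pd.DataFrame]:
    """Subsample one phenotype to ``n_keep`` cells, leaving others intact."""
    mask = (labels["phenotype"] == phenotype).to_numpy()
    size = int(mask.sum())
    if size == 0:
        raise ValueError(f"phenotype {phenotype!r} not present")
    if n_keep > size:
        raise ValueError(f"n_keep={n_keep} exceeds phenotype size {size}")
    rng = np.random.default_rng(seed)
    members = np.where(mask)[0]
    keep = set(rng.choice(members, size=n_keep, replace=False).tolist())
    selected = np.array([(not mask[i]) or (i in keep) for i in range(len(labels))])
    new_expr = RawExpression(
        expr.values[:, selected],
        expr.gene_ids,
        [c for c, s in zip(expr.cell_ids, selected) if s],
        is_counts=expr.is_counts,
    )
    return new_expr, labels.loc[selected].reset_index(drop=True)
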