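"""The gene-set binary network (GSBN) core model and its forward pass.

One GSBN module per potency category learns ``M`` gene sets as columns of
a binary N x M weight matrix (binarized from a continuous surrogate).
Each gene set is scored per cell by two complementary enrichment
statistics:

* ``Score_U`` — a rank-based (UCell-style) score over the cell's trimmed
  rank vector, bounded above by 1 when the set occupies the top ranks;
* ``Score_A`` — the mean log-expression of set genes minus the mean over
  expression-matched background genes (module-score style), using a fixed
  background map built once from reference mean expression.

The 2M scores are standardized with stored running statistics, passed
through a per-module enrichment layer (weights ``V`` and a scalar bias)
to a logit, and the six module logits are concatenated and softmaxed into
the category likelihood matrix ``P``.  The raw potency score is
``RPS = P @ t`` with the ordered anchor vector ``t = [0, 0.2, ..., 1]``.
"""

from __future__ import annotations

import io as _io
import json
import warnings
import zipfile
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .constants import CATEGORIES, N_CATEGORIES, T_VEC
from .io import HarmonizedExpression

BN_EPS = 1e-5
BN_MOMENTUM = 0.1


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def trim_ranks(R: np.ndarray, tau: float) -> np.ndarray:
    """Trim ranks at the learnable cutoff: ``T = min(R, tau)``."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    return np.minimum(R, tau)


def binarize(W: np.ndarray, a: float = 0.0) -> np.ndarray:
    """Binary weights: 1 where ``W > a``, 0 where ``W <= a``."""
    return (np.asarray(W) > a).astype(float)


def compute_tau(tau_m: float, set_sizes: np.ndarray) -> int:
    """Rank cutoff ``tau = 10 + max_j S_j + 1000 * max(0, tau_m)``.

    Keeps at least ten ranks beyond the largest gene set; rounded to the
    nearest integer for use as a rank.
    """
    s_max = float(np.max(set_sizes)) if np.size(set_sizes) else 0.0
    return int(round(10.0 + s_max + 1000.0 * max(0.0, float(tau_m))))


def ucell_score(
    T: np.ndarray, W_B: np.ndarray, tau: float, allow_empty: bool = False
) -> np.ndarray:
    """Rank-based enrichment score per cell and gene set.

    ``Score_U[k, j] = 1 + [S_j (S_j + 1) - 2 sum_i T[i,k] W_B[i,j]] / (2 tau S_j)``

    with ``S_j`` the size of gene set ``j``.  The score is 1 when the set
    occupies ranks ``1..S_j`` and ``(S_j + 1) / (2 tau)`` when every set
    gene is trimmed at ``tau``.  Returns a C x M matrix.
    """
    W_B = np.asarray(W_B, dtype=float)
    S = W_B.sum(axis=0)
    if (S == 0).any():
        if not allow_empty:
            raise ValueError(f"empty gene sets at columns {np.where(S == 0)[0].tolist()}")
        S = np.maximum(S, 1.0)
    rank_sums = np.asarray(T, dtype=float).T @ W_B  # C x M
    return 1.0 + (S * (S + 1.0) - 2.0 * rank_sums) / (2.0 * float(tau) * S)


@dataclass
class BackgroundMap:
    """Fixed mapping of each gene to expression-matched background genes.

    ``B`` is a sparse binary N x N matrix: ``B[i, j] = 1`` when gene j
    serves as background for gene i.  Background genes are sampled without
    replacement from gene i's average-expression bin, excluding i itself.
    """

    B: sparse.csr_matrix
    n_bins: int = 24
    n_sample: int = 100
    seed: int = 0

    def __post_init__(self):
        self.B = sparse.csr_matrix(self.B)
        self._B_t = None

    @property
    def set_to_background(self) -> sparse.csr_matrix:
        """``B.T`` — left-multiplying a gene-set matrix by this maps set
        genes to their background genes (with multiplicity when shared)."""
        if self._B_t is None:
            self._B_t = self.B.T.tocsr()
        return self._B_t


def build_background_map(
    mean_log_expr: np.ndarray,
    n_bins: int = 24,
    n_sample: int = 100,
    seed: int = 0,
) -> BackgroundMap:
    """Sample the background-gene map from reference mean expression.

    Genes are ranked by ``mean_log_expr`` and uniformly partitioned into
    ``n_bins`` bins.  For each gene, the background count is drawn from a
    Gaussian with mean ``n_sample`` and variance
    ``n_sample * (s_bin - n_sample) / s_bin`` (rounded, clamped to
    ``[1, s_bin - 1]``), and that many distinct same-bin genes are sampled
    without replacement, self excluded.  Deterministic given ``seed``.
    """
    mean_log_expr = np.asarray(mean_log_expr, dtype=float)
    n = mean_log_expr.size
    if n <= n_bins:
        raise ValueError(f"need more genes ({n}) than bins ({n_bins})")
    s_bin = n // n_bins
    if s_bin <= n_sample:
        raise ValueError(
            f"bin size {s_bin} must exceed n_sample {n_sample}; "
            "reduce n_sample (or n_bins) for this feature space"
        )
    var = n_sample * (s_bin - n_sample) / s_bin
    rng = np.random.default_rng(seed)
    # descending mean expression, ties by index; split into n_bins rank bins
    order = np.argsort(-mean_log_expr, kind="stable")
    bins = np.array_split(order, n_bins)
    rows, cols = [], []
    for members in bins:
        members = np.asarray(members)
        for gene in members:
            candidates = members[members != gene]
            count = int(round(rng.normal(n_sample, np.sqrt(var))))
            count = min(max(count, 1), len(candidates))
            chosen = rng.choice(candidates, size=count, replace=False)
            rows.extend([gene] * count)
            cols.extend(chosen.tolist())
    B = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    return BackgroundMap(B=B, n_bins=n_bins, n_sample=n_sample, seed=seed)


def ams_score(
    L: np.ndarray,
    W_B: np.ndarray,
    background: BackgroundMap,
    allow_empty: bool = False,
) -> np.ndarray:
    """Background-subtracted mean-expression score per cell and gene set.

    ``Score_A[k, j]`` is the mean expression of set-j genes in cell k minus
    the aggregated mean over their background genes (counted with
    multiplicity when shared between set members).  Returns C x M.
    """
    W_B = np.asarray(W_B, dtype=float)
    S = W_B.sum(axis=0)
    if (S == 0).any() and not allow_empty:
        raise ValueError(f"empty gene sets at columns {np.where(S == 0)[0].tolist()}")
    S = np.maximum(S, 1.0)
    E = np.asarray(L, dtype=float).T  # C x N
    BW = np.asarray(background.set_to_background @ W_B)  # N x M
    bg_totals = np.maximum(BW.sum(axis=0), 1.0)
    return (E @ W_B) / S - (E @ BW) / bg_totals


def normalize_scores(K: np.ndarray, stats: "NormStats", mode: str) -> np.ndarray:
    """Standardize each enrichment-score column.

    In ``"train"`` mode columns are standardized by batch mean/variance and
    running statistics are updated with momentum 0.1; in ``"infer"`` mode
    the stored statistics are applied unchanged.
    """
    K = np.asarray(K, dtype=float)
    if mode == "train":
        mean = K.mean(axis=0)
        var = K.var(axis=0)
        n = K.shape[0]
        unbiased = var * n / max(n - 1, 1)
        stats.update(mean, unbiased)
        return (K - mean) / np.sqrt(var + BN_EPS)
    if mode == "infer":
        if not stats.fitted:
            raise ValueError("normalization statistics have not been fitted")
        return (K - stats.mean) / np.sqrt(stats.var + BN_EPS)
    raise ValueError("mode must be 'train' or 'infer'")


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class NormStats:
    """Running mean/variance of the 2M enrichment scores of one module."""

    mean: np.ndarray
    var: np.ndarray
    fitted: bool = False
    momentum: float = BN_MOMENTUM

    @classmethod
    def empty(cls, n: int) -> "NormStats":
        return cls(mean=np.zeros(n), var=np.ones(n), fitted=False)

    def update(self, batch_mean: np.ndarray, batch_var: np.ndarray) -> None:
        if not self.fitted:
            self.mean = batch_mean.copy()
            self.var = batch_var.copy()
            self.fitted = True
        else:
            m = self.momentum
            self.mean = (1 - m) * self.mean + m * batch_mean
            self.var = (1 - m) * self.var + m * batch_var


@dataclass
class GSBNModuleParams:
    """Learnable parameters of one potency-category module."""

    W: np.ndarray          # N x M continuous gene-set weights
    tau_m: float           # rank-cutoff parameter (scaled into tau)
    V: np.ndarray          # length-2M enrichment-layer weights
    bias: float = 0.0
    norm_stats: NormStats | None = None

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.V.size != 2 * self.W.shape[1]:
            raise ValueError("V must have length 2M")
        if self.norm_stats is None:
            self.norm_stats = NormStats.empty(self.V.size)

    @property
    def n_gene_sets(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "GSBNModuleParams":
        return GSBNModuleParams(
            W=self.W.copy(),
            tau_m=float(self.tau_m),
            V=self.V.copy(),
            bias=float(self.bias),
            norm_stats=NormStats(
                self.norm_stats.mean.copy(),
                self.norm_stats.var.copy(),
                self.norm_stats.fitted,
            ),
        )


@dataclass
class CoreModel:
    """Six ordered GSBN modules plus the shared background map."""

    modules: list[GSBNModuleParams]
    background: BackgroundMap
    dropout_rate: float = 0.5
    feature_list: list[str] | None = None
    t_vec: np.ndarray = field(default_factory=lambda: T_VEC.copy())

    def __post_init__(self):
        if len(self.modules) != N_CATEGORIES:
            raise ValueError(f"expected {N_CATEGORIES} modules, got {len(self.modules)}")
        if not np.all(np.diff(self.t_vec) > 0) or self.t_vec[0] != 0 or self.t_vec[-1] != 1:
            raise ValueError("t_vec must increase strictly from 0 to 1")

    @property
    def n_features(self) -> int:
        return self.modules[0].W.shape[0]

    def copy(self) -> "CoreModel":
        return CoreModel(
            modules=[m.copy() for m in self.modules],
            background=self.background,
            dropout_rate=self.dropout_rate,
            feature_list=self.feature_list,
            t_vec=self.t_vec.copy(),
        )


@dataclass
class PotencyPrediction:
    """Per-cell category likelihoods and potency scores."""

    P: np.ndarray                      # C x 6 likelihoods
    y_hat: np.ndarray                  # category codes 1..6
    RPS: np.ndarray                    # raw potency score in [0, 1]
    cell_ids: list[str] | None = None
    SPS: np.ndarray | None = None      # diffusion-smoothed score
    SPS_binned: np.ndarray | None = None
    final_score: np.ndarray | None = None
    y_hat_star: np.ndarray | None = None
    k_used: np.ndarray | None = None

    @property
    def category_names(self) -> list[str]:
        codes = self.y_hat_star if self.y_hat_star is not None else self.y_hat
        return [CATEGORIES[c - 1] for c in codes]


def softmax(Q: np.ndarray) -> np.ndarray:
    """Row softmax with max subtraction for numerical stability."""
    z = Q - Q.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def module_scores(
    module: GSBNModuleParams,
    H: HarmonizedExpression,
    background: BackgroundMap,
    mode: str = "infer",
    allow_empty: bool = True,
) -> np.ndarray:
    """Normalized C x 2M enrichment-score matrix for one module."""
    W_B = binarize(module.W)
    S = W_B.sum(axis=0)
    if (S == 0).any():
        if not allow_empty:
            raise ValueError("module contains empty gene sets")
        warnings.warn("module contains empty gene sets; their scores are constant",
                      stacklevel=2)
    tau = compute_tau(module.tau_m, S)
    T = trim_ranks(H.R, tau)
    U = ucell_score(T, W_B, tau, allow_empty=True)
    A = ams_score(H.L, W_B, background, allow_empty=True)
    K = np.concatenate([U, A], axis=1)
    return normalize_scores(K, module.norm_stats, mode)


def core_forward(
    model: CoreModel,
    H: HarmonizedExpression,
    mode: str = "infer",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, PotencyPrediction]:
    """Run the core model, returning logits ``Q`` and a prediction.

    In train mode, dropout with the configured rate is applied to the
    normalized scores (requires ``rng``); inference is deterministic.
    """
    if H.n_features != model.n_features:
        raise ValueError(
            f"expression has {H.n_features} features but model expects {model.n_features}"
        )
    q_cols = []
    for module in model.modules:
        K_norm = module_scores(module, H, model.background, mode=mode)
        if mode == "train" and model.dropout_rate > 0:
            if rng is None:
                raise ValueError("train-mode dropout requires an rng")
            keep = rng.random(K_norm.shape) >= model.dropout_rate
            K_norm = K_norm * keep / (1.0 - model.dropout_rate)
        q_cols.append(K_norm @ module.V + module.bias)
    Q = np.column_stack(q_cols)
    P = softmax(Q)
    y_hat = np.argmax(P, axis=1) + 1
    RPS = P @ model.t_vec
    return Q, PotencyPrediction(P=P, y_hat=y_hat, RPS=RPS, cell_ids=list(H.cell_ids))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def save_model(path, model: CoreModel, extra_meta: dict | None = None) -> None:
    """Serialize a model as a zip archive of JSON metadata + npy arrays."""
    meta = {
        "schema_version": SCHEMA_VERSION,
        "n_modules": len(model.modules),
        "dropout_rate": model.dropout_rate,
        "t_vec": model.t_vec.tolist(),
        "feature_list": model.feature_list,
        "background": {
            "n_bins": model.background.n_bins,
            "n_sample": model.background.n_sample,
            "seed": model.background.seed,
        },
        "tau_m": [float(m.tau_m) for m in model.modules],
        "bias": [float(m.bias) for m in model.modules],
        "norm_fitted": [bool(m.norm_stats.fitted) for m in model.modules],
    }
    if extra_meta:
        meta["extra"] = extra_meta
    arrays: dict[str, np.ndarray] = {}
    for i, m in enumerate(model.modules):
        arrays[f"W_{i}"] = m.W
        arrays[f"V_{i}"] = m.V
        arrays[f"norm_mean_{i}"] = m.norm_stats.mean
        arrays[f"norm_var_{i}"] = m.norm_stats.var
    coo = model.background.B.tocoo()
    arrays["bg_row"] = coo.row
    arrays["bg_col"] = coo.col
    arrays["bg_shape"] = np.array(coo.shape)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for name, arr in arrays.items():
            buf = _io.BytesIO()
            np.save(buf, arr)
            zf.writestr(name + ".npy", buf.getvalue())


def load_model(path) -> CoreModel:
    """Load a model archive written by :func:`save_model`."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["schema_version"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {meta['schema_version']}")

        def arr(name):
            return np.load(_io.BytesIO(zf.read(name + ".npy")))

        modules = []
        for i in range(meta["n_modules"]):
            stats = NormStats(
                mean=arr(f"norm_mean_{i}"),
                var=arr(f"norm_var_{i}"),
                fitted=meta["norm_fitted"][i],
            )
            modules.append(
                GSBNModuleParams(
                    W=arr(f"W_{i}"),
                    tau_m=meta["tau_m"][i],
                    V=arr(f"V_{i}"),
                    bias=meta["bias"][i],
                    norm_stats=stats,
                )
            )
        shape = tuple(arr("bg_shape"))
        B = sparse.csr_matrix(
            (np.ones(arr("bg_row").size), (arr("bg_row"), arr("bg_col"))), shape=shape
        )
        background = BackgroundMap(B=B, **meta["background"])
    return CoreModel(
        modules=modules,
        background=background,
        dropout_rate=meta["dropout_rate"],
        feature_list=meta["feature_list"],
        t_vec=np.asarray(meta["t_vec"]),
    )
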