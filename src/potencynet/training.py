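"""GSBN training: loss, hierarchical weighting, STE backprop, ensembling.

The loss is ``J = J_S + sum_w v_w CE_w``: a weighted softmax cross-entropy
over the six category logits plus a gene-set-size penalty ``J_S`` that is
invariant to the number of gene sets per module.  Cell weights ``v`` are
hierarchical — equal total mass per broad category, per phenotype within
a category, and per dataset within a phenotype — and the batch sampler
draws cells with replacement proportionally to those weights.

Continuous gene-set weights ``W`` are binarized in the forward pass; the
backward pass uses a straight-through estimator with a hardtanh window
(gradients pass where ``|W| <= 1``).  The optimizer is NAdam with
persistent state across epochs, which damps binary bit flipping.  Early
stopping keeps the checkpoint with the best hierarchical weighted accuracy
on a held-out validation set after a minimum number of epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from . import autodiff as ad
from .constants import CATEGORIES, N_CATEGORIES, category_codes
from .gsbn import (
    BN_EPS,
    BackgroundMap,
    CoreModel,
    GSBNModuleParams,
    PotencyPrediction,
    build_background_map,
    core_forward,
    softmax,
)
from .io import HarmonizedExpression


# ---------------------------------------------------------------------------
# hyperparameters
# ---------------------------------------------------------------------------

@dataclass
class Hyperparameters:
    """Training hyperparameters with their selected defaults."""

    M: int = 24                     # gene sets per potency category
    rho: float = 0.5                # dropout on normalized scores
    lam: float = 0.01               # gene-set-size penalty weight
    lr: float = 0.001               # NAdam learning rate
    batch_size: int = 1024
    max_epochs: int = 100
    min_epochs_before_stop: int = 15
    init_mean: float = -0.1         # Gaussian init of continuous weights
    init_sd: float = 0.055
    n_bins: int = 24                # background-map expression bins
    n_sample: int = 100             # background genes per gene (mean)

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        for name in ("M", "lr", "batch_size", "max_epochs", "init_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# loss components
# ---------------------------------------------------------------------------

def hierarchical_loss_weights(labels: pd.DataFrame) -> np.ndarray:
    """Per-cell loss weights with equal mass per category/phenotype/dataset.

    ``weight = 1 / (n_categories * n_phenotypes_in_category *
    n_datasets_of_phenotype * n_cells_in_phenotype_dataset)``; the vector
    sums to 1.
    """
    for col in ("broad_category", "phenotype", "dataset"):
        if col not in labels.columns:
            raise ValueError(f"label table needs column '{col}'")
    cat = labels["broad_category"].to_numpy()
    phen = labels["phenotype"].astype(str).to_numpy()
    ds = labels["dataset"].astype(str).to_numpy()

    n_cat = len(pd.unique(cat))
    phen_per_cat = pd.DataFrame({"c": cat, "p": phen}).groupby("c")["p"].nunique()
    ds_per_phen = pd.DataFrame({"p": phen, "d": ds}).groupby("p")["d"].nunique()
    cells_per_pd = pd.DataFrame({"p": phen, "d": ds}).groupby(["p", "d"]).size()

    w = np.empty(len(labels))
    for i, (c, p, d) in enumerate(zip(cat, phen, ds)):
        w[i] = 1.0 / (n_cat * phen_per_cat[c] * ds_per_phen[p] * cells_per_pd[(p, d)])
    return w


def prediction_loss(Q: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    """Weighted cross-entropy ``sum_w v_w CE_w`` from logits.

    ``Q`` is C x 6 logits, ``y`` category codes in 1..6, ``v`` per-cell
    weights.  Computed with the log-sum-exp form.
    """
    y = np.asarray(y, dtype=int)
    if ((y < 1) | (y > N_CATEGORIES)).any():
        raise ValueError(f"category codes must lie in 1..{N_CATEGORIES}")
    Q = np.asarray(Q, dtype=float)
    zmax = Q.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(Q - zmax).sum(axis=1))
    ce = lse - Q[np.arange(len(y)), y - 1]
    return float(np.dot(np.asarray(v, dtype=float), ce))


def gene_set_size_penalty(W_B_list, lam: float, M: int, N: int) -> float:
    """Size penalty ``J_S = a * lam * sum_p ||S_p / N||_2`` with ``a = sqrt(12/M)``.

    The diagonal of the scaled Gram matrix of a binary weight matrix holds
    the relative gene-set sizes ``S_j / N``, so the Frobenius norm of that
    diagonal is the Euclidean norm of the size vector.
    """
    a = np.sqrt(12.0 / M)
    total = 0.0
    for W_B in W_B_list:
        S = np.asarray(W_B, dtype=float).sum(axis=0)
        total += float(np.sqrt(np.sum((S / N) ** 2)))
    return a * lam * total


def ste_backward(grad_wrt_W_B: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Straight-through gradient: pass where ``|W| <= 1``, zero outside."""
    return np.asarray(grad_wrt_W_B) * (np.abs(np.asarray(W)) <= 1.0)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize_gene_set_weights(
    hp: Hyperparameters, n_features: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw the continuous N x M weight matrix of one module.

    Entries are i.i.d. Normal(init_mean, init_sd^2); with the defaults the
    positive fraction is about 3.5%, i.e. roughly 500 genes per set on a
    14,271-gene feature space.
    """
    return rng.normal(hp.init_mean, hp.init_sd, size=(n_features, hp.M))


def initialize_model(
    hp: Hyperparameters,
    n_features: int,
    seed: int,
    background: BackgroundMap,
    feature_list: list[str] | None = None,
) -> CoreModel:
    """Seed-reproducible model initialization.

    Gene-set weights follow the sparse Gaussian scheme; ``tau_m`` is
    uniform on [0, 1]; enrichment-layer weights use the standard uniform
    fan-in scheme and the per-module bias starts at zero.
    """
    rng = np.random.default_rng(seed)
    modules = []
    bound = 1.0 / np.sqrt(2 * hp.M)
    for _ in range(N_CATEGORIES):
        modules.append(
            GSBNModuleParams(
                W=initialize_gene_set_weights(hp, n_features, rng),
                tau_m=float(rng.uniform(0.0, 1.0)),
                V=rng.uniform(-bound, bound, size=2 * hp.M),
                bias=0.0,
            )
        )
    return CoreModel(
        modules=modules,
        background=background,
        dropout_rate=hp.rho,
        feature_list=feature_list,
    )


# ---------------------------------------------------------------------------
# batch sampling
# ---------------------------------------------------------------------------

def make_sampler(labels: pd.DataFrame, batch_size: int, seed: int):
    """Yield batches of cell indices, sampled with replacement.

    Sampling probabilities are proportional to the hierarchical loss
    weights, balancing categories, phenotypes and datasets.  One epoch
    yields ``ceil(C / batch_size)`` batches; the sequence is a pure
    function of the seed.
    """
    weights = hierarchical_loss_weights(labels)
    probs = weights / weights.sum()
    n = len(labels)
    per_epoch = max(1, int(np.ceil(n / batch_size)))
    rng = np.random.default_rng(seed)

    def epoch():
        for _ in range(per_epoch):
            yield rng.choice(n, size=min(batch_size, n), replace=True, p=probs)

    return epoch


# ---------------------------------------------------------------------------
# validation metric
# ---------------------------------------------------------------------------

def weighted_accuracy(pred_codes: np.ndarray, labels: pd.DataFrame) -> float:
    """Hierarchically averaged F1 used for early stopping.

    F1 is computed per (phenotype, dataset) group against that group's
    true category, then averaged across datasets per phenotype, across
    phenotypes per category, and across categories.
    """
    pred = np.asarray(pred_codes, dtype=int)
    truth = category_codes(labels["broad_category"])
    phen = labels["phenotype"].astype(str).to_numpy()
    ds = labels["dataset"].astype(str).to_numpy()

    df = pd.DataFrame({"truth": truth, "pred": pred, "phen": phen, "ds": ds})
    cat_scores = []
    for _, cat_group in df.groupby(df["truth"]):
        phen_scores = []
        for _, phen_group in cat_group.groupby("phen"):
            ds_scores = []
            for _, g in phen_group.groupby("ds"):
                target = int(g["truth"].iloc[0])
                _, _, f1, _ = precision_recall_fscore_support(
                    g["truth"], g["pred"], labels=[target], average=None,
                    zero_division=0,
                )
                ds_scores.append(float(f1[0]))
            phen_scores.append(float(np.mean(ds_scores)))
        cat_scores.append(float(np.mean(phen_scores)))
    if not cat_scores:
        raise ValueError("no evaluable potency categories")
    return float(np.mean(cat_scores))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class NAdam:
    """NAdam with the standard decaying Nesterov momentum schedule.

    Defaults: betas (0.9, 0.999), eps 1e-8, momentum decay 0.004.  State
    persists for the lifetime of the object, which training exploits to
    keep momentum across epochs.
    """

    def __init__(self, lr=0.001, betas=(0.9, 0.999), eps=1e-8, momentum_decay=0.004):
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.psi = momentum_decay
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None
        self.mu_product = 1.0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        t = self.t
        mu_t = self.beta1 * (1 - 0.5 * 0.96 ** (t * self.psi))
        mu_next = self.beta1 * (1 - 0.5 * 0.96 ** ((t + 1) * self.psi))
        self.mu_product *= mu_t
        bias2 = 1 - self.beta2**t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            denom = np.sqrt(v / bias2) + self.eps
            p -= self.lr * (
                (1 - mu_t) * g / (1 - self.mu_product)
                + mu_next * m / (1 - self.mu_product * mu_next)
            ) / denom


# ---------------------------------------------------------------------------
# training graph
# ---------------------------------------------------------------------------

class _ModuleTensors:
    """Parameter tensors of one module for a single batch graph."""

    def __init__(self, module: GSBNModuleParams):
        self.module = module
        self.W = ad.Tensor(module.W)
        self.tau_m = ad.Tensor(np.asarray(float(module.tau_m)))
        self.V = ad.Tensor(module.V)
        self.bias = ad.Tensor(np.asarray(float(module.bias)))

    def params(self):
        return [self.W, self.tau_m, self.V, self.bias]


def _module_logit(
    mt: _ModuleTensors,
    Rb: np.ndarray,
    Lb: np.ndarray,
    background: BackgroundMap,
    rho: float,
    rng: np.random.Generator | None,
):
    """Build the autodiff graph of one module; returns (logit, set_sizes)."""
    n_cells, n_features = Rb.shape
    WB = ad.binarize_ste(mt.W)
    S = ad.tsum(WB, axis=0)
    S_safe = ad.maximum(S, 1.0)
    tau = ad.round_ste(10.0 + ad.tmax(S) + 1000.0 * ad.relu(mt.tau_m))

    T = ad.minimum(ad.Tensor(Rb), tau)
    rank_sums = ad.matmul(T, WB)
    U = 1.0 + (S * (S + 1.0) - 2.0 * rank_sums) / (2.0 * tau * S_safe)

    Lb_t = ad.Tensor(Lb)
    set_mean = ad.matmul(Lb_t, WB) / S_safe
    BW = ad.sparse_matmul(background.set_to_background, WB)
    bg_totals = ad.maximum(ad.tsum(BW, axis=0), 1.0)
    A = set_mean - ad.matmul(Lb_t, BW) / bg_totals

    K = ad.concat([U, A], axis=1)
    mu = ad.tsum(K, axis=0) * (1.0 / n_cells)
    centered = K - mu
    var = ad.tsum(ad.square(centered), axis=0) * (1.0 / n_cells)
    K_norm = centered / ad.sqrt(var + BN_EPS)
    # running stats track the batch moments (unbiased variance)
    mt.module.norm_stats.update(
        mu.value, var.value * n_cells / max(n_cells - 1, 1)
    )
    if rho > 0:
        keep = (rng.random(K_norm.shape) >= rho) / (1.0 - rho)
        K_norm = K_norm * ad.Tensor(keep)
    logit = ad.matmul(K_norm, mt.V) + mt.bias
    return logit, S


def _batch_loss(
    module_tensors: list[_ModuleTensors],
    Rb: np.ndarray,
    Lb: np.ndarray,
    y0: np.ndarray,
    v: np.ndarray,
    hp: Hyperparameters,
    background: BackgroundMap,
    rng: np.random.Generator,
) -> ad.Tensor:
    n_cells, n_features = Rb.shape
    logits, penalty = [], None
    a = np.sqrt(12.0 / hp.M)
    for mt in module_tensors:
        logit, S = _module_logit(mt, Rb, Lb, background, hp.rho, rng)
        logits.append(ad.reshape(logit, (n_cells, 1)))
        norm = ad.sqrt(ad.tsum(ad.square(S * (1.0 / n_features))) + 1e-12)
        penalty = norm if penalty is None else penalty + norm
    Q = ad.concat(logits, axis=1)
    ce = ad.weighted_cross_entropy(Q, y0, v / v.sum())
    return ce + (a * hp.lam) * penalty


def train_model(
    train_data: tuple[HarmonizedExpression, pd.DataFrame],
    val_data: tuple[HarmonizedExpression, pd.DataFrame],
    hp: Hyperparameters | None = None,
    seed: int = 0,
    background: BackgroundMap | None = None,
    verbose: bool = False,
) -> CoreModel:
    """Train a single GSBN model and return the best validation checkpoint.

    The background map, when not supplied, is built from the mean
    log-expression of the training corpus.  Training runs for
    ``hp.max_epochs`` epochs; the returned checkpoint is the one with the
    highest hierarchical weighted accuracy on ``val_data`` reached at or
    after ``hp.min_epochs_before_stop`` epochs.  Fully deterministic given
    ``seed`` and the data.
    """
    hp = hp or Hyperparameters()
    H_train, labels_train = train_data
    H_val, labels_val = val_data
    if len(labels_train) == 0 or len(labels_val) == 0:
        raise ValueError("both training and validation splits must be nonempty")

    if background is None:
        background = build_background_map(
            H_train.L.mean(axis=1), n_bins=hp.n_bins, n_sample=hp.n_sample, seed=seed
        )
    model = initialize_model(
        hp, H_train.n_features, seed, background, feature_list=H_train.feature_list
    )

    Rt = np.asarray(H_train.R, dtype=float).T  # cells x genes
    Lt = np.asarray(H_train.L, dtype=float).T
    y = category_codes(labels_train["broad_category"])
    v_all = hierarchical_loss_weights(labels_train)

    sampler = make_sampler(labels_train, hp.batch_size, seed)
    dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    optimizer = NAdam(lr=hp.lr)

    best_acc, best_model = -np.inf, None
    min_epoch = min(hp.min_epochs_before_stop, hp.max_epochs)
    history = []
    for epoch in range(1, hp.max_epochs + 1):
        for idx in sampler():
            mts = [_ModuleTensors(m) for m in model.modules]
            loss = _batch_loss(
                mts, Rt[idx], Lt[idx], y[idx] - 1, v_all[idx], hp,
                background, dropout_rng,
            )
            if not np.isfinite(loss.value):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.value!r}"
                )
            loss.backward()
            params = [p.value for mt in mts for p in mt.params()]
            grads = [p.grad for mt in mts for p in mt.params()]
            optimizer.step(params, grads)
            for mt in mts:
                mt.module.W = mt.W.value
                mt.module.tau_m = float(mt.tau_m.value)
                mt.module.V = mt.V.value
                mt.module.bias = float(mt.bias.value)
        _, pred = core_forward(model, H_val, mode="infer")
        acc = weighted_accuracy(pred.y_hat, labels_val)
        history.append((epoch, float(loss.value), acc))
        if verbose:
            print(f"epoch {epoch:3d}  loss {loss.value:.4f}  val weighted acc {acc:.4f}")
        if epoch >= min_epoch and acc > best_acc:
            best_acc, best_model = acc, model.copy()
    result = best_model if best_model is not None else model.copy()
    result.training_history = history
    return result


# ---------------------------------------------------------------------------
# ensembling
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """A set of GSBN models aggregated by entrywise averaging of P."""

    members: list[CoreModel] = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        n = self.members[0].n_features
        for m in self.members[1:]:
            if m.n_features != n:
                raise ValueError("ensemble members disagree on feature space")
            if not np.array_equal(m.t_vec, self.members[0].t_vec):
                raise ValueError("ensemble members disagree on category order")

    @property
    def n_features(self) -> int:
        return self.members[0].n_features


def ensemble_predict(
    models: EnsembleModel | list[CoreModel], H: HarmonizedExpression
) -> PotencyPrediction:
    """Average member likelihood matrices and rederive category and RPS."""
    if isinstance(models, EnsembleModel):
        members = models.members
    else:
        members = list(models)
        EnsembleModel(members=members)  # validation only
    P = np.mean([core_forward(m, H, mode="infer")[1].P for m in members], axis=0)
    y_hat = np.argmax(P, axis=1) + 1
    RPS = P @ members[0].t_vec
    return PotencyPrediction(P=P, y_hat=y_hat, RPS=RPS, cell_ids=list(H.cell_ids))
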