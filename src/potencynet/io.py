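"""Expression and label I/O, gene harmonization and dual representations.

The model consumes a genes x cells expression matrix mapped onto a fixed
harmonized feature space of N gene symbols, in two parallel encodings:

* ``L`` — log2(1 + CPM/TPM), retaining quantitative detail;
* ``R`` — within-cell integer ranks (rank 1 = highest expression), a
  batch-robust encoding.

Gene symbols are harmonized through a :class:`GeneDictionary` built from a
human-mouse ortholog table: each human gene is paired with its closest
mouse ortholog by sequence similarity; when several human genes share the
same best-hit mouse gene, only the most similar human gene is kept; human
genes without an ortholog are retained as singleton features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .constants import CATEGORIES, category_code

LABEL_COLUMNS = ("cell_id", "broad_category", "granular_level", "phenotype", "dataset")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawExpression:
    """A genes x cells non-negative expression matrix with identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    is_counts: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if (self.values < 0).any():
            raise ValueError("expression matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneDictionary:
    """Fixed harmonized feature space and symbol mappings onto it."""

    feature_list: list[str]
    human_to_feature: dict[str, str]
    mouse_to_feature: dict[str, str]
    alias_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.feature_list)) != len(self.feature_list):
            raise ValueError("feature_list contains duplicates")
        features = set(self.feature_list)
        for mapping in (self.human_to_feature, self.mouse_to_feature):
            bad = set(mapping.values()) - features
            if bad:
                raise ValueError(f"mapping targets not in feature_list: {sorted(bad)[:5]}")

    @property
    def n_features(self) -> int:
        return len(self.feature_list)

    def mapping_for(self, species: str) -> dict[str, str]:
        if species == "human":
            return self.human_to_feature
        if species == "mouse":
            return self.mouse_to_feature
        raise ValueError("species must be 'human' or 'mouse'")


@dataclass
class HarmonizedExpression:
    """Dual log/rank representation on the fixed feature space.

    ``L`` holds log2(1 + CPM/TPM) values and ``R`` within-cell integer
    ranks, both N x C with features in dictionary order.
    """

    L: np.ndarray
    R: np.ndarray
    cell_ids: list[str]
    feature_list: list[str] | None = None

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        self.R = np.asarray(self.R)
        if self.L.shape != self.R.shape:
            raise ValueError("L and R must share a shape")
        if (self.L < 0).any():
            raise ValueError("L must be non-negative")

    @property
    def n_features(self) -> int:
        return self.L.shape[0]

    @property
    def n_cells(self) -> int:
        return self.L.shape[1]


def validate_labels(labels: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-cell label table and return it with ordered categories.

    Required columns: ``cell_id`` and ``broad_category``; optional:
    ``granular_level``, ``phenotype``, ``dataset``, ``relative_order``.
    """
    if "cell_id" not in labels.columns or "broad_category" not in labels.columns:
        raise ValueError("label table needs 'cell_id' and 'broad_category' columns")
    bad = set(labels["broad_category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown potency categories: {sorted(bad)}")
    return labels


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_expression(path, fmt: str = "auto", is_counts: bool = True) -> RawExpression:
    """Read an expression matrix from disk.

    Supported formats: ``"mtx"`` — Matrix Market coordinate file with
    ``genes.tsv`` / ``barcodes.tsv`` sidecars in the same directory — and
    ``"dense"`` — TSV/CSV with a header row of cell ids and gene symbols in
    the first column.  Duplicate gene symbols are collapsed by summation.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "mtx" if path.suffix == ".mtx" else "dense"
    if fmt == "mtx":
        mat = spio.mmread(path)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(path.parent / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        if values.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {values.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} barcodes)"
            )
    elif fmt == "dense":
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'mtx' or 'dense'")
    if np.asarray(values < 0).any():
        raise ValueError(f"negative expression values in {path}")
    return collapse_duplicate_genes(
        RawExpression(values, genes, cells, is_counts=is_counts)
    )


def write_expression(path, expr: RawExpression, fmt: str = "auto") -> None:
    """Write an expression matrix as Matrix Market + sidecars or dense TSV."""
    path = Path(path)
    if fmt == "auto":
        fmt = "mtx" if path.suffix == ".mtx" else "dense"
    if fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(expr.values))
        pd.Series(expr.gene_ids).to_csv(
            path.parent / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(expr.cell_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", header=False, index=False
        )
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids).to_csv(
            path, sep=sep
        )


def load_labels(path) -> pd.DataFrame:
    """Read a per-cell label TSV and validate it."""
    return validate_labels(pd.read_csv(path, sep="\t", dtype={"cell_id": str}))


def write_labels(path, labels: pd.DataFrame) -> None:
    labels.to_csv(path, sep="\t", index=False)


def collapse_duplicate_genes(expr: RawExpression) -> RawExpression:
    """Sum rows sharing a gene symbol (keeps first-occurrence order)."""
    if len(set(expr.gene_ids)) == len(expr.gene_ids):
        return expr
    order: dict[str, int] = {}
    for g in expr.gene_ids:
        order.setdefault(g, len(order))
    out = np.zeros((len(order), expr.n_cells))
    for row, g in zip(expr.values, expr.gene_ids):
        out[order[g]] += row
    return RawExpression(out, list(order), expr.cell_ids, is_counts=expr.is_counts)


# ---------------------------------------------------------------------------
# dictionary construction and harmonization
# ---------------------------------------------------------------------------

def build_dictionary(
    ortholog_table: pd.DataFrame, alias_map: dict[str, str] | None = None
) -> GeneDictionary:
    """Build a harmonized feature space from a human-mouse ortholog table.

    ``ortholog_table`` has columns ``human_symbol``, ``mouse_symbol`` and
    ``similarity``; ``mouse_symbol`` may be missing/NaN for human genes
    without an ortholog, which become singleton features.  When several
    human genes best-hit the same mouse gene, only the human gene with the
    highest similarity is kept (ties broken alphabetically for
    determinism).  Features are named by the mouse symbol of a pair and by
    the human symbol for singletons, and listed in sorted order.
    """
    df = ortholog_table.copy()
    required = {"human_symbol", "mouse_symbol", "similarity"}
    if not required.issubset(df.columns):
        raise ValueError(f"ortholog table must have columns {sorted(required)}")

    paired = df[df["mouse_symbol"].notna() & (df["mouse_symbol"] != "")]
    dup = paired.groupby(["human_symbol", "mouse_symbol"])["similarity"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()[:3]
        raise ValueError(f"conflicting similarity for duplicated pairs: {bad}")
    paired = paired.drop_duplicates(["human_symbol", "mouse_symbol"])

    # one human gene per mouse best hit: keep max similarity, tie -> alphabetical
    paired = paired.sort_values(
        ["mouse_symbol", "similarity", "human_symbol"],
        ascending=[True, False, True],
    ).drop_duplicates("mouse_symbol", keep="first")

    human_to_feature: dict[str, str] = {}
    mouse_to_feature: dict[str, str] = {}
    features: list[str] = []
    for h, m in zip(paired["human_symbol"], paired["mouse_symbol"]):
        features.append(str(m))
        human_to_feature[str(h)] = str(m)
        mouse_to_feature[str(m)] = str(m)

    paired_humans = set(paired["human_symbol"])
    singles = df[df["mouse_symbol"].isna() | (df["mouse_symbol"] == "")]
    for h in sorted(set(singles["human_symbol"]) - paired_humans):
        h = str(h)
        if h in mouse_to_feature:  # name collision with a mouse symbol
            continue
        features.append(h)
        human_to_feature[h] = h

    return GeneDictionary(
        feature_list=sorted(set(features)),
        human_to_feature=human_to_feature,
        mouse_to_feature=mouse_to_feature,
        alias_map=dict(alias_map or {}),
    )


def harmonize(expr: RawExpression, dictionary: GeneDictionary, species: str) -> np.ndarray:
    """Map an expression matrix onto the fixed N-feature space.

    Aliases are resolved first, then species-specific symbols are looked up
    in the dictionary.  Features absent from the input become all-zero
    rows; input genes absent from the dictionary are dropped; several input
    genes mapping to one feature are summed.
    """
    mapping = dictionary.mapping_for(species)
    feature_index = {f: i for i, f in enumerate(dictionary.feature_list)}
    out = np.zeros((dictionary.n_features, expr.n_cells))
    n_hit = 0
    for row, gene in zip(expr.values, expr.gene_ids):
        gene = dictionary.alias_map.get(gene, gene)
        feat = mapping.get(gene)
        if feat is not None:
            out[feature_index[feat]] += row
            n_hit += 1
    if n_hit == 0:
        raise ValueError(
            f"no overlap between the {expr.n_genes} input genes and the "
            f"{dictionary.n_features}-feature dictionary ({species} mapping); "
            "check species and gene identifiers"
        )
    if n_hit < 0.25 * dictionary.n_features:
        warnings.warn(
            f"only {n_hit}/{dictionary.n_features} dictionary features matched",
            stacklevel=2,
        )
    return out


def dual_representation(
    matrix: np.ndarray,
    cell_ids,
    is_counts: bool = True,
    feature_list: list[str] | None = None,
) -> HarmonizedExpression:
    """Build the log/rank dual encoding of a harmonized N x C matrix.

    ``L`` scales each cell to a total of 1e6 (CPM/TPM) and applies
    log2(x + 1).  ``R`` assigns ordinal within-cell ranks with rank 1 for
    the highest expression; ties (including the all-zero tail) are broken
    by ascending feature index so columns are exact permutations of 1..N.
    """
    matrix = np.asarray(matrix, dtype=float)
    if (matrix < 0).any():
        raise ValueError("expression must be non-negative")
    totals = matrix.sum(axis=0)
    zero_cells = np.where(totals == 0)[0]
    if zero_cells.size:
        ids = [cell_ids[i] for i in zero_cells[:10]]
        raise ValueError(f"all-zero cells cannot be normalized: {ids}")
    scaled = matrix / totals * 1e6
    L = np.log2(scaled + 1.0)
    # stable argsort of descending expression -> ties by ascending gene index
    order = np.argsort(-matrix, axis=0, kind="stable")
    R = np.empty(matrix.shape, dtype=np.int64)
    ranks = np.arange(1, matrix.shape[0] + 1)[:, None]
    np.put_along_axis(R, order, np.broadcast_to(ranks, matrix.shape), axis=0)
    return HarmonizedExpression(L=L, R=R, cell_ids=list(cell_ids), feature_list=feature_list)


def preprocess(
    expr: RawExpression, dictionary: GeneDictionary, species: str
) -> HarmonizedExpression:
    """Harmonize onto the dictionary feature space and build L and R."""
    mat = harmonize(expr, dictionary, species)
    return dual_representation(
        mat, expr.cell_ids, is_counts=expr.is_counts, feature_list=dictionary.feature_list
    )
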