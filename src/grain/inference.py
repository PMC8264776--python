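"""Single-algorithm network inference engines and the top-K edge filter.

Five engines score directed TF -> target edges from an expression
matrix:

* ``pcc`` / ``scc`` — absolute Pearson / Spearman correlation;
* ``clr`` — mutual information rescaled against each gene's background
  MI distribution (z-score combination), which attenuates promiscuous
  high-MI genes;
* ``aracne`` — mutual information pruned by the data processing
  inequality: in every connected triplet the weakest edge is deemed
  indirect and removed;
* ``genie3`` — per-target random-forest regression whose feature
  importances score directed regulator -> target edges.

All engines share one candidate edge space (ordered TF -> gene pairs
over all genes; symmetric scores are emitted in both orientations for
TF–TF pairs) so their outputs can be aligned by the consensus stage.
Mutual information uses equal-width binning with the plug-in
(maximum-likelihood) entropy estimator in log base 2; the default bin
count is ceil(sqrt(n_samples)).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor

from .errors import ValidationError
from .types import ExpressionMatrix, RankedEdgeList, RegulatorSet

logger = logging.getLogger(__name__)


# -- discretization and mutual information ------------------------------------

def discretize(profile: Sequence[float], n_bins: int) -> np.ndarray:
    """Equal-width binning of a profile into integer codes 0..n_bins-1.

    Bins span [min, max]; interior edges are right-closed so a value on
    an edge falls in the lower bin, and the last bin includes the max.
    A constant profile maps entirely to bin 0.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    x = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("profile contains non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(len(x), dtype=np.int64)
    edges = np.linspace(lo, hi, n_bins + 1)[1:-1]
    return np.digitize(x, edges, right=True).astype(np.int64)


def default_bins(n_samples: int) -> int:
    return max(2, math.ceil(math.sqrt(n_samples)))


def mutual_information(x: Sequence[int], y: Sequence[int]) -> float:
    """Plug-in MI (bits) from the empirical joint distribution of two
    integer-coded vectors."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if x.size < 2:
        raise ValidationError("vectors must have length >= 2")
    nx, ny = int(x.max()) + 1, int(y.max()) + 1
    joint = np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny) / x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    denom = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / denom[nz])))


def _discretize_matrix(values: np.ndarray, n_bins: int) -> np.ndarray:
    return np.vstack([discretize(row, n_bins) for row in values])


def mi_matrix(expr: ExpressionMatrix, n_bins: int | None = None) -> pd.DataFrame:
    """Symmetric gene x gene mutual-information matrix in bits.

    The diagonal holds each gene's marginal entropy (MI of a profile
    with itself). Computed by one-hot encoding the binned profiles and
    accumulating all pairwise joint histograms with a single matrix
    product.
    """
    nb = n_bins or default_bins(expr.n_samples)
    vals = expr.values.to_numpy()
    codes = _discretize_matrix(vals, nb)
    n_genes, n_samples = codes.shape
    # one-hot: (n_genes * nb) x n_samples
    onehot = np.zeros((n_genes * nb, n_samples))
    rows = (np.arange(n_genes)[:, None] * nb + codes).ravel()
    cols = np.tile(np.arange(n_samples), n_genes)
    onehot[rows, cols] = 1.0
    joint = (onehot @ onehot.T) / n_samples  # (G*nb) x (G*nb) block matrix
    blocks = joint.reshape(n_genes, nb, n_genes, nb)
    p_marg = np.stack(
        [np.bincount(c, minlength=nb) / n_samples for c in codes]
    )  # G x nb

    mi = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        pj = blocks[i]  # pj[a, g, b] = p(x_i = a, x_g = b)
        denom = p_marg[i][:, None, None] * p_marg[None, :, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(
                pj > 0, pj * np.log2(np.where(pj > 0, pj, 1.0) / np.where(denom > 0, denom, 1.0)), 0.0
            )
        mi[i] = term.sum(axis=(0, 2))
    mi = 0.5 * (mi + mi.T)  # exact symmetry against float noise
    mi[mi < 0] = 0.0
    return pd.DataFrame(mi, index=expr.gene_ids, columns=expr.gene_ids)


# -- edge assembly helpers ----------------------------------------------------

def _edge_frame(scored: Iterable[tuple[str, str, float]]) -> pd.DataFrame:
    df = pd.DataFrame(scored, columns=["regulator", "target", "score"])
    return df


def top_k_filter(scored: pd.DataFrame | Iterable[tuple[str, str, float]],
                 k: int, method: str = "unknown") -> RankedEdgeList:
    """Keep the K highest-scoring edges with dense ranks 1..K.

    Ties are broken by (regulator, target) lexicographic order so ranks
    are reproducible. If fewer than K edges exist, all are retained.
    """
    if k < 1:
        raise ValidationError("top_k must be >= 1")
    df = scored if isinstance(scored, pd.DataFrame) else _edge_frame(scored)
    df = df.sort_values(
        ["score", "regulator", "target"], ascending=[False, True, True],
        kind="mergesort",
    ).head(k).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return RankedEdgeList(method=method, edges=df)


def _symmetric_edges(score: pd.DataFrame, tfs: RegulatorSet) -> pd.DataFrame:
    """Expand a symmetric gene x gene score matrix into the shared
    directed edge universe: (tf, gene) for every gene != tf; a TF–TF
    pair therefore appears in both orientations with the same score."""
    genes = list(score.columns)
    tf_list = sorted(set(genes) & tfs.tf_ids)
    sub = score.loc[tf_list, genes]
    long = sub.reset_index(names="regulator").melt(
        id_vars="regulator", var_name="target", value_name="score"
    )
    long = long[long["regulator"] != long["target"]]
    return long.reset_index(drop=True)


def _check_inputs(expr: ExpressionMatrix, tfs: RegulatorSet) -> None:
    tfs.validate_against(expr)


# -- correlation engines ------------------------------------------------------

def infer_correlation(
    expr: ExpressionMatrix,
    tfs: RegulatorSet,
    flavor: str = "pearson",
    top_k: int = 500000,
    signed: bool = False,
) -> RankedEdgeList:
    """Correlation-based inference; score = |r| between TF and target
    profiles (Spearman = Pearson on average-tie ranks). Zero-variance
    profiles yield correlation 0. ``signed`` ranks by the signed value
    instead of the absolute value."""
    if flavor not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation flavor {flavor!r}")
    _check_inputs(expr, tfs)
    vals = expr.values.to_numpy(dtype=float)
    if flavor == "spearman":
        vals = np.vstack([rankdata(row, method="average") for row in vals])
    sd = vals.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.info("%d zero-variance profile(s); correlations set to 0",
                    int(flat.sum()))
    centered = vals - vals.mean(axis=1, keepdims=True)
    denom = np.where(flat, 1.0, sd * math.sqrt(vals.shape[1]))
    normed = centered / denom[:, None]
    corr = normed @ normed.T
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    score = pd.DataFrame(corr if signed else np.abs(corr),
                         index=expr.gene_ids, columns=expr.gene_ids)
    tag = "pcc" if flavor == "pearson" else "scc"
    return top_k_filter(_symmetric_edges(score, tfs), top_k, method=tag)


# -- CLR ----------------------------------------------------------------------

def infer_clr(
    expr: ExpressionMatrix,
    tfs: RegulatorSet,
    n_bins: int | None = None,
    top_k: int = 500000,
) -> RankedEdgeList:
    """Context-likelihood-of-relatedness scores.

    For edge (i, j), z_i = max(0, (MI_ij - mean_i) / sd_i) against gene
    i's background of MI values with all other genes (likewise z_j);
    score = sqrt(z_i^2 + z_j^2). A degenerate background (sd 0) sets
    that z to 0."""
    _check_inputs(expr, tfs)
    mi = mi_matrix(expr, n_bins).to_numpy()
    n = mi.shape[0]
    off = ~np.eye(n, dtype=bool)
    bg = np.where(off, mi, np.nan)
    mean = np.nanmean(bg, axis=1)
    sd = np.nanstd(bg, axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.info("%d gene(s) with degenerate MI background", int(degenerate.sum()))
    safe_sd = np.where(degenerate, 1.0, sd)
    z = (mi - mean[:, None]) / safe_sd[:, None]
    z = np.maximum(z, 0.0)
    z[degenerate, :] = 0.0
    score = np.sqrt(z**2 + z.T**2)
    score_df = pd.DataFrame(score, index=expr.gene_ids, columns=expr.gene_ids)
    return top_k_filter(_symmetric_edges(score_df, tfs), top_k, method="clr")


# -- ARACNe -------------------------------------------------------------------

def dpi_prune(mi: np.ndarray, tolerance: float = 0.0) -> np.ndarray:
    """Data-processing-inequality mask.

    Returns a boolean matrix marking surviving edges: an edge (i, j)
    with MI > 0 is removed when some third gene k (connected to both)
    satisfies MI_ij < min(MI_ik, MI_jk) * (1 - tolerance). Decisions
    are taken simultaneously on the unpruned matrix."""
    if tolerance < 0:
        raise ValidationError("dpi tolerance must be >= 0")
    m = np.array(mi, dtype=float)
    np.fill_diagonal(m, 0.0)
    n = m.shape[0]
    present = m > 0
    keep = present.copy()
    factor = 1.0 - tolerance
    for i in range(n):
        # bottleneck MI through every k: min(M_ik, M_jk), masked to k
        # adjacent to both i and j
        bottleneck = np.minimum(m[i][None, :], m)  # j x k
        connected = present[i][None, :] & present  # j x k
        bottleneck = np.where(connected, bottleneck, 0.0)
        best = bottleneck.max(axis=1)  # per j
        removal = present[i] & (m[i] < best * factor)
        keep[i, removal] = False
        keep[removal, i] = False
    return keep


def infer_aracne(
    expr: ExpressionMatrix,
    tfs: RegulatorSet,
    n_bins: int | None = None,
    dpi_tolerance: float = 0.0,
    top_k: int = 500000,
) -> RankedEdgeList:
    """MI network pruned by the data processing inequality; surviving
    TF–gene edges are scored by MI."""
    _check_inputs(expr, tfs)
    mi = mi_matrix(expr, n_bins)
    keep = dpi_prune(mi.to_numpy(), dpi_tolerance)
    pruned = mi.to_numpy() * keep
    score_df = pd.DataFrame(pruned, index=expr.gene_ids, columns=expr.gene_ids)
    long = _symmetric_edges(score_df, tfs)
    long = long[long["score"] > 0]
    return top_k_filter(long, top_k, method="aracne")


# -- GENIE3 -------------------------------------------------------------------

def infer_genie3(
    expr: ExpressionMatrix,
    tfs: RegulatorSet,
    n_trees: int = 1000,
    seed: int = 0,
    top_k: int = 500000,
) -> RankedEdgeList:
    """Tree-ensemble regression importance scores for directed edges.

    Each gene in turn is the regression target (standardized to unit
    variance) predicted from all candidate TF profiles (the target
    itself excluded). The importance of TF t for target g is the mean
    total variance reduction attributed to t across the forest's trees;
    edges are ranked globally. Random-feature subset size per split is
    ceil(sqrt(#candidates)). Zero-variance targets are skipped."""
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    _check_inputs(expr, tfs)
    genes = expr.gene_ids
    tf_list = sorted(set(genes) & tfs.tf_ids)
    vals = expr.values
    tf_mat = vals.loc[tf_list].to_numpy(dtype=float).T  # samples x TFs
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in
                   ss.spawn(len(genes))]
    scored: list[tuple[str, str, float]] = []
    for gi, gene in enumerate(genes):
        y = vals.loc[gene].to_numpy(dtype=float)
        sd = y.std()
        if sd == 0:
            logger.info("target %s has zero variance; skipped", gene)
            continue
        y = (y - y.mean()) / sd
        if gene in tf_list:
            cand_idx = [i for i, t in enumerate(tf_list) if t != gene]
        else:
            cand_idx = list(range(len(tf_list)))
        if not cand_idx:
            continue
        X = tf_mat[:, cand_idx]
        max_feat = min(len(cand_idx), max(1, math.ceil(math.sqrt(len(cand_idx)))))
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_feat,
            random_state=child_seeds[gi],
            n_jobs=1,
        )
        forest.fit(X, y)
        imp = np.zeros(len(cand_idx))
        for tree in forest.estimators_:
            imp += tree.tree_.compute_feature_importances(normalize=False)
        imp /= n_trees
        for ci, w in zip(cand_idx, imp):
            scored.append((tf_list[ci], gene, float(w)))
    return top_k_filter(_edge_frame(scored), top_k, method="genie3")


# -- dispatch -----------------------------------------------------------------

def infer(
    method: str,
    expr: ExpressionMatrix,
    tfs: RegulatorSet,
    top_k: int = 500000,
    n_bins: int | None = None,
    dpi_tolerance: float = 0.0,
    n_trees: int = 1000,
    seed: int = 0,
) -> RankedEdgeList:
    """Run one inference engine by method tag."""
    if method == "pcc":
        return infer_correlation(expr, tfs, "pearson", top_k)
    if method == "scc":
        return infer_correlation(expr, tfs, "spearman", top_k)
    if method == "clr":
        return infer_clr(expr, tfs, n_bins, top_k)
    if method == "aracne":
        return infer_aracne(expr, tfs, n_bins, dpi_tolerance, top_k)
    if method == "genie3":
        return infer_genie3(expr, tfs, n_trees, seed, top_k)
    raise ValidationError(f"unknown inference method {method!r}")
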