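"""Linear-margin classification of TFs from TF x module connectivity.

A linear-kernel SVM is trained on the TF x module Jaccard feature
matrix with binary labels (stress-positive vs negative TFs). Model
quality is measured by the area under the precision-recall curve
(AUC-PR) in repeated stratified cross-validation; two negative
controls re-train the classifier on randomly drawn pseudo-positives
(uniform, and matched to the positive class's family composition).

Each TF's final margin value D is averaged over the cross-validation
fold models that trained on it (all models for unlabeled TFs). TFs are
ranked by descending D, and the scaled score DS = 1 - (rank-1)/(N-1)
maps rank 1 to 1.0 and rank N to 0.0. Features are used raw (Jaccard
indices are already in [0, 1]) so hyperplane coefficients read
directly as module importances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ValidationError
from .types import LabelSet

logger = logging.getLogger(__name__)

_MAX_FOLD_REDRAWS = 100


def auc_pr(y_true, scores) -> float:
    """Area under the precision-recall curve by step integration.

    Thresholds sweep the distinct score values in descending order;
    AP = sum over thresholds of (R_k - R_{k-1}) * P_k.
    """
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("labels and scores must have equal length")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValidationError("AUC-PR undefined without positive examples")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    pred = np.arange(1, len(y) + 1)
    # keep only the last index of each tied score block
    last_of_block = np.append(s_sorted[1:] != s_sorted[:-1], True)
    tp_b = tp[last_of_block]
    pred_b = pred[last_of_block]
    precision = tp_b / pred_b
    recall = tp_b / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


@dataclass
class CVReport:
    """Per-run, per-fold AUC-PR of a cross-validated classifier."""

    fold_aucs: list[list[float]]
    c: float
    seed: int
    fold_assignments: list[dict[str, int]] = field(default_factory=list)

    @property
    def run_means(self) -> list[float]:
        return [float(np.mean(run)) for run in self.fold_aucs]

    @property
    def mean_auc(self) -> float:
        if not self.fold_aucs:
            return float("nan")
        return float(np.mean([a for run in self.fold_aucs for a in run]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"run": ri, "fold": fi, "auc_pr": a}
            for ri, run in enumerate(self.fold_aucs)
            for fi, a in enumerate(run)
        ]
        return pd.DataFrame(rows, columns=["run", "fold", "auc_pr"])


def _labeled_arrays(grain: pd.DataFrame, labels: LabelSet
                    ) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels.require_trainable()
    tf_ids = [t for t in grain.index if t in labels.assignments]
    y = np.array([labels.assignments[t] == "positive" for t in tf_ids])
    if not y.any() or y.all():
        raise ValidationError("both classes must be present among TFs with features")
    X = grain.loc[tf_ids].to_numpy(dtype=float)
    return tf_ids, X, y


def _derive_seed(seed: int, *salt: int) -> int:
    return int(np.random.SeedSequence([seed, *salt]).generate_state(1)[0] % (2**31 - 1))


def _stratified_split(X, y, n_folds, seed, run):
    """Stratified folds, re-drawn (up to a cap) until every fold's train
    part holds both classes and its test part holds a positive."""
    for attempt in range(_MAX_FOLD_REDRAWS):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True,
            random_state=_derive_seed(seed, run, attempt),
        )
        folds = list(skf.split(X, y))
        ok = all(
            y[tr].any() and (~y[tr]).any() and y[te].any() and (~y[te]).any()
            for tr, te in folds
        )
        if ok:
            if attempt:
                logger.info("fold split re-drawn %d time(s)", attempt)
            return folds
    raise ValidationError(
        f"could not form {n_folds} stratified folds with both classes "
        f"after {_MAX_FOLD_REDRAWS} attempts"
    )


def _fit_svm(X, y, c: float) -> SVC:
    model = SVC(kernel="linear", C=c)
    model.fit(X, y.astype(int))
    return model


def c_grid_values(grid: tuple[float, float, float]) -> list[float]:
    """The C values lo, lo+step, ... not exceeding hi."""
    lo, hi, step = grid
    n = int(np.floor((hi - lo) / step + 1e-12)) + 1
    return [round(lo + i * step, 12) for i in range(n)]


def tune_c(
    grain: pd.DataFrame,
    labels: LabelSet,
    grid: tuple[float, float, float] = (0.001, 10.0, 0.1),
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Pick the grid C maximizing mean cross-validated AUC-PR.

    One seeded stratified split is shared by every grid point so scores
    are comparable; ties go to the smallest C.
    """
    tf_ids, X, y = _labeled_arrays(grain, labels)
    folds = _stratified_split(X, y, n_folds, seed, run=0)
    values = c_grid_values(grid)
    rows = []
    best_c, best_auc = None, -np.inf
    for c in values:
        aucs = []
        for tr, te in folds:
            model = _fit_svm(X[tr], y[tr], c)
            aucs.append(auc_pr(y[te], model.decision_function(X[te])))
        mean = float(np.mean(aucs))
        rows.append({"C": c, "mean_auc_pr": mean})
        if mean > best_auc + 1e-12:
            best_auc, best_c = mean, c
    return float(best_c), pd.DataFrame(rows)


def crossvalidate(
    grain: pd.DataFrame,
    labels: LabelSet,
    c: float = 1.0,
    n_folds: int = 5,
    n_runs: int = 10,
    seed: int = 0,
) -> CVReport:
    """``n_runs`` independent stratified ``n_folds``-fold CV rounds;
    each held-out fold is scored by AUC-PR."""
    tf_ids, X, y = _labeled_arrays(grain, labels)
    report = CVReport(fold_aucs=[], c=float(c), seed=seed)
    for run in range(n_runs):
        folds = _stratified_split(X, y, n_folds, seed, run)
        run_aucs = []
        assignment: dict[str, int] = {}
        for fi, (tr, te) in enumerate(folds):
            model = _fit_svm(X[tr], y[tr], c)
            run_aucs.append(auc_pr(y[te], model.decision_function(X[te])))
            for i in te:
                assignment[tf_ids[i]] = fi
        report.fold_aucs.append(run_aucs)
        report.fold_assignments.append(assignment)
    return report


def baseline(
    grain: pd.DataFrame,
    labels: LabelSet,
    mode: str = "uniform",
    n_runs: int = 10,
    c: float = 1.0,
    n_folds: int = 5,
    seed: int = 0,
) -> CVReport:
    """Negative-control classifiers.

    ``uniform`` replaces the positive set with randomly drawn TFs of
    equal count; ``family_matched`` draws pseudo-positives matching the
    positive class's family composition. Negatives are re-drawn from
    the remaining pool. Each run draws fresh pseudo-labels and performs
    one stratified CV round.
    """
    if mode not in ("uniform", "family_matched"):
        raise ValidationError(f"unknown baseline mode {mode!r}")
    labels.require_trainable()
    pool = [t for t in grain.index]
    positives = sorted(labels.positives & set(pool))
    negatives = sorted(labels.negatives & set(pool))
    if mode == "family_matched":
        if not labels.family:
            raise ValidationError("family_matched baseline needs family tags")
        by_family: dict[str, list[str]] = {}
        for tf in pool:
            fam = labels.family.get(tf)
            if fam is not None:
                by_family.setdefault(fam, []).append(tf)
    report = CVReport(fold_aucs=[], c=float(c), seed=seed)
    for run in range(n_runs):
        rng = np.random.default_rng(_derive_seed(seed, 7, run))
        if mode == "uniform":
            pseudo_pos = set(rng.choice(pool, size=len(positives), replace=False))
        else:
            pseudo_pos = set()
            fam_counts: dict[str, int] = {}
            for tf in positives:
                fam = labels.family.get(tf, "")
                fam_counts[fam] = fam_counts.get(fam, 0) + 1
            for fam, count in sorted(fam_counts.items()):
                members = sorted(by_family.get(fam, []))
                if not members:
                    raise ValidationError(f"no TFs available in family {fam!r}")
                replace = len(members) < count
                if replace:
                    logger.info(
                        "family %r has %d member(s) for %d draws; sampling "
                        "with replacement", fam, len(members), count,
                    )
                pseudo_pos |= set(rng.choice(members, size=count, replace=replace))
        remaining = sorted(set(pool) - pseudo_pos)
        pseudo_neg = set(rng.choice(remaining, size=min(len(negatives),
                                                        len(remaining)),
                         replace=False))
        pseudo = LabelSet(assignments={
            **{t: "positive" for t in pseudo_pos},
            **{t: "negative" for t in pseudo_neg},
        })
        sub = crossvalidate(grain, pseudo, c=c, n_folds=n_folds, n_runs=1,
                            seed=_derive_seed(seed, 11, run))
        report.fold_aucs.extend(sub.fold_aucs)
        report.fold_assignments.extend(sub.fold_assignments)
    return report


@dataclass
class FittedScorer:
    """The five fold-models of the final CV round plus their fold map."""

    models: list[SVC]
    fold_of_tf: dict[str, int]
    feature_names: list[str]


def score_all(
    grain: pd.DataFrame,
    labels: LabelSet,
    c: float = 1.0,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, FittedScorer]:
    """Margin scores for every TF from one final stratified CV round.

    Every fold model scores every TF; a labeled TF averages the models
    that trained on it (i.e. all but its own test fold), an unlabeled
    TF averages all models. Returns the score table (tf_id, D, rank,
    DS) and the fitted fold models.
    """
    tf_labeled, X, y = _labeled_arrays(grain, labels)
    folds = _stratified_split(X, y, n_folds, seed, run=0)
    models: list[SVC] = []
    fold_of: dict[str, int] = {}
    all_ids = list(grain.index)
    X_all = grain.to_numpy(dtype=float)
    D = np.zeros((len(all_ids), n_folds))
    for fi, (tr, te) in enumerate(folds):
        model = _fit_svm(X[tr], y[tr], c)
        models.append(model)
        D[:, fi] = model.decision_function(X_all)
        for i in te:
            fold_of[tf_labeled[i]] = fi
    d_mean = np.empty(len(all_ids))
    for i, tf in enumerate(all_ids):
        if tf in fold_of:
            mask = np.arange(n_folds) != fold_of[tf]
            d_mean[i] = D[i, mask].mean()
        else:
            d_mean[i] = D[i].mean()
    table = pd.DataFrame({"tf_id": all_ids, "D": d_mean})
    table = table.sort_values(["D", "tf_id"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    n = len(table)
    table["DS"] = 1.0 if n == 1 else 1.0 - (table["rank"] - 1) / (n - 1)
    scorer = FittedScorer(models=models, fold_of_tf=fold_of,
                          feature_names=list(grain.columns))
    return table, scorer


def feature_importance(scorer: FittedScorer) -> pd.DataFrame:
    """Module importances: |hyperplane coefficient| averaged across the
    fold models, ranked descending."""
    coefs = np.vstack([np.abs(m.coef_.ravel()) for m in scorer.models])
    imp = coefs.mean(axis=0)
    df = pd.DataFrame({"module_id": scorer.feature_names, "importance": imp})
    df = df.sort_values(["importance", "module_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def top_modules(importance: pd.DataFrame, fraction: float = 0.1) -> list[str]:
    """The top-``fraction`` modules by importance (at least one)."""
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    k = max(1, int(round(fraction * len(importance))))
    return list(importance["module_id"].head(k))


def decile_diagnostic(
    scores: pd.DataFrame,
    expr,
    n_bins: int = 100,
    n_folds: int = 3,
    group_size: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Score-ordered bin diagnostic.

    TFs are sorted by DS descending and split into ``n_bins``
    equal-size bins (remainder spread over the leading bins). Each
    bin's TF expression profiles are the features of a linear
    classifier of the sample condition, evaluated by stratified
    ``n_folds``-fold CV AUC-ROC. Bins with no TF present in the
    expression matrix are recorded with a missing AUC. The ``group``
    column batches bins in blocks of ``group_size`` for reporting.
    """
    from sklearn.metrics import roc_auc_score

    if expr.condition is None:
        raise ValidationError("expression matrix must carry condition labels")
    levels = sorted(expr.condition.unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 condition levels, got {levels}")
    y = (expr.condition == levels[1]).to_numpy()
    ordered = scores.sort_values("rank")["tf_id"].tolist()
    n = len(ordered)
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    bins: list[list[str]] = []
    pos = 0
    for size in sizes:
        bins.append(ordered[pos:pos + size])
        pos += size
    rows = []
    gene_set = set(expr.gene_ids)
    for bi, members in enumerate(bins):
        present = [t for t in members if t in gene_set]
        record = {"bin": bi + 1, "group": bi // group_size + 1,
                  "n_tfs": len(present), "auc_roc": np.nan}
        if present:
            X = expr.values.loc[present].to_numpy(dtype=float).T
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=_derive_seed(seed, 13, bi))
            held_scores = np.zeros(len(y))
            ok = True
            for tr, te in skf.split(X, y):
                if not (y[tr].any() and (~y[tr]).any()):
                    ok = False
                    break
                model = _fit_svm(X[tr], y[tr], 1.0)
                held_scores[te] = model.decision_function(X[te])
            if ok:
                record["auc_roc"] = float(roc_auc_score(y, held_scores))
        rows.append(record)
    return pd.DataFrame(rows, columns=["bin", "group", "n_tfs", "auc_roc"])
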