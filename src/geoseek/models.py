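"""Model protocols: splits, cross-validated fits, ROC/AUC, Hand-Till, ablation.

Five learner families are supported — lasso, ridge, and elastic-net
logistic regression, an RBF-kernel SVM, and a random forest.  Learner
internals come from scikit-learn; this module owns the protocol around
them: the stratified 80/20 split, the 5-fold cross-validation over a
regularization path with the one-standard-error lambda rule, the
``gamma = 1/p`` SVM convention with a cost grid, probability-score
extraction, and the ROC / AUC / Hand-Till computations (hand-written here
and cross-checked against rank statistics in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import ModelSpec
from .errors import GeoseekError

# ---------------------------------------------------------------------------
# splitting


def split_train_test(X: pd.DataFrame, y: pd.Series, fraction: float = 0.8,
                     seed: int = 0) -> tuple[pd.Index, pd.Index]:
    """Seeded stratified user-level split; returns (train_index, test_index).

    Within each class the users are shuffled and the first
    ``round(fraction * n_class)`` go to training, so class proportions in
    both parts match the overall proportions to within one user.
    """
    if not 0 < fraction < 1:
        raise GeoseekError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for cls in np.unique(y):
        members = np.array(sorted(X.index[y == cls]))
        rng.shuffle(members)
        n_train = int(round(fraction * len(members)))
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    return pd.Index(sorted(train_idx)), pd.Index(sorted(test_idx))


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve (FPR, TPR) sweeping the threshold over distinct scores.

    Tied scores move along the curve together, which is equivalent to
    rank-averaging ties in the AUC.  The curve starts at (0,0) and ends
    at (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise GeoseekError("need at least one positive and one negative label")
    order = np.argsort(-scores, kind="mergesort")
    s, p = scores[order], pos[order]
    distinct = np.concatenate([np.diff(s) != 0, [True]])
    tp = np.cumsum(p)[distinct]
    fp = np.cumsum(~p)[distinct]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    return fpr, tpr


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the trapezoid rule.

    Numerically identical to the Mann-Whitney statistic
    U / (n_pos * n_neg) with rank-averaged ties.
    """
    fpr, tpr = roc_points(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def hand_till_auc(proba: np.ndarray, labels, classes=None) -> float:
    """Multiclass AUC of Hand & Till: mean over unordered class pairs.

    For classes i, j the pairwise term is [A(i|j) + A(j|i)] / 2 where
    A(i|j) is the binary AUC of the class-i probability column restricted
    to samples of classes {i, j}.  With two classes this reduces exactly
    to the binary AUC.
    """
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    classes = list(classes)
    if len(classes) < 2:
        raise GeoseekError("need at least two classes")
    proba = np.asarray(proba, dtype=float)
    col = {c: k for k, c in enumerate(classes)}
    terms = []
    for a_i in range(len(classes)):
        for a_j in range(a_i + 1, len(classes)):
            ci, cj = classes[a_i], classes[a_j]
            mask = (labels == ci) | (labels == cj)
            yi = (labels[mask] == ci).astype(int)
            a_ij = roc_auc(proba[mask, col[ci]], yi)
            a_ji = roc_auc(proba[mask, col[cj]], 1 - yi)
            terms.append(0.5 * (a_ij + a_ji))
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# cross-validated fitting


@dataclass
class EvalResult:
    """Fit outcome: train/test AUC, ROC points, per-user scores, extras."""

    family: str
    train_auc: float
    test_auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    scores: pd.Series                   # test-user probability of class 1
    chosen: dict = field(default_factory=dict)
    multiclass: bool = False
    hand_till: float | None = None
    accuracy: float | None = None

    def summary(self) -> dict:
        out = {"family": self.family, "train_auc": self.train_auc,
               "test_auc": self.test_auc, **self.chosen}
        if self.multiclass:
            out.update(hand_till_auc=self.hand_till, accuracy=self.accuracy)
        return out


def _kfold_indices(n: int, k: int, y: np.ndarray, rng: np.random.Generator):
    """Stratified k-fold assignment: per class, shuffled round-robin."""
    fold = np.empty(n, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def _lambda_path(X: np.ndarray, y: np.ndarray, alpha: float, spec: ModelSpec
                 ) -> np.ndarray:
    """Decreasing log-spaced lambda path from the null-model gradient.

    ``lambda_max`` is the smallest penalty that zeroes every coefficient of
    an l1-type model (max absolute gradient at the intercept-only fit,
    scaled by the l1 mixing weight); the path descends to
    ``lambda_min_ratio * lambda_max``.
    """
    n = len(y)
    ybar = y.mean()
    g = np.abs(X.T @ (y - ybar)) / n
    lam_max = g.max() / max(alpha, 1e-3)
    lam_max = max(lam_max, 1e-4)
    return np.geomspace(lam_max, lam_max * spec.lambda_min_ratio, spec.n_lambdas)


def _make_logistic(penalty: str, lam: float, alpha: float, n: int) -> LogisticRegression:
    C = 1.0 / max(n * lam, 1e-12)
    if penalty == "elasticnet":
        return LogisticRegression(solver="saga", l1_ratio=alpha, C=C,
                                  max_iter=2000, tol=1e-4)
    l1_ratio = 1.0 if penalty == "l1" else 0.0
    return LogisticRegression(l1_ratio=l1_ratio, solver="liblinear", C=C,
                              max_iter=2000)


def _cv_deviance(X, y, builder, grid, folds, seed):
    """Mean and SE (over folds) of binomial deviance for each grid point."""
    rng = np.random.default_rng(seed)
    fold = _kfold_indices(len(y), folds, y, rng)
    dev = np.zeros((len(grid), folds))
    for f in range(folds):
        tr, va = fold != f, fold == f
        for gi, g in enumerate(grid):
            model = builder(g)
            model.fit(X[tr], y[tr])
            p = model.predict_proba(X[va])
            dev[gi, f] = log_loss(y[va], p, labels=np.unique(y))
    mean = dev.mean(axis=1)
    se = dev.std(axis=1, ddof=1) / np.sqrt(folds)
    return mean, se


def _one_se_choice(grid: np.ndarray, mean: np.ndarray, se: np.ndarray,
                   one_se: bool) -> tuple[float, dict]:
    """Pick the grid point by minimum CV error or the one-SE rule.

    The one-SE rule selects the *largest* lambda (strongest penalty) whose
    mean CV error is within one standard error of the minimum, so the
    penalization is never weaker than at the minimizing lambda.  Assumes
    ``grid`` is sorted in decreasing lambda order.
    """
    i_min = int(np.argmin(mean))
    info = {"lambda_min": float(grid[i_min]), "cv_error_min": float(mean[i_min])}
    if not one_se:
        return float(grid[i_min]), info
    threshold = mean[i_min] + se[i_min]
    eligible = np.flatnonzero(mean <= threshold)
    i_1se = int(eligible.min())  # earliest index = largest lambda
    info["lambda_1se"] = float(grid[i_1se])
    return float(grid[i_1se]), info


def _fit_regularized(Xtr, ytr, spec: ModelSpec, penalty: str):
    scaler = StandardScaler().fit(Xtr)
    Xs = scaler.transform(Xtr)
    n = len(ytr)
    if penalty == "elasticnet":
        best = None
        for alpha in spec.enet_alphas:
            lams = _lambda_path(Xs, ytr, alpha, spec)
            mean, se = _cv_deviance(
                Xs, ytr, lambda lam: _make_logistic("elasticnet", lam, alpha, n),
                lams, spec.cv_folds, spec.seed)
            lam, info = _one_se_choice(lams, mean, se, spec.one_se_rule)
            key = mean[int(np.argmin(np.abs(lams - lam)))]
            if best is None or key < best[0]:
                best = (key, alpha, lam, info)
        _, alpha, lam, info = best
        model = _make_logistic("elasticnet", lam, alpha, n).fit(Xs, ytr)
        info.update(alpha=alpha, lambda_=lam)
    else:
        alpha_mix = 1.0 if penalty == "l1" else 0.0
        lams = _lambda_path(Xs, ytr, alpha_mix if penalty == "l1" else 0.5, spec)
        mean, se = _cv_deviance(
            Xs, ytr, lambda lam: _make_logistic(penalty, lam, 1.0, n),
            lams, spec.cv_folds, spec.seed)
        lam, info = _one_se_choice(lams, mean, se, spec.one_se_rule)
        model = _make_logistic(penalty, lam, 1.0, n).fit(Xs, ytr)
        info.update(lambda_=lam)
    return model, scaler, info


def _fit_svm(Xtr, ytr, spec: ModelSpec):
    scaler = StandardScaler().fit(Xtr)
    Xs = scaler.transform(Xtr)
    gamma = 1.0 / Xtr.shape[1]  # 1 / number of features
    mean, se = _cv_deviance(
        Xs, ytr,
        lambda c: SVC(kernel="rbf", gamma=gamma, C=c, probability=True,
                      random_state=spec.seed),
        np.array(spec.svm_cost_grid, dtype=float), spec.cv_folds, spec.seed)
    i = int(np.argmin(mean))
    cost = float(spec.svm_cost_grid[i])
    model = SVC(kernel="rbf", gamma=gamma, C=cost, probability=True,
                random_state=spec.seed).fit(Xs, ytr)
    return model, scaler, {"gamma": gamma, "cost": cost}


def fit_and_score(Xtr: pd.DataFrame, ytr: pd.Series, Xte: pd.DataFrame,
                  yte: pd.Series, spec: ModelSpec) -> EvalResult:
    """Tune, fit, and evaluate one learner family.

    Regularized linear families are tuned by ``cv_folds``-fold CV over a
    lambda path with the one-SE rule (elastic net over an (alpha, lambda)
    grid); the SVM uses ``gamma = 1/p`` and a CV-chosen cost; the random
    forest needs no tuning.  Binary problems report train/test AUC and a
    ROC curve; a multiclass label vector switches the evaluation to
    Hand-Till AUC and argmax accuracy.
    """
    if list(Xtr.columns) != list(Xte.columns):
        raise GeoseekError("train and test matrices must share columns")
    ytr_a = np.asarray(ytr)
    classes = np.unique(ytr_a)
    if len(classes) < 2:
        raise GeoseekError("training labels contain a single class")
    multiclass = len(classes) > 2

    Xtr_a, Xte_a = Xtr.to_numpy(dtype=float), Xte.to_numpy(dtype=float)
    fam = spec.family
    if fam in ("lasso", "ridge", "elastic_net"):
        penalty = {"lasso": "l1", "ridge": "l2", "elastic_net": "elasticnet"}[fam]
        model, scaler, chosen = _fit_regularized(Xtr_a, ytr_a, spec, penalty)
        tr_p = model.predict_proba(scaler.transform(Xtr_a))
        te_p = model.predict_proba(scaler.transform(Xte_a))
    elif fam == "svm_rbf":
        model, scaler, chosen = _fit_svm(Xtr_a, ytr_a, spec)
        tr_p = model.predict_proba(scaler.transform(Xtr_a))
        te_p = model.predict_proba(scaler.transform(Xte_a))
    elif fam == "random_forest":
        model = RandomForestClassifier(n_estimators=spec.n_trees,
                                       random_state=spec.seed, n_jobs=1)
        model.fit(Xtr_a, ytr_a)
        chosen = {"n_trees": spec.n_trees}
        tr_p, te_p = model.predict_proba(Xtr_a), model.predict_proba(Xte_a)
    else:  # pragma: no cover - guarded by ModelSpec
        raise GeoseekError(f"unknown family {fam}")

    yte_a = np.asarray(yte)
    if multiclass:
        ht_train = hand_till_auc(tr_p, ytr_a, classes)
        ht = hand_till_auc(te_p, yte_a, classes)
        acc = float((classes[np.argmax(te_p, axis=1)] == yte_a).mean())
        scores = pd.Series(np.max(te_p, axis=1), index=Xte.index)
        return EvalResult(family=fam, train_auc=ht_train, test_auc=ht,
                          fpr=np.array([]), tpr=np.array([]), scores=scores,
                          chosen=chosen, multiclass=True, hand_till=ht,
                          accuracy=acc)
    pos_col = int(np.flatnonzero(classes == classes.max())[0])
    tr_s, te_s = tr_p[:, pos_col], te_p[:, pos_col]
    fpr, tpr = roc_points(te_s, yte_a)
    return EvalResult(
        family=fam,
        train_auc=roc_auc(tr_s, (ytr_a == classes.max()).astype(int)),
        test_auc=roc_auc(te_s, (yte_a == classes.max()).astype(int)),
        fpr=fpr, tpr=tpr,
        scores=pd.Series(te_s, index=Xte.index),
        chosen=chosen)


# ---------------------------------------------------------------------------
# ablation


def ablation_study(X: pd.DataFrame, y: pd.Series, column_categories: dict[str, str],
                   spec: ModelSpec, fraction: float = 0.8,
                   seed: int = 0) -> dict[str, float]:
    """Leave-one-feature-category-out refits on a common split.

    Returns a dict mapping ``"full"`` and ``"without_<category>"`` to the
    held-out test AUC of a model trained with that category's columns
    removed.  All fits share the same train/test split and seed, so the
    differences isolate the dropped category's contribution.
    """
    cats = sorted(set(column_categories.values()))
    tr, te = split_train_test(X, y, fraction, seed)
    out = {}
    res = fit_and_score(X.loc[tr], y.loc[tr], X.loc[te], y.loc[te], spec)
    out["full"] = res.test_auc
    for cat in cats:
        keep = [c for c in X.columns if column_categories.get(c) != cat]
        res = fit_and_score(X.loc[tr, keep], y.loc[tr], X.loc[te, keep],
                            y.loc[te], spec)
        out[f"without_{cat}"] = res.test_auc
    return out
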