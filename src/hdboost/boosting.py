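"""Boosting ensembles for two-class prediction with tree base learners.

Five algorithms share the CART base learners of :mod:`hdboost.tree`:

* **AdaBoost.M1** — classic discrete AdaBoost: the weighted resubstitution
  error of each stage drives the sample-weight update.  When a depth-5
  tree shatters a small high-dimensional sample its resubstitution error
  is zero, the weights never change, and every stage is the same tree —
  so the ensemble degenerates to its base classifier.
* **AdaBoost.M1.ICV** — identical except the per-sample errors entering
  the weight update are estimated by internal k-fold cross-validation of
  the current weighted training set, which keeps the error estimate away
  from zero under overfitting and restores the boosting dynamic.
* **GrBoost** — gradient boosting of the exponential loss with regression
  trees and a per-leaf Newton step.
* **St-GrBoost** — the same with per-iteration subsampling without
  replacement (stochastic gradient boosting); out-of-bag loss
  improvements are recorded for early stopping.
* **LogitBoost** — Newton boosting of the binomial log-likelihood via
  weighted least-squares stumps on the working response.

All estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``decision_function`` / ``staged_*``, ``get_params``), accept labels in
{1, 2}, and are deterministic given ``random_state``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .datasets import LabeledDataset
from .tree import (TreeConfig, TreeModel, fit_classification_tree,
                   fit_regression_tree)

CLASSES = np.array([1, 2])

#: Cap on gradient-boosting leaf updates (numerical safety for exp loss).
MAX_LEAF_VALUE = 8.0
#: LogitBoost working-response clip and weight floor (standard choices).
Z_MAX = 4.0
W_MIN = 2.0 * np.sqrt(np.finfo(np.float64).eps)


# ---------------------------------------------------------------------------
# configuration and shared helpers
# ---------------------------------------------------------------------------

@dataclass
class BoostConfig:
    """Hyperparameters shared by the thin ``fit_*`` wrapper functions.

    ``nu=None`` means "the algorithm's default": no shrinkage (1.0) for
    plain gradient boosting, 0.01 for the stochastic variant.  ``eta`` is
    the subsampling fraction (stochastic variant only, default 0.5) and
    ``icv_folds`` the number of internal CV folds (ICV variant, default 5).
    """

    M: int = 100
    nu: float | None = None
    eta: float = 0.5
    icv_folds: int = 5
    tree: TreeConfig = field(default_factory=TreeConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.nu is not None and not 0.0 < self.nu <= 1.0:
            raise ValueError("nu must lie in (0, 1]")
        if not 0.0 < self.eta <= 1.0:
            raise ValueError("eta must lie in (0, 1]")
        if self.icv_folds < 2:
            raise ValueError("icv_folds must be >= 2")


def _validate_xy(X, y):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match X rows")
    if not np.isin(y, CLASSES).all():
        raise ValueError("labels must take values in {1, 2}")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present for fitting")
    return X, y.astype(np.int64)


def _check_predict_X(est, X):
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != est.n_features_in_:
        raise ValueError(f"X must be 2-D with {est.n_features_in_} columns")
    return X


def stratified_folds(y: np.ndarray, k: int,
                     rng: np.random.Generator) -> list[np.ndarray]:
    """Partition sample indices into ``k`` class-stratified folds.

    Indices of each class are shuffled and dealt round-robin, so fold
    sizes differ by at most one per class.  Returns the held-out index
    arrays.  A fold may end up one-class when a class has fewer members
    than ``k``; callers must tolerate degenerate (single-leaf) fold models.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > y.shape[0]:
        raise ValueError("more folds than samples")
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


def adaboost_weight_update(w: np.ndarray, eps_i: np.ndarray
                           ) -> tuple[float, float, np.ndarray]:
    """One AdaBoost weight update from per-sample error indicators.

    ``eps_i`` is 1 for a misclassified sample and 0 otherwise (for the ICV
    variant it is the cross-validated indicator).  Returns
    ``(eps, alpha, w_new)`` where ``eps = sum_i w_i eps_i``,
    ``alpha = ln((1 - eps) / eps)`` and
    ``w_new_i \\propto w_i exp(alpha * eps_i)``.

    Boundary rules: at ``eps == 0`` the error is clamped to
    ``delta = 1/(2n)`` for the stage weight and the sample weights are
    left unchanged (so all subsequent stages repeat the same fit); at
    ``eps >= 1/2`` the stage gets zero vote (``alpha = 0``) and the
    weights are again left unchanged — the stage is effectively skipped,
    which keeps the recursion alive when cross-validated error estimates
    hover around chance.
    """
    w = np.asarray(w, dtype=np.float64)
    eps_i = np.asarray(eps_i, dtype=np.float64)
    n = w.shape[0]
    eps = float(w @ eps_i)
    if eps <= 0.0:
        delta = 1.0 / (2.0 * n)
        alpha = float(np.log((1.0 - delta) / delta))
        return 0.0, alpha, w.copy()
    if eps >= 0.5:
        return eps, 0.0, w.copy()
    alpha = float(np.log((1.0 - eps) / eps))
    w_new = w * np.exp(alpha * eps_i)
    w_new /= w_new.sum()
    return eps, alpha, w_new


# ---------------------------------------------------------------------------
# AdaBoost.M1 and AdaBoost.M1.ICV
# ---------------------------------------------------------------------------

class AdaBoostM1Classifier(ClassifierMixin, BaseEstimator):
    """Discrete AdaBoost.M1 with depth-capped classification trees.

    Parameters
    ----------
    n_estimators : int
        Number of boosting iterations M.
    max_depth : int
        Depth cap of the base trees (1 = stump, 5 = CART(5)).
    random_state : int
        Seed for any randomized component (fold draws in the ICV subclass).

    Attributes
    ----------
    estimators_ : list of TreeModel
        The voted stage classifiers.
    alphas_ : ndarray
        Stage (classifier) weights.
    errors_ : ndarray
        The per-stage weighted error estimates driving the updates.
    """

    _algorithm = "adaboost.m1"

    def __init__(self, n_estimators: int = 100, max_depth: int = 5,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    # -- per-iteration error estimate (overridden by the ICV subclass) --
    def _stage_error_indicators(self, X, y, w, tree, rng) -> np.ndarray:
        return (tree.predict(X) != y).astype(np.float64)

    def fit(self, X, y):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        X, y = _validate_xy(X, y)
        n = X.shape[0]
        tcfg = TreeConfig(max_depth=self.max_depth)
        rng = np.random.default_rng(self.random_state)
        data = LabeledDataset(X, y)
        w = np.full(n, 1.0 / n)

        estimators, alphas, errors = [], [], []
        for _m in range(self.n_estimators):
            tree = fit_classification_tree(data, w, tcfg)
            eps_i = self._stage_error_indicators(X, y, w, tree, rng)
            eps, alpha, w = adaboost_weight_update(w, eps_i)
            estimators.append(tree)
            alphas.append(alpha)
            errors.append(eps)

        self.classes_ = CLASSES.copy()
        self.n_features_in_ = X.shape[1]
        self.estimators_ = estimators
        self.alphas_ = np.array(alphas)
        self.errors_ = np.array(errors)
        return self

    # -- prediction ----------------------------------------------------
    def _stage_margins(self, X):
        """Yield the running normalized vote margin after each stage.

        The margin is ``(sum_m alpha_m (1[c_m=2] - 1[c_m=1])) / sum_m
        alpha_m``; positive means class 2.  It doubles as the ranking
        score for AUC.
        """
        X = _check_predict_X(self, X)
        vote = np.zeros(X.shape[0])
        total = 0.0
        for tree, alpha in zip(self.estimators_, self.alphas_):
            sign = np.where(tree.predict(X) == 2, 1.0, -1.0)
            vote = vote + alpha * sign
            total += alpha
            yield vote / total if total > 0 else np.zeros_like(vote)

    def decision_function(self, X):
        out = None
        for out in self._stage_margins(X):
            pass
        return out

    def staged_decision_function(self, X):
        yield from self._stage_margins(X)

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, 2, 1)

    def staged_predict(self, X):
        for score in self._stage_margins(X):
            yield np.where(score > 0, 2, 1)


class AdaBoostM1ICVClassifier(AdaBoostM1Classifier):
    """AdaBoost.M1 with internally cross-validated weight updates.

    At every boosting iteration the training set is split into
    ``icv_folds`` class-stratified folds (re-randomized per iteration);
    per-sample misclassification indicators come from fold models fit on
    the complementary folds under the current weights.  The stage
    classifier that actually votes is refit on the full weighted training
    set.  Everything else matches AdaBoost.M1.
    """

    _algorithm = "adaboost.m1.icv"

    def __init__(self, n_estimators: int = 100, max_depth: int = 5,
                 icv_folds: int = 5, random_state: int = 0):
        super().__init__(n_estimators=n_estimators, max_depth=max_depth,
                         random_state=random_state)
        self.icv_folds = icv_folds

    def _stage_error_indicators(self, X, y, w, tree, rng) -> np.ndarray:
        tcfg = TreeConfig(max_depth=self.max_depth)
        eps_i = np.zeros(X.shape[0])
        for hold in stratified_folds(y, self.icv_folds, rng):
            fit_idx = np.setdiff1d(np.arange(X.shape[0]), hold,
                                   assume_unique=True)
            if np.unique(y[fit_idx]).size < 2 or w[fit_idx].sum() <= 0:
                # degenerate fold model: a single leaf predicting the
                # dominant (or only) class of the fit part
                counts = np.bincount(y[fit_idx], weights=w[fit_idx],
                                     minlength=3)[1:]
                pred = np.full(hold.size, int(np.argmax(counts)) + 1)
            else:
                sub = LabeledDataset(X[fit_idx], y[fit_idx])
                fold_tree = fit_classification_tree(sub, w[fit_idx], tcfg)
                pred = fold_tree.predict(X[hold])
            eps_i[hold] = (pred != y[hold]).astype(np.float64)
        return eps_i


# ---------------------------------------------------------------------------
# gradient boosting with exponential loss
# ---------------------------------------------------------------------------

class GradientExpBoostClassifier(ClassifierMixin, BaseEstimator):
    """Gradient boosting of the exponential loss with regression trees.

    With labels recoded to ``y~ in {-1, +1}`` and score F(x), the loss is
    ``exp(-y~ F)``.  Each iteration fits a depth-capped regression tree to
    the pseudo-residuals ``r_i = y~_i exp(-y~_i F_i)`` and replaces every
    leaf value by one Newton step ``gamma_j = sum r_i / sum |r_i|``
    (capped in magnitude), then updates ``F <- F + nu * gamma``.  With
    ``subsample < 1`` a fraction of samples is drawn without replacement
    per iteration for the tree fit and leaf steps (stochastic gradient
    boosting) and the out-of-bag loss improvement is recorded.

    Parameters
    ----------
    n_estimators : int
        Boosting iterations M.
    learning_rate : float
        Shrinkage factor nu in (0, 1]; 1 = no shrinkage.
    subsample : float
        Fraction eta of samples used per tree, drawn without replacement;
        1 disables subsampling.
    max_depth : int
        Depth cap of the regression trees.

    Attributes
    ----------
    F0_ : float
        Initial score, ``0.5 * ln(n2 / n1)`` (zero for balanced data).
    estimators_ : list of TreeModel
        Stage trees whose leaf values are the (unshrunk) Newton steps.
    oob_improvement_ : ndarray
        Per-iteration mean decrease of the loss on the out-of-bag
        samples; present only when ``subsample < 1``.
    train_loss_ : ndarray
        Mean training exponential loss after each iteration.
    """

    _algorithm = "grboost"

    def __init__(self, n_estimators: int = 100, learning_rate: float = 1.0,
                 subsample: float = 1.0, max_depth: int = 5,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        if not 0.0 < self.subsample <= 1.0:
            raise ValueError("subsample must lie in (0, 1]")
        X, y = _validate_xy(X, y)
        n = X.shape[0]
        n_sub = int(np.floor(self.subsample * n))
        if n_sub < 2:
            raise ValueError("subsample fraction leaves fewer than 2 samples")
        tcfg = TreeConfig(max_depth=self.max_depth)
        rng = np.random.default_rng(self.random_state)

        ypm = np.where(y == 2, 1.0, -1.0)
        n2 = float(np.sum(y == 2))
        F0 = 0.5 * np.log(n2 / (n - n2))
        F = np.full(n, F0)

        estimators, train_loss, oob_improvement = [], [], []
        stochastic = self.subsample < 1.0
        for _m in range(self.n_estimators):
            r = ypm * np.exp(-ypm * F)
            if stochastic:
                idx = rng.choice(n, size=n_sub, replace=False)
            else:
                idx = np.arange(n)
            tree = fit_regression_tree(X[idx], r[idx], config=tcfg)
            self._newton_leaves(tree, X[idx], r[idx])
            increment = self.learning_rate * tree.predict(X)
            if stochastic:
                oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
                before = np.exp(-ypm[oob] * F[oob])
                after = np.exp(-ypm[oob] * (F[oob] + increment[oob]))
                oob_improvement.append(float(np.mean(before - after)))
            F = F + increment
            train_loss.append(float(np.mean(np.exp(-ypm * F))))
            estimators.append(tree)

        self.classes_ = CLASSES.copy()
        self.n_features_in_ = X.shape[1]
        self.F0_ = float(F0)
        self.estimators_ = estimators
        self.train_loss_ = np.array(train_loss)
        if stochastic:
            self.oob_improvement_ = np.array(oob_improvement)
        return self

    @staticmethod
    def _newton_leaves(tree: TreeModel, X_fit, r_fit) -> None:
        """Replace fitted leaf means by the capped Newton step
        ``gamma_j = sum_{i in leaf} r_i / sum_{i in leaf} |r_i|``."""
        leaf_of = tree.apply(X_fit)
        num = np.zeros(tree.n_nodes)
        den = np.zeros(tree.n_nodes)
        np.add.at(num, leaf_of, r_fit)
        np.add.at(den, leaf_of, np.abs(r_fit))
        with np.errstate(invalid="ignore"):
            gamma = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        gamma = np.clip(gamma, -MAX_LEAF_VALUE, MAX_LEAF_VALUE)
        leaves = tree.is_leaf
        tree.value[leaves] = gamma[leaves]

    # -- prediction ----------------------------------------------------
    def _stage_scores(self, X):
        X = _check_predict_X(self, X)
        F = np.full(X.shape[0], self.F0_)
        for tree in self.estimators_:
            F = F + self.learning_rate * tree.predict(X)
            yield F

    def decision_function(self, X):
        out = None
        for out in self._stage_scores(X):
            pass
        return out

    def staged_decision_function(self, X):
        yield from self._stage_scores(X)

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, 2, 1)

    def staged_predict(self, X):
        for F in self._stage_scores(X):
            yield np.where(F > 0, 2, 1)


# ---------------------------------------------------------------------------
# LogitBoost
# ---------------------------------------------------------------------------

class LogitBoostClassifier(ClassifierMixin, BaseEstimator):
    """LogitBoost: Newton boosting of the binomial deviance with weighted
    least-squares trees (stumps by default).

    With ``y* in {0, 1}`` and probability ``p = 1 / (1 + exp(-2F))``, each
    iteration computes working weights ``w_i = p_i (1 - p_i)`` (floored)
    and responses ``z_i = (y*_i - p_i) / w_i`` (clipped to ±4), fits a
    weighted regression tree ``f_m`` to ``z`` and updates
    ``F <- F + f_m / 2``.  Prone to overfitting at large M on
    high-dimensional data — the error curve typically turns up after
    ~100 iterations.
    """

    _algorithm = "logitboost"

    def __init__(self, n_estimators: int = 100, max_depth: int = 1,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        X, y = _validate_xy(X, y)
        n = X.shape[0]
        tcfg = TreeConfig(max_depth=self.max_depth)
        ystar = (y == 2).astype(np.float64)
        F = np.zeros(n)
        p = np.full(n, 0.5)

        estimators = []
        for _m in range(self.n_estimators):
            w = np.maximum(p * (1.0 - p), W_MIN)
            z = np.clip((ystar - p) / w, -Z_MAX, Z_MAX)
            tree = fit_regression_tree(X, z, weights=w, config=tcfg)
            F = F + 0.5 * tree.predict(X)
            p = 1.0 / (1.0 + np.exp(-2.0 * F))
            estimators.append(tree)

        self.classes_ = CLASSES.copy()
        self.n_features_in_ = X.shape[1]
        self.F0_ = 0.0
        self.estimators_ = estimators
        return self

    def _stage_scores(self, X):
        X = _check_predict_X(self, X)
        F = np.zeros(X.shape[0])
        for tree in self.estimators_:
            F = F + 0.5 * tree.predict(X)
            yield F

    def decision_function(self, X):
        out = None
        for out in self._stage_scores(X):
            pass
        return out

    def staged_decision_function(self, X):
        yield from self._stage_scores(X)

    def predict_proba(self, X):
        p2 = 1.0 / (1.0 + np.exp(-2.0 * self.decision_function(X)))
        return np.column_stack([1.0 - p2, p2])

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, 2, 1)

    def staged_predict(self, X):
        for F in self._stage_scores(X):
            yield np.where(F > 0, 2, 1)


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators
# ---------------------------------------------------------------------------

def fit_adaboost_m1(data: LabeledDataset,
                    config: BoostConfig) -> AdaBoostM1Classifier:
    est = AdaBoostM1Classifier(n_estimators=config.M,
                               max_depth=config.tree.max_depth,
                               random_state=config.seed)
    return est.fit(data.X, data.y)


def fit_adaboost_m1_icv(data: LabeledDataset,
                        config: BoostConfig) -> AdaBoostM1ICVClassifier:
    est = AdaBoostM1ICVClassifier(n_estimators=config.M,
                                  max_depth=config.tree.max_depth,
                                  icv_folds=config.icv_folds,
                                  random_state=config.seed)
    return est.fit(data.X, data.y)


def fit_grboost(data: LabeledDataset,
                config: BoostConfig) -> GradientExpBoostClassifier:
    nu = 1.0 if config.nu is None else config.nu
    est = GradientExpBoostClassifier(n_estimators=config.M, learning_rate=nu,
                                     subsample=1.0,
                                     max_depth=config.tree.max_depth,
                                     random_state=config.seed)
    return est.fit(data.X, data.y)


def fit_st_grboost(data: LabeledDataset,
                   config: BoostConfig) -> GradientExpBoostClassifier:
    nu = 0.01 if config.nu is None else config.nu
    est = GradientExpBoostClassifier(n_estimators=config.M, learning_rate=nu,
                                     subsample=config.eta,
                                     max_depth=config.tree.max_depth,
                                     random_state=config.seed)
    return est.fit(data.X, data.y)


def fit_logitboost(data: LabeledDataset,
                   config: BoostConfig) -> LogitBoostClassifier:
    est = LogitBoostClassifier(n_estimators=config.M,
                               max_depth=config.tree.max_depth,
                               random_state=config.seed)
    return est.fit(data.X, data.y)


def staged_predict(model, X, at_iterations):
    """Predictions and scores of the first M' stages, for several M'.

    One pass over the stages regardless of how many iteration counts are
    requested.  Returns ``(labels, scores)``, each of shape
    ``(len(at_iterations), n_samples)`` in the order given.
    """
    at = [int(m) for m in at_iterations]
    M = len(model.estimators_)
    for m in at:
        if not 1 <= m <= M:
            raise ValueError(f"requested iteration {m} outside 1..{M}")
    wanted = {m: k for k, m in enumerate(at)}
    labels = np.empty((len(at), np.asarray(X).shape[0]), dtype=np.int64)
    scores = np.empty((len(at), np.asarray(X).shape[0]))
    for m, score in enumerate(model.staged_decision_function(X), start=1):
        if m in wanted:
            k = wanted[m]
            scores[k] = score
            labels[k] = np.where(score > 0, 2, 1)
        if m >= max(at):
            break
    return labels, scores


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

_REGISTRY = {cls._algorithm: cls for cls in
             (AdaBoostM1Classifier, AdaBoostM1ICVClassifier,
              GradientExpBoostClassifier, LogitBoostClassifier)}


def model_to_json(model) -> str:
    """Serialize a fitted boosting model; reload predicts bit-identically."""
    payload = {
        "algorithm": model._algorithm,
        "params": model.get_params(),
        "n_features_in": int(model.n_features_in_),
        "F0": float(getattr(model, "F0_", 0.0)),
        "alphas": np.asarray(getattr(model, "alphas_", [])).tolist(),
        "stages": [t.to_dict() for t in model.estimators_],
    }
    return json.dumps(payload)


def model_from_json(s: str):
    payload = json.loads(s)
    cls = _REGISTRY[payload["algorithm"]]
    model = cls(**payload["params"])
    model.classes_ = CLASSES.copy()
    model.n_features_in_ = payload["n_features_in"]
    model.estimators_ = [TreeModel.from_dict(d) for d in payload["stages"]]
    if payload["alphas"]:
        model.alphas_ = np.array(payload["alphas"])
    if payload["algorithm"] in ("grboost", "logitboost"):
        model.F0_ = payload["F0"]
    return model
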