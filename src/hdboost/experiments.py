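"""Seeded experiment runner: replicate simulations, fit classifier panels,
tabulate staged test errors, and evaluate classifiers on fixed datasets by
repeated cross-validation with majority-class down-sizing.

Classifiers are addressed by the benchmark tags used throughout the
package, e.g. ``CART(5)``, ``AdaBoost.M1(1)``, ``AdaBoost.M1.ICV(5)``,
``GrBoost(5)``, ``St-GrBoost(5)``, ``LogitBoost(1)`` — the parenthesized
number is the tree depth cap.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin

from .boosting import (AdaBoostM1Classifier, AdaBoostM1ICVClassifier,
                       BoostConfig, GradientExpBoostClassifier,
                       LogitBoostClassifier, staged_predict)
from .datasets import LabeledDataset
from .evaluation import accuracy_metrics, records_to_frame
from .preprocess import downsize_majority
from .simulate import (SimulationConfig, simulate_block_mvn,
                       simulate_null_independent, simulate_variance_shift)
from .tree import TreeConfig, fit_classification_tree

#: Largest admissible fraction of failed replicates before aborting a run.
MAX_FAILED_FRACTION = 0.10


class CARTClassifier(ClassifierMixin, BaseEstimator):
    """A single depth-capped classification tree, wrapped as an estimator.

    This is the boosting base classifier run on its own (the M = 1
    reference row of every comparison).  Its decision score is the vote
    margin ±1 implied by the predicted label.
    """

    def __init__(self, max_depth: int = 5, random_state: int = 0):
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        data = LabeledDataset(np.asarray(X, dtype=float), y)
        self.tree_ = fit_classification_tree(
            data, config=TreeConfig(max_depth=self.max_depth))
        self.classes_ = np.array([1, 2])
        self.n_features_in_ = data.n_variables
        self.estimators_ = [self.tree_]
        return self

    def predict(self, X):
        return self.tree_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X):
        return np.where(self.predict(X) == 2, 1.0, -1.0)

    def staged_decision_function(self, X):
        yield self.decision_function(X)

    def staged_predict(self, X):
        yield self.predict(X)


_TAG_RE = re.compile(
    r"^(CART|AdaBoost\.M1|AdaBoost\.M1\.ICV|GrBoost|St-GrBoost|LogitBoost)"
    r"\((\d+)\)$", re.IGNORECASE)


def make_classifier(tag: str, config: BoostConfig | None = None):
    """Instantiate an unfitted estimator from a benchmark tag.

    ``config`` supplies M, shrinkage, subsampling fraction, ICV folds and
    seed; the depth inside the tag overrides ``config.tree.max_depth``.
    """
    config = config or BoostConfig()
    m = _TAG_RE.match(tag.strip())
    if m is None:
        raise ValueError(f"unrecognized classifier tag {tag!r}")
    family = m.group(1).lower()
    depth = int(m.group(2))
    M, seed = config.M, config.seed
    if family == "cart":
        return CARTClassifier(max_depth=depth, random_state=seed)
    if family == "adaboost.m1":
        return AdaBoostM1Classifier(n_estimators=M, max_depth=depth,
                                    random_state=seed)
    if family == "adaboost.m1.icv":
        return AdaBoostM1ICVClassifier(n_estimators=M, max_depth=depth,
                                       icv_folds=config.icv_folds,
                                       random_state=seed)
    if family == "grboost":
        nu = 1.0 if config.nu is None else config.nu
        return GradientExpBoostClassifier(n_estimators=M, learning_rate=nu,
                                          subsample=1.0, max_depth=depth,
                                          random_state=seed)
    if family == "st-grboost":
        nu = 0.01 if config.nu is None else config.nu
        return GradientExpBoostClassifier(n_estimators=M, learning_rate=nu,
                                          subsample=config.eta,
                                          max_depth=depth, random_state=seed)
    if family == "logitboost":
        return LogitBoostClassifier(n_estimators=M, max_depth=depth,
                                    random_state=seed)
    raise ValueError(f"unrecognized classifier tag {tag!r}")  # unreachable


@dataclass
class ExperimentSpec:
    """A full simulation experiment: scenario, classifier panel, replicates.

    Per-replicate seeds are derived deterministically from ``seed``, so
    results are independent of execution order or batching.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    classifiers: list = field(default_factory=lambda: ["CART(5)"])
    boost: BoostConfig = field(default_factory=BoostConfig)
    replicates: int = 100
    m_grid: list = field(default_factory=lambda: [1, 10, 100])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for m in self.m_grid:
            if not 1 <= int(m) <= self.boost.M:
                raise ValueError("m_grid entries must lie in 1..M")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["sim"] = SimulationConfig(**d.get("sim", {}))
        boost = d.get("boost", {})
        if "tree" in boost:
            boost["tree"] = TreeConfig(**boost["tree"])
        d["boost"] = BoostConfig(**boost)
        return cls(**d)


def replicate_seed(master_seed: int, r: int) -> int:
    """Deterministic per-replicate substream seed, kept below 2**31."""
    return int((master_seed * 1_000_003 + r) % (2**31 - 1))


def _generate(sim: SimulationConfig, seed: int
              ) -> tuple[LabeledDataset, LabeledDataset]:
    cfg = SimulationConfig(**{**asdict(sim), "seed": seed})
    if cfg.scenario == "block-mvn":
        return simulate_block_mvn(cfg)
    if cfg.scenario == "null-independent":
        train = simulate_null_independent(cfg.p, cfg.n_train, seed)
        test = simulate_null_independent(cfg.p, 2 * cfg.n_test_per_class,
                                         seed + 1)
        return train, test
    if cfg.scenario == "variance-shift":
        return simulate_variance_shift(
            p_null=cfg.p - 20, seed=seed,
            n_train_per_class=cfg.n_train // 2,
            n_test_per_class=cfg.n_test_per_class)
    raise ValueError(f"unknown scenario {cfg.scenario!r}")


def run_experiment(spec: ExperimentSpec, output_prefix=None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every replicate of an experiment and tabulate staged metrics.

    For each replicate a fresh train/test pair is generated, every
    classifier in the panel is fit on the training set, and the test-set
    metrics are recorded at every iteration count of the grid (single
    trees only at M = 1).  Returns the per-replicate tidy table and the
    mean ± SD summary.  Replicates whose fits fail are skipped and
    counted; more than 10 % failures aborts the run.
    """
    rows = []
    failures = 0
    for r in range(spec.replicates):
        seed_r = replicate_seed(spec.seed, r)
        try:
            train, test = _generate(spec.sim, seed_r)
            for tag in spec.classifiers:
                cfg = BoostConfig(M=spec.boost.M, nu=spec.boost.nu,
                                  eta=spec.boost.eta,
                                  icv_folds=spec.boost.icv_folds,
                                  tree=spec.boost.tree, seed=seed_r)
                model = make_classifier(tag, cfg)
                model.fit(train.X, train.y)
                grid = ([1] if isinstance(model, CARTClassifier)
                        else [int(m) for m in spec.m_grid])
                labels, scores = staged_predict(model, test.X, grid)
                for k, m in enumerate(grid):
                    rec = accuracy_metrics(test.y, labels[k], scores[k],
                                           classifier=tag, M=m)
                    row = rec.as_dict()
                    row["replicate"] = r
                    rows.append(row)
        except Exception:
            failures += 1
            if failures > MAX_FAILED_FRACTION * spec.replicates:
                raise RuntimeError(
                    f"{failures} of {spec.replicates} replicates failed")
    per_rep = pd.DataFrame(rows)
    metric_cols = ["PA", "PA1", "PA2", "AUC", "gmeans", "test_error"]
    summary = (per_rep.groupby(["classifier", "M"])[metric_cols]
               .agg(["mean", "std"]))
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    summary = summary.reset_index()
    if output_prefix is not None:
        per_rep.to_csv(f"{output_prefix}_replicates.csv", index=False)
        summary.to_csv(f"{output_prefix}_summary.csv", index=False)
        meta = {"spec": {**asdict(spec.sim)}, "replicates": spec.replicates,
                "m_grid": [int(m) for m in spec.m_grid],
                "classifiers": list(spec.classifiers),
                "master_seed": spec.seed, "failed_replicates": failures}
        with open(f"{output_prefix}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)
    return per_rep, summary


def repeated_cv_evaluate(data: LabeledDataset, classifiers, folds: int = 5,
                         repeats: int = 50, seed: int = 0,
                         config: BoostConfig | None = None) -> pd.DataFrame:
    """Repeated stratified k-fold CV with per-run majority down-sizing.

    In every CV run the training folds are first balanced by randomly
    down-sizing their majority class; held-out predictions are pooled
    across the ``folds`` folds of a repeat and summarized into one set of
    metrics per repeat and classifier.  Returns mean and SD over repeats.
    """
    from .boosting import stratified_folds  # shared fold machinery

    config = config or BoostConfig()
    records = []
    for rep in range(repeats):
        rep_seed = replicate_seed(seed, rep)
        rng = np.random.default_rng(rep_seed)
        fold_sets = stratified_folds(data.y, folds, rng)
        preds = {tag: np.zeros(data.n_samples, dtype=np.int64)
                 for tag in classifiers}
        scores = {tag: np.zeros(data.n_samples) for tag in classifiers}
        for hold in fold_sets:
            fit_idx = np.setdiff1d(np.arange(data.n_samples), hold,
                                   assume_unique=True)
            train = LabeledDataset(data.X[fit_idx], data.y[fit_idx])
            train = downsize_majority(train,
                                      seed=replicate_seed(rep_seed, hold[0]))
            for tag in classifiers:
                cfg = BoostConfig(M=config.M, nu=config.nu, eta=config.eta,
                                  icv_folds=config.icv_folds,
                                  tree=config.tree, seed=rep_seed)
                model = make_classifier(tag, cfg).fit(train.X, train.y)
                preds[tag][hold] = model.predict(data.X[hold])
                scores[tag][hold] = model.decision_function(data.X[hold])
        for tag in classifiers:
            rec = accuracy_metrics(data.y, preds[tag], scores[tag],
                                   classifier=tag, M=config.M)
            row = rec.as_dict()
            row["repeat"] = rep
            records.append(row)
    per_repeat = pd.DataFrame(records)
    metric_cols = ["PA", "PA1", "PA2", "AUC", "gmeans", "test_error"]
    out = per_repeat.groupby("classifier")[metric_cols].agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()


__all__ = ["CARTClassifier", "ExperimentSpec", "make_classifier",
           "replicate_seed", "run_experiment", "repeated_cv_evaluate",
           "records_to_frame"]
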