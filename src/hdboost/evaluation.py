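"""Performance measures, boosting-iteration selection, and classifier ranking.

Five accuracy measures are tracked: overall predictive accuracy (PA),
class-specific accuracies (PA1, PA2), AUC, and g-means — the geometric
mean ``sqrt(PA1 * PA2)``, which penalizes classifiers that sacrifice one
class.  Two data-driven rules pick the number of boosting iterations:
k-fold cross-validation (with the smallest minimizer under ties) and,
for stochastic gradient boosting, the out-of-bag improvement rule.
Classifier comparison across simulation settings uses per-setting ranks
and paired Wilcoxon signed-rank tests with Holm adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .boosting import BoostConfig, stratified_folds
from .datasets import LabeledDataset

#: Number of paired settings up to which the Wilcoxon null is enumerated
#: exactly; the normal approximation is used beyond.
EXACT_WILCOXON_MAX_N = 25


@dataclass
class MetricsRecord:
    """One classifier's accuracy measures at one iteration count.

    ``test_error = 1 - PA`` and ``gmeans = sqrt(PA1 * PA2)``; PA1/PA2/AUC
    are NaN when the truth contains a single class (undefined).
    """

    PA: float
    PA1: float
    PA2: float
    AUC: float
    gmeans: float
    test_error: float
    classifier: str = ""
    M: int = 0

    def as_dict(self) -> dict:
        return {"classifier": self.classifier, "M": self.M, "PA": self.PA,
                "PA1": self.PA1, "PA2": self.PA2, "AUC": self.AUC,
                "gmeans": self.gmeans, "test_error": self.test_error}


def accuracy_metrics(y_true, y_pred, scores=None, classifier: str = "",
                     M: int = 0) -> MetricsRecord:
    """PA, class-wise accuracies, AUC and g-means for one prediction set.

    ``scores`` are real-valued with larger values indicating class 2; AUC
    is the Mann–Whitney rank statistic with midrank tie handling.  With a
    one-class truth only PA is defined; the rest are NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pa = float(np.mean(y_pred == y_true))
    is1, is2 = y_true == 1, y_true == 2
    if is1.any() and is2.any():
        pa1 = float(np.mean(y_pred[is1] == 1))
        pa2 = float(np.mean(y_pred[is2] == 2))
        gmeans = float(np.sqrt(pa1 * pa2))
        auc = (float(roc_auc_score(is2.astype(int), np.asarray(scores)))
               if scores is not None else float("nan"))
    else:
        pa1 = pa2 = gmeans = auc = float("nan")
    return MetricsRecord(PA=pa, PA1=pa1, PA2=pa2, AUC=auc, gmeans=gmeans,
                         test_error=1.0 - pa, classifier=classifier, M=M)


def resubstitution_error(model, data: LabeledDataset) -> float:
    """Fraction of training samples misclassified by a model fit on them."""
    return float(np.mean(model.predict(data.X) != data.y))


# ---------------------------------------------------------------------------
# choosing the number of boosting iterations
# ---------------------------------------------------------------------------

def select_m_by_cv(data: LabeledDataset, algorithm: str, config: BoostConfig,
                   folds: int = 5) -> tuple[int, np.ndarray]:
    """Cross-validated number of boosting iterations.

    The training set is split into ``folds`` class-stratified folds
    (``folds = n`` gives leave-one-out); each fold model is fit with the
    full M iterations and its held-out staged predictions are pooled
    across folds, giving one cross-validated error per iteration count.
    Returns the iteration with the smallest pooled error — the smallest
    such iteration under ties — together with the error curve.

    The pooled error is a step function with increments of ``1/n``, which
    is why small samples produce many ties and a downward-biased M.
    """
    from .experiments import make_classifier  # local import, no cycle at load

    n = data.n_samples
    if not 2 <= folds <= n:
        raise ValueError("folds must lie in 2..n_samples")
    rng = np.random.default_rng(config.seed)
    wrong = np.zeros(config.M)
    for hold in stratified_folds(data.y, folds, rng):
        fit_idx = np.setdiff1d(np.arange(n), hold, assume_unique=True)
        model = make_classifier(algorithm, config)
        model.fit(data.X[fit_idx], data.y[fit_idx])
        for m, pred in enumerate(model.staged_predict(data.X[hold])):
            wrong[m] += np.sum(pred != data.y[hold])
    cv_curve = wrong / n
    m_cv = int(np.argmin(cv_curve)) + 1  # argmin takes the first minimum
    return m_cv, cv_curve


def select_m_oob(model) -> int:
    """Out-of-bag stopping rule for stochastic gradient boosting.

    Returns the iteration maximizing the cumulative sum of per-iteration
    out-of-bag loss improvements (first maximizer under ties).  Requires a
    model fit with ``subsample < 1``.
    """
    if not hasattr(model, "oob_improvement_"):
        raise ValueError("model has no out-of-bag record; fit with "
                         "subsample < 1")
    cum = np.cumsum(model.oob_improvement_)
    return int(np.argmax(cum)) + 1


# ---------------------------------------------------------------------------
# ranking and paired comparison across settings
# ---------------------------------------------------------------------------

def rank_and_compare(gmeans_by_setting: pd.DataFrame,
                     reference: str) -> dict:
    """Rank classifiers per setting and test each against a reference.

    Parameters
    ----------
    gmeans_by_setting : DataFrame
        Rows = classifiers, columns = simulation settings; entries are the
        best g-means each classifier attained in that setting.
    reference : str
        Row label of the reference classifier.

    Returns
    -------
    dict with ``ranks`` (per-setting ranks, 1 = best, midranks for ties),
    ``p_raw`` / ``p_adjusted`` (two-sided paired Wilcoxon signed-rank
    p-values of every other classifier vs the reference, Holm step-down
    adjusted) and ``significant`` (adjusted p < 0.05).
    """
    if reference not in gmeans_by_setting.index:
        raise ValueError(f"unknown reference classifier {reference!r}")
    if gmeans_by_setting.shape[0] < 2:
        raise ValueError("need at least two classifiers")

    ranks = gmeans_by_setting.apply(
        lambda col: stats.rankdata(-col.to_numpy(), method="average"),
        axis=0, result_type="broadcast")

    ref_vals = gmeans_by_setting.loc[reference].to_numpy(dtype=float)
    others = [c for c in gmeans_by_setting.index if c != reference]
    p_raw = pd.Series(
        [_paired_wilcoxon(gmeans_by_setting.loc[c].to_numpy(dtype=float),
                          ref_vals) for c in others],
        index=others, name="p_raw")
    p_adj = pd.Series(
        multipletests(p_raw.to_numpy(), method="holm")[1],
        index=others, name="p_adjusted")
    return {"ranks": ranks, "p_raw": p_raw, "p_adjusted": p_adj,
            "significant": p_adj < 0.05}


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p; exact null for small n.

    All-zero differences return 1 by convention.
    """
    d = x - y
    if np.allclose(d, 0.0):
        return 1.0
    method = "exact" if d.size <= EXACT_WILCOXON_MAX_N else "approx"
    try:
        return float(stats.wilcoxon(x, y, alternative="two-sided",
                                    method=method).pvalue)
    except ValueError:
        return float(stats.wilcoxon(x, y, alternative="two-sided",
                                    method="approx").pvalue)


def records_to_frame(records) -> pd.DataFrame:
    """Tidy DataFrame from an iterable of MetricsRecord."""
    return pd.DataFrame([r.as_dict() for r in records])
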