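"""Preprocessing operators for expression-style matrices.

The operators mirror a typical microarray analysis pipeline: an unsupervised
variance pre-filter, column-wise missing-value handling (drop genes with too
many missing entries, zero-impute the rest), and majority-class down-sizing
to remove class-imbalance bias before fitting.
"""

from __future__ import annotations

import numpy as np

from .datasets import LabeledDataset


def variance_prefilter(data: LabeledDataset, k: int) -> LabeledDataset:
    """Retain the ``k`` columns with the largest sample variance.

    The filter is class-independent (it never sees the labels), so it does
    not leak outcome information.  ``k >= p`` is the identity.  Retained
    columns keep their original order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= data.n_variables:
        return LabeledDataset(data.X.copy(), data.y.copy(),
                              list(data.variable_names))
    variances = np.nanvar(data.X, axis=0, ddof=1)
    keep = np.sort(np.argsort(variances, kind="stable")[::-1][:k])
    return LabeledDataset(data.X[:, keep], data.y.copy(),
                          [data.variable_names[j] for j in keep])


def handle_missing(data: LabeledDataset,
                   max_missing_fraction: float = 0.10) -> LabeledDataset:
    """Drop columns with too many missing values; zero-impute the rest.

    A column is dropped when its missing fraction *strictly* exceeds
    ``max_missing_fraction`` (a column at exactly the threshold is kept).
    Remaining NaNs are replaced with 0.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    frac = np.mean(np.isnan(data.X), axis=0)
    keep = np.flatnonzero(frac <= max_missing_fraction)
    if keep.size == 0:
        raise ValueError("all columns exceed the missing-value threshold")
    X = np.nan_to_num(data.X[:, keep], nan=0.0)
    return LabeledDataset(X, data.y.copy(),
                          [data.variable_names[j] for j in keep])


def downsize_majority(data: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Balance the classes by random down-sizing of the majority class.

    Uniformly without replacement, ``min(n1, n2)`` majority-class samples
    are retained; the minority class is untouched.  Sample order is
    preserved.  Already-balanced data pass through unchanged.
    """
    if not data.both_classes_present():
        raise ValueError("both classes must be present")
    n1, n2 = data.class_counts()
    if n1 == n2:
        return LabeledDataset(data.X.copy(), data.y.copy(),
                              list(data.variable_names))
    minority, majority = (1, 2) if n1 < n2 else (2, 1)
    n_keep = min(n1, n2)
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(data.y == majority)
    kept_maj = rng.choice(maj_idx, size=n_keep, replace=False)
    keep = np.sort(np.concatenate(
        [np.flatnonzero(data.y == minority), kept_maj]))
    return LabeledDataset(data.X[keep], data.y[keep],
                          list(data.variable_names))
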