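"""Labeled two-class datasets and their delimited-text representation.

A :class:`LabeledDataset` is the package-wide container: a dense ``n x p``
feature matrix plus class labels coded ``1`` and ``2``.  Datasets round-trip
losslessly through TSV/CSV with a header row of variable names and a
``class`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABEL_COLUMN = "class"
VALID_LABELS = (1, 2)


@dataclass
class LabeledDataset:
    """Feature matrix ``X`` (n samples x p variables) with labels in {1, 2}.

    Missing values (NaN) are permitted only when injected deliberately, e.g.
    to exercise the missing-value preprocessing rules; the simulators never
    produce them.
    """

    X: np.ndarray
    y: np.ndarray
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if not np.isin(self.y, VALID_LABELS).all():
            raise ValueError("labels must take values in {1, 2}")
        if not self.variable_names:
            self.variable_names = [f"V{j + 1}" for j in range(self.X.shape[1])]
        elif len(self.variable_names) != self.X.shape[1]:
            raise ValueError("variable_names length must match column count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """Counts of class-1 and class-2 samples, in that order."""
        return int(np.sum(self.y == 1)), int(np.sum(self.y == 2))

    def both_classes_present(self) -> bool:
        n1, n2 = self.class_counts()
        return n1 > 0 and n2 > 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.variable_names)
        df[LABEL_COLUMN] = self.y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        if LABEL_COLUMN not in df.columns:
            raise ValueError(f"missing required column {LABEL_COLUMN!r}")
        y = df[LABEL_COLUMN].to_numpy(dtype=np.int64)
        feats = df.drop(columns=[LABEL_COLUMN])
        return cls(feats.to_numpy(dtype=np.float64), y, list(feats.columns))

    def write(self, path, sep: str = "\t") -> None:
        """Write as delimited text at full double precision (lossless)."""
        self.to_frame().to_csv(path, sep=sep, index=False,
                               float_format="%.17g")

    @classmethod
    def read(cls, path, sep: str = "\t") -> "LabeledDataset":
        # round_trip parsing keeps the write/read cycle bit-exact
        return cls.from_frame(pd.read_csv(path, sep=sep,
                                          float_precision="round_trip"))
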