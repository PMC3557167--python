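"""Expression-matrix container and TSV I/O.

The expected input is a genes x conditions table of strictly positive,
linear-scale expression ratios (experiment / control), tab-separated with a
header row of condition labels and gene identifiers in the first column —
the shape of a classic two-channel time-course microarray dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class ExpressionMatrix:
    """Genes x conditions matrix of positive expression ratios.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifier with one column per condition,
        in experiment order. Values are linear-scale ratios; zeros or
        negatives are tolerated on input and floored downstream before any
        log transform.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise ValueError("expression matrix must be non-empty")
        if data.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")
        if data.columns.has_duplicates:
            raise ValueError("duplicate condition labels in expression matrix")
        self.data = data.astype(float)

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def conditions(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    @property
    def universe(self) -> set[str]:
        return set(self.genes)

    def values_for(self, condition: str) -> np.ndarray:
        if condition not in self.data.columns:
            raise KeyError(f"unknown condition label: {condition!r}")
        return self.data[condition].to_numpy()

    def median(self) -> float:
        return float(np.median(self.data.to_numpy()))

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({self.data.shape[0]} genes x "
            f"{self.data.shape[1]} conditions)"
        )
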