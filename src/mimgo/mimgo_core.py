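"""Matrix-assisted identification of differentially expressed gene sets.

For each gene set, the K x K comparison matrix marks cell (i, j) when the
set's genes are significantly more upregulated in condition i than in
condition j (positive-direction enrichment q below a threshold). A row
densely marked with 1 means concerted upregulation in that condition; a
densely marked column means concerted downregulation.

Each row and column (a "line") is tested for enrichment of marks with the
upper-tail hypergeometric probability

    p = sum_{j=x}^{min(n, M)} C(n, j) C(N-n, M-j) / C(N, M)

where N = K(K-1) is the number of off-diagonal cells, M the total marks,
n = K-1 the cells in the line, and x the marks in the line. The multiple
comparisons over lines are corrected with the percentage false discovery
rate 100 * MC * p / PN, where MC is the number of lines tested per
direction (= K) and PN the number of lines with p < alpha in that
direction. Lines with FDR below the cutoff define the conditions of
up-/down-regulation; a term with at least one such line is differentially
expressed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .enrichment_core import PairEnrichmentTensor

__all__ = [
    "ComparisonMatrix",
    "LineTest",
    "MatrixDecision",
    "MimgoResult",
    "binarize",
    "eq1_row_p",
    "eq2_fdr",
    "decide_matrix",
    "run_mimgo",
]


@dataclass
class ComparisonMatrix:
    """Per-term K x K binary mark matrix; the diagonal is undefined."""

    term_id: str
    conditions: list[str]
    cells: np.ndarray
    q_threshold: float

    def __post_init__(self):
        k = len(self.conditions)
        self.cells = np.asarray(self.cells, dtype=int)
        if self.cells.shape != (k, k):
            raise ValueError("cells must be K x K")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be 0/1")
        if np.diag(self.cells).any():
            raise ValueError("diagonal cells must not be marked")

    @property
    def k(self) -> int:
        return len(self.conditions)

    @property
    def total_marks(self) -> int:
        return int(self.cells.sum())

    def to_tsv(self, path) -> None:
        """0/1 grid with condition labels, diagonal shown as '-'."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.conditions) + "\n")
            for i, row_label in enumerate(self.conditions):
                vals = ["-" if i == j else str(int(self.cells[i, j]))
                        for j in range(self.k)]
                fh.write(row_label + "\t" + "\t".join(vals) + "\n")


def binarize(tensor: PairEnrichmentTensor, term_id: str,
             q_threshold: float) -> ComparisonMatrix:
    """Mark cell (i, j) when the positive-direction q for pair i -> j is
    below the threshold."""
    if not 0 < q_threshold < 1:
        raise ValueError("q_threshold must be in (0, 1)")
    conds = tensor.conditions
    k = len(conds)
    cells = np.zeros((k, k), dtype=int)
    for i, row in enumerate(conds):
        for j, col in enumerate(conds):
            if i == j:
                continue
            res = tensor.get(term_id, row, col)
            if res.es > 0 and res.q_fdr < q_threshold:
                cells[i, j] = 1
    return ComparisonMatrix(term_id, conds, cells, q_threshold)


def eq1_row_p(N: int, M: int, n: int, x: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    Population of N cells, M marked, n drawn (the line); probability of
    seeing at least x marks in the line under uniform mark placement.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= x <= min(n, M)):
        raise ValueError(f"invalid arguments N={N} M={M} n={n} x={x}")
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, N, M, n))


def eq2_fdr(MC: int, p: float, PN: int) -> float:
    """Percentage false discovery rate 100 * MC * p / PN.

    May exceed 100%; reported raw (a warning is emitted when it does).
    """
    if MC < 1:
        raise ValueError("MC must be >= 1")
    if PN < 1:
        raise ValueError("PN must be >= 1 (no significant lines otherwise)")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    fdr = 100.0 * MC * p / PN
    if fdr > 100.0:
        warnings.warn(f"FDR exceeds 100% ({fdr:.3g}); reported raw")
    return fdr


@dataclass
class LineTest:
    """Hypergeometric test of one matrix line (row or column)."""

    line_kind: str          # "row" (upregulation) or "column" (downregulation)
    line_label: str
    N: int
    M: int
    n: int
    x: int
    p: float
    fdr_percent: float | None
    significant: bool


@dataclass
class MatrixDecision:
    """Outcome of testing one term's comparison matrix."""

    term_id: str
    MC: int
    PN_rows: int
    PN_columns: int
    up_rows: list[str]
    down_columns: list[str]
    min_marks_ok: bool
    line_tests: list[LineTest] = field(default_factory=list)

    @property
    def is_differentially_expressed(self) -> bool:
        return bool(self.up_rows or self.down_columns)


def _test_lines(matrix: ComparisonMatrix, axis: int, alpha: float,
                fdr_cut_percent: float) -> tuple[list[LineTest], int, list[str]]:
    k = matrix.k
    N = k * (k - 1)
    M = matrix.total_marks
    n = k - 1
    counts = matrix.cells.sum(axis=1 - axis)  # axis 0 = rows, 1 = columns
    kind = "row" if axis == 0 else "column"
    p_values = [eq1_row_p(N, M, n, int(x)) for x in counts]
    PN = sum(1 for p in p_values if p < alpha)
    tests: list[LineTest] = []
    hits: list[str] = []
    for label, x, p in zip(matrix.conditions, counts, p_values):
        if p < alpha and PN >= 1:
            fdr = eq2_fdr(k, p, PN)
            sig = fdr < fdr_cut_percent
        else:
            fdr, sig = None, False
        if sig:
            hits.append(label)
        tests.append(LineTest(kind, label, N, M, n, int(x), p, fdr, sig))
    return tests, PN, hits


def decide_matrix(matrix: ComparisonMatrix, alpha: float = 0.05,
                  fdr_cut_percent: float = 5.0, min_marks: int | None = None,
                  test_columns: bool = True) -> MatrixDecision:
    """Test every row and column of one comparison matrix.

    Rows and columns are corrected separately, each with its own PN and
    MC = K. When the matrix carries fewer than ``min_marks`` marks in
    total (default K), no line is declared significant: the line test is
    meaningless on a nearly empty matrix. Setting ``test_columns`` to
    False restricts the decision to upregulation rows.
    """
    k = matrix.k
    if k < 2:
        raise ValueError("need at least two conditions")
    if min_marks is None:
        min_marks = k
    if matrix.total_marks < min_marks:
        return MatrixDecision(matrix.term_id, k, 0, 0, [], [],
                              min_marks_ok=False)
    row_tests, pn_rows, up_rows = _test_lines(matrix, 0, alpha,
                                              fdr_cut_percent)
    if test_columns:
        col_tests, pn_cols, down_cols = _test_lines(matrix, 1, alpha,
                                                    fdr_cut_percent)
    else:
        col_tests, pn_cols, down_cols = [], 0, []
    return MatrixDecision(matrix.term_id, k, pn_rows, pn_cols, up_rows,
                          down_cols, min_marks_ok=True,
                          line_tests=row_tests + col_tests)


@dataclass
class MimgoResult:
    """Decisions for every term of a tensor at one q-value threshold."""

    q_threshold: float
    conditions: list[str]
    decisions: dict[str, MatrixDecision]
    matrices: dict[str, ComparisonMatrix]

    @property
    def de_terms(self) -> list[str]:
        return [t for t, d in self.decisions.items()
                if d.is_differentially_expressed]

    def summary(self) -> dict:
        return {
            "q_threshold": self.q_threshold,
            "n_terms": len(self.decisions),
            "n_differentially_expressed": len(self.de_terms),
            "de_terms": sorted(self.de_terms),
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("term_id\tdifferentially_expressed\tmin_marks_ok"
                     "\tup_rows\tdown_columns\ttotal_marks\n")
            for term in sorted(self.decisions):
                d = self.decisions[term]
                fh.write("\t".join([
                    term,
                    str(int(d.is_differentially_expressed)),
                    str(int(d.min_marks_ok)),
                    ",".join(d.up_rows) or "-",
                    ",".join(d.down_columns) or "-",
                    str(self.matrices[term].total_marks),
                ]) + "\n")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def run_mimgo(tensor: PairEnrichmentTensor, q_threshold: float = 0.05,
              alpha: float = 0.05, fdr_cut_percent: float = 5.0,
              min_marks: int | None = None,
              test_columns: bool = True) -> MimgoResult:
    """Binarize the tensor per term and decide every comparison matrix."""
    decisions: dict[str, MatrixDecision] = {}
    matrices: dict[str, ComparisonMatrix] = {}
    for term in tensor.term_ids:
        m = binarize(tensor, term, q_threshold)
        matrices[term] = m
        decisions[term] = decide_matrix(m, alpha=alpha,
                                        fdr_cut_percent=fdr_cut_percent,
                                        min_marks=min_marks,
                                        test_columns=test_columns)
    return MimgoResult(q_threshold, tensor.conditions, decisions, matrices)
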