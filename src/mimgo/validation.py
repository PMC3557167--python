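"""Independent check of identified up-regulation conditions.

For each flagged gene set, the mean expression of its member genes is
computed per condition; conditions whose mean exceeds the average plus one
standard deviation of those K means get an indicator bit of 1. The matrix
method's own up-regulation rows form a second bit vector, and the Pearson
correlation of the two vectors measures agreement. A high correlation over
many terms indicates that the conditions of upregulation were identified
at roughly the right places — an indication, not a sufficient condition,
since the mean-plus-SD indicator is itself only a heuristic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix
from .genesets_io import GeneSet
from .mimgo_core import MimgoResult

__all__ = [
    "ValidationRecord",
    "ValidationSummary",
    "avg_std_indicator",
    "bitvector_correlation",
    "validate_result",
    "summarize",
]


@dataclass
class ValidationRecord:
    term_id: str
    mimgo_bits: np.ndarray
    indicator_bits: np.ndarray
    avg_of_means: float
    std_of_means: float
    correlation: float | None  # None = degenerate (a constant vector)


@dataclass
class ValidationSummary:
    n_terms: int
    average_correlation: float
    std_correlation: float
    min_correlation: float
    n_above_0_9: int
    n_below_0_1: int
    n_degenerate: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def avg_std_indicator(expr: ExpressionMatrix, gene_set: GeneSet | set,
                      ddof: int = 1):
    """Per-condition upregulation indicator for one gene set.

    Returns ``(bits, avg, std)``: the per-condition means of member-gene
    expression, their average and standard deviation across the K
    conditions (sample SD by default), and bit = 1 where the mean strictly
    exceeds avg + std.
    """
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else set(gene_set)
    members = sorted(genes & expr.universe)
    if not members:
        raise ValueError("gene set does not intersect the expression matrix")
    means = expr.data.loc[members].mean(axis=0).to_numpy()
    avg = float(means.mean())
    std = float(means.std(ddof=ddof))
    bits = (means > avg + std).astype(int)
    return bits, avg, std


def bitvector_correlation(a, b) -> float | None:
    """Pearson correlation of two equal-length 0/1 vectors.

    Returns None when either vector is constant (degenerate; excluded from
    summaries and counted separately).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("vectors must have length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def validate_result(expr: ExpressionMatrix, result: MimgoResult,
                    collection, only_de: bool = True,
                    ddof: int = 1) -> list[ValidationRecord]:
    """One ValidationRecord per (differentially expressed) term.

    The comparison vector uses up-regulation rows only; columns capture
    downregulation, which the mean-plus-SD indicator does not measure.
    """
    conds = result.conditions
    records = []
    for term, dec in result.decisions.items():
        if only_de and not dec.is_differentially_expressed:
            continue
        mimgo_bits = np.array([1 if c in dec.up_rows else 0 for c in conds])
        bits, avg, std = avg_std_indicator(expr, collection[term], ddof=ddof)
        r = bitvector_correlation(mimgo_bits, bits)
        records.append(ValidationRecord(term, mimgo_bits, bits, avg, std, r))
    return records


def summarize(records: list[ValidationRecord]) -> ValidationSummary:
    """Aggregate correlations over non-degenerate records."""
    rs = np.array([r.correlation for r in records
                   if r.correlation is not None], dtype=float)
    n_degen = sum(1 for r in records if r.correlation is None)
    if rs.size == 0:
        raise ValueError("all records are degenerate")
    return ValidationSummary(
        n_terms=len(records),
        average_correlation=float(rs.mean()),
        std_correlation=float(rs.std(ddof=1)) if rs.size > 1 else 0.0,
        min_correlation=float(rs.min()),
        n_above_0_9=int((rs > 0.9).sum()),
        n_below_0_1=int((rs < 0.1).sum()),
        n_degenerate=n_degen,
    )


def write_records_tsv(records: list[ValidationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tmimgo_bits\tindicator_bits\tavg_of_means"
                 "\tstd_of_means\tcorrelation\n")
        for r in records:
            corr = "NA" if r.correlation is None else f"{r.correlation:.6g}"
            fh.write("\t".join([
                r.term_id,
                "".join(map(str, r.mimgo_bits)),
                "".join(map(str, r.indicator_bits)),
                f"{r.avg_of_means:.6g}",
                f"{r.std_of_means:.6g}",
                corr,
            ]) + "\n")
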