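"""Self-contained gene-set enrichment engine.

Implements the weighted Kolmogorov–Smirnov-style running-sum enrichment
score over a ranked gene list, a gene-set permutation null, normalized
enrichment scores (NES) and FDR q-values, and the driver that runs one
enrichment pass per ordered condition pair of an expression matrix.

Ranking metrics:

* ``log2_ratio_metric`` — per-gene log2 ratio of one condition to another
  (the two-class metric for a pairwise comparison);
* ``pearson_phenotype_metric`` — per-gene Pearson correlation with a
  continuous phenotype label (an idealized expression pattern).

Significance uses gene-set permutation only: random gene sets of the same
size are re-scored on the fixed ranking. NES normalizes each ES by the mean
magnitude of same-sign null ES; q-values compare each observed NES against
the pooled null NES distribution within one run, following the standard
signed-side GSEA convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix
from .genesets_io import GeneSet, GeneSetCollection

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "EnrichmentParams",
    "PairEnrichmentTensor",
    "log2_ratio_metric",
    "pearson_phenotype_metric",
    "enrichment_score",
    "gene_set_permutation",
    "nes_and_fdr",
    "run_single",
    "run_all_pairs",
]


@dataclass
class RankedList:
    """Genes ordered by descending metric; ties broken by gene id ascending."""

    gene_ids: np.ndarray
    metric: np.ndarray

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.metric = np.asarray(self.metric, dtype=float)
        if self.gene_ids.shape != self.metric.shape:
            raise ValueError("gene_ids and metric must have equal length")
        self._index: dict[str, int] = {
            g: i for i, g in enumerate(self.gene_ids)
        }

    def __len__(self) -> int:
        return len(self.gene_ids)

    def positions_of(self, genes) -> np.ndarray:
        """Sorted rank positions (0-based) of the given genes."""
        pos = np.array(sorted(self._index[g] for g in genes), dtype=np.int64)
        return pos


def _rank(gene_ids, metric) -> RankedList:
    gene_ids = np.asarray(gene_ids, dtype=object)
    metric = np.asarray(metric, dtype=float)
    # primary key: metric descending; secondary: gene id ascending
    order = np.lexsort((gene_ids.astype(str), -metric))
    return RankedList(gene_ids[order], metric[order])


def default_floor(expr: ExpressionMatrix) -> float:
    """Guard floor for the log2 ratio: 1e-3 of the matrix median."""
    return 1e-3 * expr.median()


def log2_ratio_metric(expr: ExpressionMatrix, row_cond: str, col_cond: str,
                      floor: float | None = None) -> RankedList:
    """Per-gene log2(row / col) on floored linear-scale ratios."""
    if floor is None:
        floor = default_floor(expr)
    if floor <= 0:
        raise ValueError("floor must be positive")
    x_row = np.maximum(expr.values_for(row_cond), floor)
    x_col = np.maximum(expr.values_for(col_cond), floor)
    return _rank(expr.genes, np.log2(x_row / x_col))


def pearson_phenotype_metric(expr: ExpressionMatrix,
                             label: np.ndarray) -> RankedList:
    """Per-gene Pearson correlation with a continuous phenotype label.

    Constant gene rows get metric 0 (flagged with a warning); a constant
    label is an error.
    """
    label = np.asarray(label, dtype=float)
    if label.shape != (expr.n_conditions,):
        raise ValueError("label length must equal the number of conditions")
    lc = label - label.mean()
    lnorm = float(np.sqrt((lc ** 2).sum()))
    if lnorm == 0:
        raise ValueError("phenotype label is constant")
    x = expr.data.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((xc ** 2).sum(axis=1))
    flat = xnorm == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant gene row(s); metric set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ lc) / (xnorm * lnorm)
    r[flat] = 0.0
    return _rank(expr.genes, r)


def _hit_weights(ranked: RankedList, exponent: float) -> np.ndarray:
    return np.abs(ranked.metric) ** exponent


def _es_from_positions(positions: np.ndarray, weights: np.ndarray,
                       n_genes: int) -> np.ndarray:
    """Enrichment scores for one or many hit-position vectors.

    ``positions``: (P, s) int array, each row the sorted 0-based rank
    positions of a candidate set; ``weights``: length-``n_genes`` array of
    |metric|^exponent in ranked order. The running sum changes only at
    hits, so its extreme is attained immediately after a hit (maximum) or
    immediately before one (minimum); only those 2s candidates are scanned.
    """
    positions = np.atleast_2d(positions)
    _, s = positions.shape
    if not 0 < s < n_genes:
        raise ValueError("set size must satisfy 0 < size < universe size")
    hw = weights[positions]
    tot = hw.sum(axis=1, keepdims=True)
    # all-zero hit weights: fall back to equal weighting (degenerate ranking)
    zero = tot[:, 0] == 0
    if zero.any():
        hw = hw.copy()
        hw[zero] = 1.0
        tot = hw.sum(axis=1, keepdims=True)
    cw = np.cumsum(hw, axis=1) / tot
    miss = (positions - np.arange(s)) / (n_genes - s)
    d_after = cw - miss
    d_before = np.concatenate(
        [np.zeros((cw.shape[0], 1)), cw[:, :-1]], axis=1) - miss
    mx = d_after.max(axis=1)          # running max is always >= 0
    mn = d_before.min(axis=1)         # running min is always <= 0
    return np.where(mx >= -mn, mx, mn)  # |tie| -> positive extreme


def enrichment_score(ranked: RankedList, gene_set: GeneSet | set,
                     exponent: float = 1.0):
    """Weighted running-sum enrichment score with its full profile.

    Returns ``(es, profile)`` where ``profile[i]`` is the running-sum value
    after processing rank position ``i``. The running sum increments by the
    normalized |metric|^exponent at member genes and decrements by
    1/(universe − set size) at non-members; ES is the signed extreme.
    """
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else set(gene_set)
    members = genes & set(ranked.gene_ids)
    n = len(ranked)
    if not members:
        raise ValueError("gene set does not intersect the ranked universe")
    if len(members) == n:
        raise ValueError("gene set equals the universe; no misses defined")
    hit = np.fromiter((g in members for g in ranked.gene_ids),
                      dtype=bool, count=n)
    w = _hit_weights(ranked, exponent) * hit
    tot = w.sum()
    if tot == 0:
        w = hit.astype(float)
        tot = w.sum()
    p_hit = np.cumsum(w) / tot
    p_miss = np.cumsum(~hit) / (n - len(members))
    profile = p_hit - p_miss
    mx, mn = profile.max(), profile.min()
    es = mx if mx >= -mn else mn      # |tie| -> positive extreme
    return float(es), profile


def gene_set_permutation(ranked: RankedList, set_size: int, n_perm: int,
                         seed, exponent: float = 1.0) -> np.ndarray:
    """Null ES sample from uniformly drawn gene sets of ``set_size``.

    ``seed`` may be an int or a numpy Generator/SeedSequence; fixed seeds
    reproduce the sample bit-for-bit.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(ranked)
    if not 1 <= set_size < n:
        raise ValueError("set_size out of range")
    rng = np.random.default_rng(seed)
    # the set_size smallest of iid uniforms index a uniform random subset
    u = rng.random((n_perm, n))
    positions = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
    positions.sort(axis=1)
    w = _hit_weights(ranked, exponent)
    return _es_from_positions(positions, w, n)


@dataclass
class EnrichmentResult:
    term_id: str
    es: float
    nes: float
    p_nominal: float
    q_fdr: float
    n_perm: int
    direction: str = field(default="positive")

    def __post_init__(self):
        self.direction = "positive" if self.es >= 0 else "negative"


def _normalize(es_values: np.ndarray, mean_pos: float,
               mean_neg: float) -> np.ndarray:
    out = np.zeros_like(es_values, dtype=float)
    pos = es_values > 0
    neg = es_values < 0
    if mean_pos > 0:
        out[pos] = es_values[pos] / mean_pos
    if mean_neg > 0:
        out[neg] = es_values[neg] / mean_neg
    return out


def nes_and_fdr(observed: dict[str, float], nulls: dict[str, np.ndarray],
                n_perm: int) -> dict[str, EnrichmentResult]:
    """NES, nominal p and FDR q for one enrichment run.

    ``observed`` maps term id to ES; ``nulls`` maps term id to its null ES
    sample (terms of equal size may share one array). Nominal p uses the
    (r+1)/(n+1) estimator on the same-sign side of the term's own null.
    q compares each observed NES with the pooled null NES distribution,
    signed-side, floored at 1/n_perm and capped at 1.
    """
    missing = set(observed) - set(nulls)
    if missing:
        raise ValueError(f"terms without null samples: {sorted(missing)}")

    nes_obs: dict[str, float] = {}
    p_obs: dict[str, float] = {}
    null_nes_pool: list[np.ndarray] = []
    for term, es in observed.items():
        null = np.asarray(nulls[term], dtype=float)
        if np.all(null == 0):
            warnings.warn(f"term {term}: all-zero null sample")
        pos = null[null > 0]
        neg = -null[null < 0]
        mean_pos = float(pos.mean()) if pos.size else 0.0
        mean_neg = float(neg.mean()) if neg.size else 0.0
        if es > 0:
            nes = es / mean_pos if mean_pos > 0 else 0.0
            r = int((pos >= es).sum())
        elif es < 0:
            nes = es / mean_neg if mean_neg > 0 else 0.0
            r = int((neg >= -es).sum())
        else:
            nes, r = 0.0, null.size
        p = min(1.0, (r + 1) / (null.size + 1))
        nes_obs[term] = nes
        p_obs[term] = p
        null_nes_pool.append(_normalize(null, mean_pos, mean_neg))

    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    obs_arr = np.array(list(nes_obs.values()))
    results: dict[str, EnrichmentResult] = {}
    for term, nes in nes_obs.items():
        if nes > 0:
            n_pool_side = int((pool >= 0).sum())
            num = (pool >= nes).sum() / n_pool_side if n_pool_side else 0.0
            n_obs_side = int((obs_arr >= 0).sum())
            den = (obs_arr >= nes).sum() / n_obs_side if n_obs_side else 0.0
        elif nes < 0:
            n_pool_side = int((pool <= 0).sum())
            num = (pool <= nes).sum() / n_pool_side if n_pool_side else 0.0
            n_obs_side = int((obs_arr <= 0).sum())
            den = (obs_arr <= nes).sum() / n_obs_side if n_obs_side else 0.0
        else:
            results[term] = EnrichmentResult(term, observed[term], 0.0,
                                             1.0, 1.0, n_perm)
            continue
        q = num / den if den > 0 else 1.0
        q = float(np.clip(q, 1.0 / n_perm, 1.0))
        if np.all(np.asarray(nulls[term]) == 0):
            q = 1.0
        results[term] = EnrichmentResult(term, observed[term], float(nes),
                                         float(p_obs[term]), q, n_perm)
    return results


@dataclass
class EnrichmentParams:
    """Run configuration for the enrichment engine.

    ``n_perm`` gene-set permutations per run (the method's published
    setting is 1000; smaller values are fine for simulation studies),
    ``exponent`` the running-sum weight ("weighted" = 1), ``floor`` the
    positivity guard before log2 (None = 1e-3 of the matrix median).
    """

    n_perm: int = 1000
    exponent: float = 1.0
    seed: int = 0
    floor: float | None = None


def _prepare_members(ranked: RankedList,
                     collection: GeneSetCollection) -> dict[str, np.ndarray]:
    members = {}
    for s in collection:
        inter = s.genes & set(ranked.gene_ids)
        if not inter:
            raise ValueError(f"gene set {s.term_id} outside the universe")
        if len(inter) == len(ranked):
            raise ValueError(f"gene set {s.term_id} equals the universe")
        members[s.term_id] = ranked.positions_of(inter)
    return members


def run_single(ranked: RankedList, collection: GeneSetCollection,
               params: EnrichmentParams,
               rng=None) -> dict[str, EnrichmentResult]:
    """One enrichment run: all gene sets scored on one ranked list.

    Null samples are shared across terms of equal effective size (the
    gene-set permutation null depends only on set size).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    members = _prepare_members(ranked, collection)
    w = _hit_weights(ranked, params.exponent)
    n = len(ranked)
    observed = {
        t: float(_es_from_positions(pos, w, n)[0])
        for t, pos in members.items()
    }
    sizes = sorted({len(pos) for pos in members.values()})
    null_by_size = {
        s: gene_set_permutation(ranked, s, params.n_perm, rng,
                                params.exponent)
        for s in sizes
    }
    nulls = {t: null_by_size[len(pos)] for t, pos in members.items()}
    return nes_and_fdr(observed, nulls, params.n_perm)


class PairEnrichmentTensor:
    """Enrichment results indexed by (term, row condition, col condition).

    Diagonal pairs are absent: each ordered pair (i, j), i != j, is one
    independent enrichment run with its own permutation null and q-values.
    """

    def __init__(self, conditions: list[str], term_ids: list[str],
                 results: dict[tuple[str, str, str], EnrichmentResult]):
        self.conditions = list(conditions)
        self.term_ids = list(term_ids)
        self.results = results

    def get(self, term_id: str, row_cond: str, col_cond: str) -> EnrichmentResult:
        key = (term_id, row_cond, col_cond)
        if key not in self.results:
            raise KeyError(f"missing pair result: {key}")
        return self.results[key]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("term_id\trow_cond\tcol_cond\tes\tnes\tp\tq\tn_perm\n")
            for (t, r, c) in sorted(self.results):
                e = self.results[(t, r, c)]
                fh.write(f"{t}\t{r}\t{c}\t{e.es:.10g}\t{e.nes:.10g}"
                         f"\t{e.p_nominal:.10g}\t{e.q_fdr:.10g}\t{e.n_perm}\n")

    @classmethod
    def read_tsv(cls, path) -> "PairEnrichmentTensor":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"term_id": str,
                                                "row_cond": str,
                                                "col_cond": str})
        results = {}
        for rec in df.itertuples(index=False):
            results[(rec.term_id, rec.row_cond, rec.col_cond)] = (
                EnrichmentResult(rec.term_id, rec.es, rec.nes, rec.p,
                                 rec.q, int(rec.n_perm)))
        conds = sorted({r for (_, r, _) in results}
                       | {c for (_, _, c) in results})
        terms = sorted({t for (t, _, _) in results})
        return cls(conds, terms, results)


def run_all_pairs(expr: ExpressionMatrix, collection: GeneSetCollection,
                  params: EnrichmentParams) -> PairEnrichmentTensor:
    """One enrichment run per ordered condition pair (the K x (K-1) cells).

    Each pair gets an independent substream of the master seed, so the
    whole tensor is reproducible bit-for-bit and insensitive to pair
    evaluation order.
    """
    conds = expr.conditions
    if len(conds) < 2:
        raise ValueError("need at least two conditions")
    floor = params.floor if params.floor is not None else default_floor(expr)
    pairs = [(r, c) for r in conds for c in conds if r != c]
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(len(pairs))
    results: dict[tuple[str, str, str], EnrichmentResult] = {}
    for (row, col), child in zip(pairs, children):
        ranked = log2_ratio_metric(expr, row, col, floor=floor)
        run = run_single(ranked, collection, params,
                         rng=np.random.default_rng(child))
        for term, res in run.items():
            results[(term, row, col)] = res
    return PairEnrichmentTensor(conds, collection.term_ids, results)
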