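import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimgo.enrichment_core import (EnrichmentParams, RankedList,
                                   enrichment_score, gene_set_permutation,
                                   log2_ratio_metric, nes_and_fdr,
                                   pearson_phenotype_metric, run_all_pairs,
                                   run_single)
from mimgo.genesets_io import GeneSet, GeneSetCollection

# ---------------------------------------------------------------- metrics


def test_log2_ratio_values(tiny_expr):
    ranked = log2_ratio_metric(tiny_expr, "c1", "c2", floor=1e-6)
    by_gene = dict(zip(ranked.gene_ids, ranked.metric))
    assert by_gene["g1"] == pytest.approx(2.0)     # 4 / 1
    assert by_gene["g2"] == pytest.approx(0.0)     # 1 / 1
    assert by_gene["g5"] == pytest.approx(-1.0)    # 0.5 / 1


def test_log2_ratio_ordering_matches_hand_computation(tiny_expr):
    ranked = log2_ratio_metric(tiny_expr, "c1", "c2", floor=1e-6)
    hand = sorted(
        tiny_expr.genes,
        key=lambda g: (-math.log2(tiny_expr.data.loc[g, "c1"]
                                  / tiny_expr.data.loc[g, "c2"]), g),
    )
    assert list(ranked.gene_ids) == hand
    assert all(a >= b for a, b in zip(ranked.metric, ranked.metric[1:]))


def test_log2_ratio_unknown_condition(tiny_expr):
    with pytest.raises(KeyError):
        log2_ratio_metric(tiny_expr, "c1", "nope")


def test_metric_ties_broken_by_gene_id(tiny_expr):
    ranked = log2_ratio_metric(tiny_expr, "c1", "c1", floor=1e-6)
    assert list(ranked.gene_ids) == sorted(tiny_expr.genes)


def test_pearson_metric_tracks_label(tiny_expr):
    label = tiny_expr.data.loc["g1"].to_numpy()  # gene equal to the label
    ranked = pearson_phenotype_metric(tiny_expr, label)
    by_gene = dict(zip(ranked.gene_ids, ranked.metric))
    assert by_gene["g1"] == pytest.approx(1.0)


def test_pearson_metric_anti_tracking_gene():
    import pandas as pd

    from mimgo.expression import ExpressionMatrix

    label = np.array([1.0, 2.0, 3.0])
    data = pd.DataFrame({"c1": [3.0], "c2": [2.0], "c3": [1.0]},
                        index=["g"])
    ranked = pearson_phenotype_metric(ExpressionMatrix(data), label)
    assert ranked.metric[0] == pytest.approx(-1.0)


def test_pearson_metric_published_vector():
    """A gene whose expression equals the idealized two-peak 18-point
    pattern correlates perfectly with it."""
    import pandas as pd

    from mimgo.expression import ExpressionMatrix
    from mimgo.synthetic_data import PHENOTYPE_VECTORS, default_conditions

    vec = PHENOTYPE_VECTORS["class1"].astype(float)
    data = pd.DataFrame([vec], index=["g"], columns=default_conditions())
    ranked = pearson_phenotype_metric(ExpressionMatrix(data), vec)
    assert ranked.metric[0] == pytest.approx(1.0)


def test_pearson_constant_label_rejected(tiny_expr):
    with pytest.raises(ValueError):
        pearson_phenotype_metric(tiny_expr, np.ones(3))


def test_pearson_constant_gene_flagged_zero():
    import pandas as pd

    from mimgo.expression import ExpressionMatrix

    data = pd.DataFrame({"c1": [1.0, 1.0], "c2": [2.0, 1.0],
                         "c3": [3.0, 1.0]}, index=["g1", "flat"])
    with pytest.warns(UserWarning, match="constant"):
        ranked = pearson_phenotype_metric(ExpressionMatrix(data),
                                          np.array([1.0, 2.0, 3.0]))
    assert dict(zip(ranked.gene_ids, ranked.metric))["flat"] == 0.0


# ---------------------------------------------------------------- ES


def _ranked(ids, metric):
    return RankedList(np.array(ids, dtype=object), np.array(metric))


def test_es_single_member_first_is_one():
    rl = _ranked(list("abcd"), [3.0, 2.0, 1.0, 0.5])
    es, _ = enrichment_score(rl, {"a"})
    assert es == pytest.approx(1.0)


def test_es_single_member_last_is_minus_one():
    rl = _ranked(list("abcd"), [3.0, 2.0, 1.0, 0.5])
    es, _ = enrichment_score(rl, {"d"})
    assert es == pytest.approx(-1.0)


def test_es_hand_computed_five_gene_unit_weights():
    # hits at positions 0 and 3 (0-based), exponent 0 -> unit weights
    # profile: 1/2, 1/2-1/3, 1/2-2/3, 1-2/3, 0 -> extreme = +1/2
    rl = _ranked(list("abcde"), [5.0, 4.0, 3.0, 2.0, 1.0])
    es, profile = enrichment_score(rl, {"a", "d"}, exponent=0.0)
    assert es == pytest.approx(0.5)
    assert profile == pytest.approx([0.5, 0.5 - 1 / 3, 0.5 - 2 / 3,
                                     1 - 2 / 3, 0.0])


def test_es_weighted_hand_computed():
    # hits a (w=4) and c (w=1); profile: 4/5, 4/5-1/3, 1-1/3, 1-2/3, 0
    rl = _ranked(list("abcde"), [4.0, 2.0, 1.0, 0.5, 0.25])
    es, profile = enrichment_score(rl, {"a", "c"}, exponent=1.0)
    assert es == pytest.approx(0.8)
    assert profile[2] == pytest.approx(1.0 - 1 / 3)


def test_es_errors_on_degenerate_sets():
    rl = _ranked(list("abc"), [2.0, 1.0, 0.5])
    with pytest.raises(ValueError):
        enrichment_score(rl, {"z"})
    with pytest.raises(ValueError):
        enrichment_score(rl, {"a", "b", "c"})


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.data())
def test_es_bounds_and_batch_profile_agreement(data):
    """|ES| <= 1 always, and the hit-position fast path equals the full
    running-sum profile extreme."""
    n = data.draw(st.integers(4, 30))
    metric = data.draw(st.lists(
        st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n))
    size = data.draw(st.integers(1, n - 1))
    ids = [f"g{i:03d}" for i in range(n)]
    rl = RankedList(*map(np.asarray, (np.array(ids, dtype=object),
                                      sorted(metric, reverse=True))))
    members = set(data.draw(st.permutations(ids))[:size])
    es, _ = enrichment_score(rl, members, exponent=1.0)
    assert -1.0 <= es <= 1.0

    from mimgo.enrichment_core import _es_from_positions, _hit_weights
    pos = rl.positions_of(members)
    fast = _es_from_positions(pos, _hit_weights(rl, 1.0), n)[0]
    assert fast == pytest.approx(es)


def test_es_sign_flips_with_reversed_ranking_exponent_zero():
    rl = _ranked(list("abcde"), [5.0, 4.0, 3.0, 2.0, 1.0])
    rev = _ranked(list("edcba"), [-1.0, -2.0, -3.0, -4.0, -5.0])
    for members in ({"a", "d"}, {"b"}, {"c", "e"}):
        es_f, _ = enrichment_score(rl, members, exponent=0.0)
        es_r, _ = enrichment_score(rev, members, exponent=0.0)
        assert es_r == pytest.approx(-es_f)


# ---------------------------------------------------------------- permutation


def test_permutation_deterministic_under_seed():
    rl = _ranked([f"g{i}" for i in range(20)], np.linspace(2, -2, 20))
    a = gene_set_permutation(rl, 5, 10, seed=42)
    b = gene_set_permutation(rl, 5, 10, seed=42)
    assert np.array_equal(a, b)
    c = gene_set_permutation(rl, 5, 10, seed=43)
    assert not np.array_equal(a, c)


def test_permutation_set_size_out_of_range():
    rl = _ranked(list("abcd"), [2.0, 1.0, 0.0, -1.0])
    with pytest.raises(ValueError):
        gene_set_permutation(rl, 4, 10, seed=0)
    with pytest.raises(ValueError):
        gene_set_permutation(rl, 0, 10, seed=0)


def test_permutation_null_matches_exhaustive_enumeration():
    """Universe of 4, sets of 2: the sampled null must hit exactly the 6
    enumerable ES values with near-uniform frequencies."""
    ids = list("abcd")
    metric = [2.0, 1.0, -1.0, -2.0]
    rl = _ranked(ids, metric)
    exact = sorted(
        enrichment_score(rl, set(pair), exponent=1.0)[0]
        for pair in itertools.combinations(ids, 2)
    )
    n_perm = 6000
    null = np.sort(gene_set_permutation(rl, 2, n_perm, seed=3))
    # support
    assert set(np.round(null, 12)) <= set(np.round(exact, 12))
    # frequencies within 4 sigma of binomial(1/6)
    for v in set(exact):
        freq = np.isclose(null, v).sum() / n_perm
        # multiple enumerated pairs can share one ES value
        p = sum(np.isclose(e, v) for e in exact) / 6
        se = math.sqrt(p * (1 - p) / n_perm)
        assert abs(freq - p) < 4 * se


def test_permutation_null_mean_near_zero_for_symmetric_metric():
    n = 100
    metric = np.linspace(3, -3, n)  # symmetric about zero
    rl = _ranked([f"g{i:03d}" for i in range(n)], metric)
    null = gene_set_permutation(rl, 10, 4000, seed=11)
    se = null.std() / math.sqrt(null.size)
    assert abs(null.mean()) < 4 * se + 0.02


# ---------------------------------------------------------------- NES / FDR


def test_nominal_p_continuity_floor():
    nulls = {"t": np.array([0.1, 0.2, -0.1, 0.3, -0.2])}
    res = nes_and_fdr({"t": 0.9}, nulls, n_perm=5)["t"]
    assert res.p_nominal == pytest.approx(1 / 6)


def test_zero_es_gets_q_one():
    nulls = {"t": np.array([0.1, -0.1, 0.2])}
    res = nes_and_fdr({"t": 0.0}, nulls, n_perm=3)["t"]
    assert res.q_fdr == 1.0
    assert res.nes == 0.0


def test_all_zero_null_warns_q_one():
    with pytest.warns(UserWarning, match="all-zero"):
        res = nes_and_fdr({"t": 0.5}, {"t": np.zeros(10)}, n_perm=10)["t"]
    assert res.q_fdr == 1.0


def test_missing_null_sample_rejected():
    with pytest.raises(ValueError):
        nes_and_fdr({"t": 0.5}, {}, n_perm=10)


def test_nes_fdr_matches_independent_recomputation():
    """Three-term run: q values recomputed step by step from the stored
    null samples with a from-scratch transcription of the convention."""
    rng = np.random.default_rng(5)
    observed = {"t1": 0.62, "t2": -0.55, "t3": 0.20}
    nulls = {t: rng.normal(0, 0.3, 50) for t in observed}
    out = nes_and_fdr(observed, nulls, n_perm=50)

    # independent recomputation
    def norm_side(es, null):
        pos = null[null > 0].mean()
        neg = -null[null < 0].mean()
        return es / pos if es > 0 else (es / neg if es < 0 else 0.0)

    nes = {t: norm_side(es, nulls[t]) for t, es in observed.items()}
    pool = np.concatenate([
        np.array([norm_side(v, nulls[t]) for v in nulls[t]])
        for t in observed
    ])
    obs = np.array(list(nes.values()))
    for t, v in nes.items():
        assert out[t].nes == pytest.approx(v)
        if v > 0:
            num = (pool >= v).sum() / (pool >= 0).sum()
            den = (obs >= v).sum() / (obs >= 0).sum()
        else:
            num = (pool <= v).sum() / (pool <= 0).sum()
            den = (obs <= v).sum() / (obs <= 0).sum()
        q = min(1.0, max(num / den, 1 / 50))
        assert out[t].q_fdr == pytest.approx(q)
        null = nulls[t]
        if observed[t] > 0:
            r = (null[null > 0] >= observed[t]).sum()
        else:
            r = (null[null < 0] <= observed[t]).sum()
        assert out[t].p_nominal == pytest.approx((r + 1) / 51)


# ---------------------------------------------------------------- all pairs


def _two_set_collection(genes):
    return GeneSetCollection([
        GeneSet("S1", "one", set(genes[:3])),
        GeneSet("S2", "two", set(genes[3:6])),
    ])


def test_run_all_pairs_two_conditions_two_runs(tiny_expr):
    import pandas as pd

    from mimgo.expression import ExpressionMatrix

    expr = ExpressionMatrix(tiny_expr.data[["c1", "c2"]])
    coll = GeneSetCollection([GeneSet("S1", "one", {"g1", "g2"})])
    tensor = run_all_pairs(expr, coll, EnrichmentParams(n_perm=20, seed=0))
    assert set(tensor.results) == {("S1", "c1", "c2"), ("S1", "c2", "c1")}


def test_run_all_pairs_18_conditions_yield_306_cells():
    import pandas as pd

    from mimgo.expression import ExpressionMatrix
    from mimgo.synthetic_data import default_conditions

    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(10)]
    expr = ExpressionMatrix(pd.DataFrame(
        rng.lognormal(size=(10, 18)), index=genes,
        columns=default_conditions()))
    coll = GeneSetCollection([GeneSet("S1", "one", set(genes[:3]))])
    tensor = run_all_pairs(expr, coll, EnrichmentParams(n_perm=5, seed=0))
    assert len(tensor.results) == 18 * 17


def test_tensor_deterministic_under_seed(small_sim):
    expr, coll, _ = small_sim
    params = EnrichmentParams(n_perm=25, seed=13)
    t1 = run_all_pairs(expr, coll, params)
    t2 = run_all_pairs(expr, coll, params)
    for key in t1.results:
        a, b = t1.results[key], t2.results[key]
        assert (a.es, a.nes, a.p_nominal, a.q_fdr) == \
               (b.es, b.nes, b.p_nominal, b.q_fdr)


def test_tensor_tsv_round_trip(small_tensor, tmp_path):
    p = tmp_path / "tensor.tsv"
    small_tensor.to_tsv(p)
    from mimgo.enrichment_core import PairEnrichmentTensor

    back = PairEnrichmentTensor.read_tsv(p)
    assert set(back.results) == set(small_tensor.results)
    key = next(iter(back.results))
    assert back.results[key].q_fdr == pytest.approx(
        small_tensor.results[key].q_fdr)
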