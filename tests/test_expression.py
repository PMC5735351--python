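import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from agingnet import (
    CountMatrix,
    DEGThresholds,
    ExpressionMatrix,
    SimConfig,
    call_degs,
    compare_experiments,
    compute_rpkm,
    simulate_expression,
    venn_partition,
)


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------


def _matrix(counts: dict, lengths: dict, groups: dict, genes=None) -> CountMatrix:
    df = pd.DataFrame(counts)
    if genes is not None:
        df.index = genes
    return CountMatrix(
        counts=df,
        gene_length_bp=pd.Series(lengths),
        group_of=groups,
    )


def test_rpkm_hand_example():
    # count 10, length 2000 bp, library 1e6 reads -> 10*1e9/(2000*1e6) = 5.0
    cm = _matrix(
        {"s1": [10, 999_990]},
        {"g1": 2000, "g2": 1000},
        {"s1": "a"},
        genes=["g1", "g2"],
    )
    em = compute_rpkm(cm)
    assert em.rpkm.loc["g1", "s1"] == pytest.approx(5.0)


def test_rpkm_zero_count_gives_zero_and_scale_invariance(toy_counts):
    em = compute_rpkm(toy_counts)
    assert em.rpkm.loc["GeneB", "s1"] == 0.0
    doubled = CountMatrix(
        counts=toy_counts.counts * 2,
        gene_length_bp=toy_counts.gene_length_bp,
        group_of=toy_counts.group_of,
    )
    em2 = compute_rpkm(doubled)
    assert np.allclose(em.rpkm, em2.rpkm)


def test_rpkm_zero_library_names_sample():
    cm = _matrix({"s1": [0, 0], "s2": [1, 1]}, {0: 100, 1: 100},
                 {"s1": "a", "s2": "b"})
    with pytest.raises(ValueError, match="s1"):
        compute_rpkm(cm)


# ---------------------------------------------------------------------------
# DEG calling
# ---------------------------------------------------------------------------


def _expr(rows: dict[str, list[float]], n_ref: int, n_alt: int) -> ExpressionMatrix:
    samples = [f"r{i}" for i in range(n_ref)] + [f"a{i}" for i in range(n_alt)]
    groups = {s: ("ref" if s.startswith("r") else "alt") for s in samples}
    return ExpressionMatrix(
        rpkm=pd.DataFrame.from_dict(rows, orient="index", columns=samples),
        group_of=groups,
    )


def test_threshold_conjunction_up_vs_ns():
    th = DEGThresholds(fc_up=1.5, fc_down=0.67, p_max=0.05)
    em = _expr(
        {
            # clean 1.6x shift, tiny variance -> UP
            "strong": [100, 101, 99, 100, 160, 161, 159, 160],
            # same mean ratio but huge within-group scatter -> p too large, NS
            "noisy": [10, 190, 40, 160, 320, 1, 190, 130],
        },
        n_ref=4,
        n_alt=4,
    )
    result = call_degs(em, "ref", "alt", th)
    assert result.table.loc["strong", "status"] == "UP"
    assert result.table.loc["strong", "fold_change"] > 1.5
    assert result.table.loc["noisy", "status"] == "NS"


def test_identical_group_values_are_not_calls():
    em = _expr({"flat": [1, 2, 3, 1, 2, 3]}, n_ref=3, n_alt=3)
    result = call_degs(em, "ref", "alt")
    assert result.table.loc["flat", "fold_change"] == pytest.approx(1.0)
    assert result.table.loc["flat", "status"] == "NS"


def test_all_zero_and_constant_genes_untestable():
    em = _expr(
        {"zero": [0, 0, 0, 0], "const": [5, 5, 5, 5]}, n_ref=2, n_alt=2
    )
    result = call_degs(em, "ref", "alt")
    assert (result.table.loc[["zero", "const"], "status"] == "UNTESTABLE").all()
    assert result.table.loc["zero", "p_value"] != result.table.loc["zero", "p_value"]


def test_small_group_rejected():
    em = _expr({"g": [1, 2, 3]}, n_ref=1, n_alt=2)
    with pytest.raises(ValueError, match="2 samples"):
        call_degs(em, "ref", "alt")


def test_up_down_disjoint_and_threshold_monotonicity():
    cm, _ = simulate_expression(SimConfig(seed=21, n_genes=400))
    em = compute_rpkm(cm)
    loose = call_degs(em, "3M", "24M", DEGThresholds(fc_up=1.5, fc_down=0.67, p_max=0.05))
    tight = call_degs(em, "3M", "24M", DEGThresholds(fc_up=2.0, fc_down=0.5, p_max=0.01))
    assert not loose.up_genes & loose.down_genes
    assert tight.up_genes <= loose.up_genes
    assert tight.down_genes <= loose.down_genes


def test_welch_and_student_both_recover_strong_effect():
    cm, truth = simulate_expression(SimConfig(seed=31, n_genes=300))
    em = compute_rpkm(cm)
    for test in ("welch", "student"):
        r = call_degs(em, "3M", "29M", DEGThresholds(test=test))
        assert len(r.up_genes & set(truth.de_genes_up)) / len(truth.de_genes_up) > 0.8


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------


def test_union_by_inclusion_exclusion_matches_published_style_counts():
    # |A| = 378, |B| = 271, |A n B| = 139  ->  |A u B| = 510
    a = {f"u{i}" for i in range(378)}
    b = {f"u{i}" for i in range(239, 510)}
    assert len(a & b) == 139
    part = venn_partition({"24M/3M": a, "29M/3M": b})
    assert part.union_size == 510
    assert len(part.intersection("24M/3M", "29M/3M")) == 139


def test_disjoint_sets_have_empty_intersection_region():
    part = venn_partition({"A": {"x"}, "B": {"y"}})
    assert part.region("A", "B") == frozenset()
    assert part.union_size == 2


def test_duplicate_labels_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        venn_partition([("A", {"x"}), ("A", {"y"})])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.sets(st.integers(0, 19), max_size=20), min_size=2, max_size=3
    )
)
def test_venn_regions_match_brute_force(sets):
    labeled = {f"S{i}": {str(x) for x in s} for i, s in enumerate(sets)}
    part = venn_partition(labeled)
    union = set().union(*labeled.values())
    # brute force: classify each element by its exact membership pattern
    for r in range(1, len(labeled) + 1):
        for combo in itertools.combinations(labeled, r):
            inside = set(combo)
            expected = {
                e for e in union
                if {l for l in labeled if e in labeled[l]} == inside
            }
            assert part.region(*combo) == expected
    assert part.union_size == len(union)


# ---------------------------------------------------------------------------
# cross-experiment comparison
# ---------------------------------------------------------------------------


def test_disjoint_sets_report_zero_overlap():
    report = compare_experiments({"A1", "A2"}, {"B1", "B2"})
    assert report.n_overlap == 0 and report.jaccard == 0.0


def test_identical_sets_have_jaccard_one():
    report = compare_experiments({"A", "B"}, {"a", "b"})
    assert report.jaccard == 1.0


def test_hypergeometric_tail_matches_enumeration():
    universe = {f"g{i}" for i in range(20)}
    a = {f"g{i}" for i in range(5)}
    b = {f"g{i}" for i in range(2, 7)}
    assert len(a & b) == 3
    report = compare_experiments(a, b, universe)
    expected = sum(stats.hypergeom.pmf(k, 20, 5, 5) for k in range(3, 6))
    assert report.p_hypergeometric == pytest.approx(expected)


def test_universe_must_cover_both_sets():
    with pytest.raises(ValueError, match="universe"):
        compare_experiments({"A"}, {"B"}, universe={"A"})
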