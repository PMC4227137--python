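"""Running-sum enrichment score, permutation FWER and signature refinement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paritysig import (
    GeneSignature,
    GseaPermutationTest,
    RankedList,
    SignatureEntry,
    leading_edge,
    permutation_fwer,
    rank_genes,
    refine_signature,
    running_es,
)

LABELS6 = np.array(["nulliparous"] * 3 + ["parous"] * 3)


def _ranked(metrics, genes=None):
    metrics = np.asarray(metrics, dtype=float)
    genes = genes or [chr(ord("a") + i) for i in range(len(metrics))]
    return RankedList(np.asarray(genes), metrics)


def _sig(*genes):
    return GeneSignature("s", tuple(SignatureEntry(g) for g in genes))


def test_ranking_metric_is_pooled_t():
    m = pd.DataFrame([[1, 2, 3, 3, 4, 5]], index=["g"], columns=list("uvwxyz"),
                     dtype=float)
    ranked = rank_genes(m, LABELS6)
    assert ranked.metric[0] == pytest.approx(2.449489742783178, abs=1e-12)


def test_identical_groups_rank_in_symbol_order(rng):
    vals = np.tile(rng.normal(size=(4, 1)), (1, 6))
    m = pd.DataFrame(vals, index=["d", "b", "a", "c"], columns=list("uvwxyz"))
    ranked = rank_genes(m, LABELS6)
    assert list(ranked.genes) == ["a", "b", "c", "d"]
    np.testing.assert_array_equal(ranked.metric, 0.0)


def test_negating_one_group_reverses_the_order(rng):
    m = pd.DataFrame(rng.normal(size=(10, 6)),
                     index=[f"g{i}" for i in range(10)], columns=list("uvwxyz"))
    ranked = rank_genes(m, LABELS6)
    flipped = m.copy()
    flipped.loc[:, ["x", "y", "z"]] = -flipped.loc[:, ["x", "y", "z"]] \
        + 2 * flipped.loc[:, ["x", "y", "z"]].mean().mean()
    # simpler and exact: negate all values, swapping the sign of every metric
    neg = rank_genes(-m, LABELS6)
    np.testing.assert_allclose(np.sort(neg.metric), np.sort(-ranked.metric), atol=1e-9)


def test_running_sum_hand_walked_example():
    run = running_es(_ranked([3, 1, -1, -3]), {"a", "d"}, weight_p=1.0)
    np.testing.assert_allclose(run.running, [0.5, 0.0, -0.5, 0.0], atol=1e-12)
    assert run.es == 0.5  # tie between +0.5 and -0.5 resolves positive
    assert run.peak_index == 0
    assert list(run.hit_positions) == [0, 3]


def test_single_gene_set_at_extremes():
    ranked = _ranked([5, 2, 1, 0.5])
    assert running_es(ranked, {"a"}).es == 1.0
    assert running_es(ranked, {"d"}).es == -1.0


@given(st.integers(0, 2 ** 31 - 1), st.integers(1, 9))
def test_running_sum_ends_at_zero_and_es_bounded(seed, n_hits):
    rng = np.random.default_rng(seed)
    n = 30
    ranked = _ranked(np.sort(rng.normal(size=n))[::-1],
                     genes=[f"g{i}" for i in range(n)])
    hits = rng.choice(ranked.genes, size=n_hits, replace=False)
    run = running_es(ranked, set(hits), weight_p=1.0)
    assert abs(run.running[-1]) < 1e-9
    assert abs(run.es) <= 1.0 + 1e-12


def test_es_with_p_zero_invariant_to_magnitude_rescaling():
    metrics = np.array([4.0, 2.0, 1.0, -1.0, -5.0])
    sig = {"b", "d"}
    es0 = running_es(_ranked(metrics), sig, weight_p=0.0).es
    es0_scaled = running_es(_ranked(metrics * 7), sig, weight_p=0.0).es
    assert es0 == pytest.approx(es0_scaled, abs=1e-12)
    es1 = running_es(_ranked(metrics), sig, weight_p=1.0).es
    es1_cubed = running_es(_ranked(np.sign(metrics) * np.abs(metrics) ** 3), sig, 1.0).es
    assert es1 != pytest.approx(es1_cubed, abs=1e-6)


def test_degenerate_gene_sets_are_rejected():
    ranked = _ranked([2, 1, -1])
    with pytest.raises(ValueError, match="intersect"):
        running_es(ranked, {"zz"})
    with pytest.raises(ValueError, match="whole ranked list"):
        running_es(ranked, {"a", "b", "c"})


def test_leading_edge_positive_and_negative_cases():
    ranked = _ranked([3, 1, -1, -3])
    run = running_es(ranked, {"a", "d"})
    assert leading_edge(run, ranked) == ["a"]
    ranked2 = _ranked([5, 2, 1, 0.5])
    assert leading_edge(running_es(ranked2, {"a"}), ranked2) == ["a"]
    assert leading_edge(running_es(ranked2, {"d"}), ranked2) == ["d"]


def test_refine_signature_intersection_in_first_list_order():
    refined = refine_signature([["A", "B", "C"], ["B", "C", "D"], ["C", "B"]])
    assert refined.genes == ["B", "C"]
    same = refine_signature([["A", "B"], ["A", "B"]])
    assert same.genes == ["A", "B"]
    empty = refine_signature([["A"], ["B"]])
    assert len(empty) == 0


def _planted_cohort(seed=0, shift=2.0, n_genes=120, n_sig=15, n_per_group=10):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    vals = rng.normal(size=(n_genes, 2 * n_per_group))
    vals[:n_sig, :n_per_group] += shift
    m = pd.DataFrame(vals, index=genes,
                     columns=[f"s{i}" for i in range(2 * n_per_group)])
    labels = np.array(["parous"] * n_per_group + ["nulliparous"] * n_per_group)
    return m, labels, _sig(*genes[:n_sig])


def test_overwhelming_signal_reaches_fwer_zero():
    m, labels, sig = _planted_cohort(shift=4.0)
    res = permutation_fwer(m, labels, sig, n_permutations=100, seed=0)
    assert res.es > 0.5
    assert res.fwer == 0.0
    assert res.significant
    assert set(res.leading_edge) <= set(sig.genes)


def test_permutation_fwer_is_reproducible_bit_for_bit():
    m, labels, sig = _planted_cohort(shift=1.0)
    r1 = permutation_fwer(m, labels, sig, n_permutations=60, seed=7)
    r2 = permutation_fwer(m, labels, sig, n_permutations=60, seed=7)
    assert r1.es == r2.es and r1.nes == r2.nes and r1.fwer == r2.fwer
    np.testing.assert_array_equal(r1.es_permuted, r2.es_permuted)


def test_few_distinct_relabellings_are_enumerated():
    m, labels, sig = _planted_cohort(n_per_group=3, shift=1.0)
    res = permutation_fwer(m, labels, sig, n_permutations=1000, seed=0)
    # C(6,3) = 20 distinct relabellings
    assert res.n_permutations == 20


def test_estimator_wrapper_matches_function(small_training):
    m, ann, truth = small_training
    est = GseaPermutationTest(gene_set=truth.genes, n_permutations=50, random_state=5)
    est.fit(m.T, ann["parity"].to_numpy())
    direct = permutation_fwer(
        m, ann["parity"].to_numpy(),
        GeneSignature("t", tuple(SignatureEntry(g) for g in truth.genes)),
        n_permutations=50, seed=5,
    )
    assert est.es_ == direct.es
    assert est.fwer_ == direct.fwer
    assert est.significant_ == direct.significant
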