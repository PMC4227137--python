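"""SAM statistic, fudge-factor search, permutation FDR and selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from paritysig import (
    SamParams,
    SamSelector,
    SyntheticConfig,
    choose_s0,
    extract_signature,
    sam_fdr,
    sam_statistic,
    simulate_training_cohort,
)
from paritysig.sam import S0_PERCENTILE_CANDIDATES, _choose_s0, _pooled_stats, _safe_ratio

LABELS6 = np.array(["nulliparous"] * 3 + ["parous"] * 3)


def _matrix(rows, n_samples=6, prefix="g"):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return pd.DataFrame(
        rows,
        index=[f"{prefix}{i}" for i in range(rows.shape[0])],
        columns=[f"s{i}" for i in range(n_samples)],
    )


def test_d_statistic_matches_pooled_se_hand_computation():
    m = _matrix([[1, 2, 3, 3, 4, 5]])
    d = sam_statistic(m, LABELS6, s0=0.0)
    # s = sqrt((1/3+1/3) * (2+2)/4) = 0.8165, d = 2 / s
    assert d.iloc[0] == pytest.approx(2.449489742783178, abs=1e-12)


def test_d_is_zero_for_identical_groups_with_positive_s0():
    m = _matrix([[2, 2, 2, 2, 2, 2]])
    assert sam_statistic(m, LABELS6, s0=0.5).iloc[0] == 0.0


def test_swapping_group_labels_negates_d(rng):
    m = _matrix(rng.normal(size=(20, 6)))
    d = sam_statistic(m, LABELS6, s0=0.1)
    swapped = np.where(LABELS6 == "parous", "nulliparous", "parous")
    np.testing.assert_allclose(sam_statistic(m, swapped, s0=0.1), -d, atol=1e-12)


def test_global_gene_shift_leaves_d_unchanged(rng):
    m = _matrix(rng.normal(size=(10, 6)))
    shifted = m + 100.0
    np.testing.assert_allclose(
        sam_statistic(m, LABELS6, 0.1), sam_statistic(shifted, LABELS6, 0.1), atol=1e-9
    )


def test_small_group_is_rejected():
    m = _matrix([[1, 2, 3, 4]], n_samples=4)
    with pytest.raises(ValueError, match=">= 2"):
        sam_statistic(m, np.array(["parous", "parous", "parous", "nulliparous"]))


def test_fixed_s0_bypasses_search(small_training):
    m, ann, _ = small_training
    res = sam_fdr(
        m,
        ann["parity"].to_numpy(),
        SamParams(s0_mode="fixed", s0_value=0.1, n_permutations=25, target_fdr=0.05),
    )
    assert res.s0 == 0.1


def test_choose_s0_flat_s_returns_the_common_value(rng):
    # every gene has the same pooled SE -> all percentile candidates coincide
    base = rng.normal(size=6)
    m = _matrix(np.tile(base, (60, 1)) + np.arange(60)[:, None])
    assert choose_s0(m, LABELS6) == pytest.approx(
        _pooled_stats(m.to_numpy(), np.array([3, 4, 5]), np.array([0, 1, 2]))[1][0]
    )


def test_choose_s0_matches_brute_force_grid_oracle(rng):
    # heteroskedastic genes: the search must agree with an independently
    # coded exhaustive scan over the same percentile candidates
    scales = rng.uniform(0.1, 3.0, size=200)
    m = _matrix(rng.normal(size=(200, 6)) * scales[:, None])
    r, s = _pooled_stats(m.to_numpy(), np.array([3, 4, 5]), np.array([0, 1, 2]))

    candidates = np.percentile(s, S0_PERCENTILE_CANDIDATES)
    n_bins = min(100, max(2, len(s) // 5))
    chunks = np.array_split(np.argsort(s, kind="stable"), n_bins)
    best, best_obj = None, np.inf
    for alpha in candidates:
        d = r / (s + alpha)
        mads = []
        for chunk in chunks:
            dc = d[chunk]
            mads.append(np.median(np.abs(dc - np.median(dc))) * 1.4826)
        mads = np.asarray(mads)
        obj = mads.std() / mads.mean()
        if obj < best_obj - 1e-15:
            best, best_obj = alpha, obj
    assert _choose_s0(r, s) == pytest.approx(best)


def test_null_data_selects_essentially_nothing():
    cfg = SyntheticConfig(
        n_genes=1000, n_signature_genes=10, train_n_parous=15,
        train_n_nulliparous=15, log2fc_range=(0.0, 0.0), seed=42,
    )
    m, ann, _ = simulate_training_cohort(cfg)
    res = sam_fdr(m, ann["parity"].to_numpy(),
                  SamParams(n_permutations=100, target_fdr=0.01, seed=0))
    assert len(res.selected_genes) <= 2


def test_all_identical_matrix_selects_nothing():
    m = _matrix(np.ones((50, 6)))
    res = sam_fdr(m, LABELS6, SamParams(n_permutations=20, target_fdr=0.05))
    assert res.selected_genes == []
    assert np.isnan(res.achieved_fdr)


def test_planted_block_recovery_sensitivity_and_fdp():
    cfg = SyntheticConfig(
        n_genes=2000, n_signature_genes=100, train_n_parous=30,
        train_n_nulliparous=30, log2fc_range=(0.3, 0.9), noise_sd=0.5, seed=9,
    )
    m, ann, truth = simulate_training_cohort(cfg)
    res = sam_fdr(m, ann["parity"].to_numpy(),
                  SamParams(n_permutations=100, target_fdr=0.05, seed=1))
    selected = set(res.selected_genes)
    true = set(truth.genes)
    assert len(selected & true) / len(true) >= 0.7
    assert len(selected - true) / max(1, len(selected)) <= 0.15
    assert res.achieved_fdr <= 0.05


def test_q_values_bounded_and_selection_nested(small_training):
    m, ann, _ = small_training
    labels = ann["parity"].to_numpy()
    strict = sam_fdr(m, labels, SamParams(n_permutations=50, target_fdr=0.01, seed=3))
    loose = sam_fdr(m, labels, SamParams(n_permutations=50, target_fdr=0.10, seed=3))
    q = strict.table["q_value"]
    assert ((q >= 0) & (q <= 1)).all()
    assert set(strict.selected_genes) <= set(loose.selected_genes)
    # selected genes never exceed the achieved threshold
    sel = strict.table[strict.table["selected"]]
    if not sel.empty:
        assert (sel["q_value"] <= strict.achieved_fdr + 1e-12).all()


def test_delta_mode_selects_extreme_statistics(small_training):
    m, ann, _ = small_training
    res = sam_fdr(m, ann["parity"].to_numpy(),
                  SamParams(n_permutations=50, delta=1.0, target_fdr=None, seed=3))
    assert res.delta_used == 1.0
    tab = res.table
    if tab["selected"].any():
        called = tab.loc[tab["selected"], "d"]
        uncalled_pos = tab.loc[~tab["selected"] & (tab["d"] > 0), "d"]
        if len(called[called > 0]) and len(uncalled_pos):
            assert called[called > 0].min() > uncalled_pos.max()


def test_extract_signature_carries_direction_and_fold_change():
    table = pd.DataFrame(
        {
            "d": [3.0, -2.5, 1.0],
            "fold_change": [1.62, 0.5, 1.1],
            "q_value": [0.0, 0.01, 0.5],
            "p_value": [0.0, 0.001, 0.2],
            "selected": [True, True, False],
        },
        index=["VNN1", "DOWN1", "OTHER"],
    )
    from paritysig.sam import SamResult

    sig = extract_signature(
        SamResult(table, achieved_fdr=0.01, s0=0.1, n_permutations_used=10), "sig"
    )
    assert sig.genes == ["VNN1", "DOWN1"]
    assert sig.entries[0].direction == "up"
    assert sig.entries[0].fold_change == 1.62
    assert sig.entries[1].direction == "down"


def test_extract_signature_empty_selection_warns():
    from paritysig.sam import SamResult

    table = pd.DataFrame(
        {"d": [0.1], "fold_change": [1.0], "q_value": [1.0], "p_value": [1.0],
         "selected": [False]},
        index=["g"],
    )
    sig = extract_signature(SamResult(table, float("nan"), 0.0, 10), "empty")
    assert len(sig) == 0


def test_sam_params_validation():
    with pytest.raises(ValueError, match="exactly one"):
        SamParams(delta=1.0, target_fdr=0.05)
    with pytest.raises(ValueError, match="exactly one"):
        SamParams(delta=None, target_fdr=None)


def test_selector_estimator_interface(small_training):
    m, ann, _ = small_training
    est = SamSelector(n_permutations=30, target_fdr=0.05, random_state=1)
    est2 = clone(est)
    assert est2.get_params() == est.get_params()
    X = m.T  # samples x genes
    y = ann["parity"].to_numpy()
    est.fit(X, y)
    assert est.selected_.sum() > 0
    reduced = est.transform(X)
    assert reduced.shape == (X.shape[0], est.selected_.sum())
    sig = est.get_signature()
    assert len(sig) == est.selected_.sum()
    # determinism under refit
    est2.fit(X, y)
    np.testing.assert_array_equal(est.selected_, est2.selected_)
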