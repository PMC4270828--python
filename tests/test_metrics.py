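"""Entropy / interaction information, MDR, and the two permutation tests."""

import numpy as np
import pytest

from epihier import (
    CaseControlDataset,
    entropy,
    mdr_fit,
    mutual_information,
    null_dataset,
    pairwise_ig,
    permutation_test_epistasis,
    permutation_test_standard,
    threeway_ig,
)


def test_entropy_values():
    assert entropy({0: 1000, 1: 1000}) == pytest.approx(1.0)
    assert entropy({0: 2000}) == 0.0
    assert entropy({0: 750, 1: 250}) == pytest.approx(0.8112781244591328, abs=1e-12)
    with pytest.raises(ValueError):
        entropy({0: 0, 1: 0})
    with pytest.raises(ValueError):
        entropy([-1, 2])


def _mi_brute_force(x, y):
    """Double-loop plug-in MI over contingency cells (independent oracle)."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    mi = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = ((x == xv) & (y == yv)).sum() / n
            if pxy > 0:
                px = (x == xv).sum() / n
                py = (y == yv).sum() / n
                mi += pxy * np.log2(pxy / (px * py))
    return mi


def test_mutual_information_matches_brute_force(rng):
    for _ in range(20):
        x = rng.integers(0, 3, size=200)
        y = rng.integers(0, 2, size=200)
        assert mutual_information(x, y) == pytest.approx(
            _mi_brute_force(x, y), abs=1e-12
        )


def test_parity_dataset_is_pure_three_way(parity):
    result = threeway_ig(parity, "A", "B", "C")
    for ig in result.main_ig.values():
        assert ig == pytest.approx(0.0, abs=1e-12)
    for ig in result.pairwise_ig.values():
        assert ig == pytest.approx(0.0, abs=1e-12)
    assert result.threeway_ig == pytest.approx(1.0, abs=1e-12)
    assert result.degenerate == ()
    assert mdr_fit(parity, ("A", "B", "C")).accuracy == 1.0


def test_pairwise_ig_of_two_locus_parity():
    # class = (A + B) mod 2 with HWE multiplicities: pure two-way synergy
    weight = {0: 1, 1: 2, 2: 1}
    rows, status = [], []
    for a in (0, 1, 2):
        for b in (0, 1, 2):
            for _ in range(weight[a] * weight[b]):
                rows.append((a, b))
                status.append((a + b) % 2)
    ds = CaseControlDataset(["A", "B"], np.array(rows), np.array(status))
    assert pairwise_ig(ds, "A", "B") == pytest.approx(1.0, abs=1e-12)


def test_threeway_requires_distinct_variants(parity):
    with pytest.raises(ValueError, match="distinct"):
        threeway_ig(parity, "A", "A", "B")


def test_degenerate_variant_is_flagged():
    ds = CaseControlDataset(
        variants=["A", "B", "C"],
        genotypes=np.column_stack(
            [np.zeros(40, dtype=int), np.tile([0, 1], 20), np.tile([0, 1, 2, 1], 10)]
        ),
        status=np.tile([0, 1], 20),
    )
    result = threeway_ig(ds, "A", "B", "C")
    assert result.degenerate == ("A",)
    assert np.isfinite(result.threeway_ig)


def test_mdr_perfect_separation_on_xor_pattern():
    rows, status = [], []
    for a in (0, 1):
        for b in (0, 1):
            for _ in range(25):
                rows.append((a, b))
                status.append(a ^ b)
    ds = CaseControlDataset(["A", "B"], np.array(rows), np.array(status))
    model = mdr_fit(ds, ("A", "B"))
    assert model.accuracy == 1.0
    assert model.cell_labels[(0, 1)] == 1 and model.cell_labels[(0, 0)] == 0
    assert np.array_equal(model.predict(np.array(rows)), np.array(status))


def test_mdr_accuracy_on_null_labels_is_near_half(rng):
    """Label-permuted data: mean training accuracy sits slightly above 0.5
    (27-cell overfitting) but well below any real signal."""
    ds = null_dataset(n_cases=500, n_controls=500, seed=1)
    accs = []
    for _ in range(100):
        shuffled = CaseControlDataset(
            ds.variants, ds.genotypes, rng.permutation(ds.status)
        )
        accs.append(mdr_fit(shuffled, ("V1", "V2", "V3")).accuracy)
    assert 0.5 <= np.mean(accs) <= 0.60
    assert all(a >= 0.5 for a in accs)  # never below the class prior


def test_mdr_empty_cells_are_low_risk():
    ds = CaseControlDataset(
        variants=["A", "B"],
        genotypes=np.array([[0, 0], [0, 0], [1, 1], [1, 1]]),
        status=np.array([1, 1, 0, 0]),
    )
    model = mdr_fit(ds, ("A", "B"))
    assert model.predict(np.array([[0, 1]]))[0] == 0  # unseen cell


def test_standard_permutation_add_one_formula(parity):
    # observed accuracy 1.0 beats (or ties) every permutation; with a seed
    # where the single permutation scores lower, p = (1+0)/(1+1)
    p = permutation_test_standard(parity, ("A", "B", "C"), n_perm=1, seed=0)
    assert p == pytest.approx(0.5)


def test_standard_permutation_detects_association(parity):
    p = permutation_test_standard(parity, ("A", "B", "C"), n_perm=1000, seed=1)
    assert p <= 0.001


def test_epistasis_permutation_destroys_parity_signal(parity):
    p = permutation_test_epistasis(parity, ("A", "B", "C"), n_perm=1000, seed=2)
    assert p <= 0.001


def test_explicit_shuffle_preserves_per_class_genotype_counts(parity, rng):
    """Reproduce the within-class shuffle and check the invariant it must
    satisfy: per-class genotype counts of every variant are unchanged."""
    status = parity.status
    case_idx = np.flatnonzero(status == 1)
    ctrl_idx = np.flatnonzero(status == 0)
    for name in parity.variants:
        col = parity.column(name).copy()
        before_case = np.bincount(col[case_idx], minlength=3)
        before_ctrl = np.bincount(col[ctrl_idx], minlength=3)
        col[case_idx] = col[case_idx][rng.permutation(len(case_idx))]
        col[ctrl_idx] = col[ctrl_idx][rng.permutation(len(ctrl_idx))]
        assert np.array_equal(np.bincount(col[case_idx], minlength=3), before_case)
        assert np.array_equal(np.bincount(col[ctrl_idx], minlength=3), before_ctrl)


def test_epistasis_permutation_spares_pure_main_effects(rng):
    """Data whose penetrance depends on a single locus: the explicit test's
    null holds, so p is typically non-significant."""
    ps = []
    for seed in range(5):
        local = np.random.default_rng(seed)
        n = 500
        a_case = local.choice([0, 1, 2], size=n, p=[0.1, 0.4, 0.5])
        a_ctrl = local.choice([0, 1, 2], size=n, p=[0.5, 0.4, 0.1])
        noise = local.choice([0, 1, 2], size=(2 * n, 2), p=[0.25, 0.5, 0.25])
        ds = CaseControlDataset(
            variants=["A", "B", "C"],
            genotypes=np.column_stack([np.concatenate([a_case, a_ctrl]), noise]),
            status=np.array([1] * n + [0] * n),
        )
        ps.append(permutation_test_epistasis(ds, ("A", "B", "C"), 200, seed=seed))
    assert np.median(ps) > 0.05
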