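"""Six-metric evaluation suite against brute-force oracles, plus the paired
Wilcoxon/Bonferroni comparison harness."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sphtract.metrics import (
    METRIC_NAMES,
    ConfusionCounts,
    aggregate,
    compare_methods,
    compute_metrics,
    confusion_counts,
    evaluate_pair,
)


def brute_force_metrics(P, G):
    """Voxel-loop oracle, written independently of the vectorized path."""
    tp = fp = fn = tn = 0
    for p, g in zip(np.asarray(P).ravel(), np.asarray(G).ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    ref = tp + fn
    return {
        "dice": 2 * tp / (2 * tp + fp + fn) if ref else np.nan,
        "vop": tp / ref if ref else np.nan,
        "vor": fp / ref if ref else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "precision": tp / (tp + fp) if tp + fp else np.nan,
        "jaccard": tp / (tp + fp + fn) if tp + fp + fn else np.nan,
    }


def test_confusion_toy_counts():
    """10x10 toy: |G| = 8, |P| = 8, 6 shared -> (6, 2, 2, 90)."""
    G = np.zeros((10, 10), dtype=np.uint8)
    P = np.zeros((10, 10), dtype=np.uint8)
    G.ravel()[:8] = 1
    P.ravel()[2:10] = 1
    c = confusion_counts(P, G)
    assert (c.tp, c.fp, c.fn, c.tn) == (6, 2, 2, 90)
    assert c.total == 100 and c.reference_size == 8


def test_metrics_on_toy_counts():
    row = compute_metrics(ConfusionCounts(6, 2, 2, 90))
    assert np.isclose(row.dice, 0.75)
    assert np.isclose(row.vop, 0.75)
    assert np.isclose(row.vor, 0.25)
    assert np.isclose(row.precision, 0.75)
    assert np.isclose(row.jaccard, 0.6)
    assert np.isclose(row.specificity, 90 / 92)
    # algebraic identity: dice = 2 vop / (1 + vop + vor)
    assert np.isclose(2 * row.vop / (1 + row.vop + row.vor), row.dice)


def test_perfect_and_disjoint_predictions():
    G = np.zeros((5, 5, 5), dtype=np.uint8)
    G[1:3, 1:3, 1:3] = 1
    row = evaluate_pair(G, G)
    assert row.dice == 1.0 and row.vop == 1.0 and row.vor == 0.0
    assert row.jaccard == 1.0
    P = np.zeros_like(G)
    P[4, 4, 4] = 1
    assert evaluate_pair(P, G).dice == 0.0


def test_empty_reference_gives_nan_sentinels():
    row = compute_metrics(ConfusionCounts(0, 3, 0, 97))
    assert np.isnan(row.dice) and np.isnan(row.vop) and np.isnan(row.vor)
    assert not np.isnan(row.specificity)


def test_grid_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion_counts(np.zeros((3, 3)), np.zeros((4, 4)))


def test_random_masks_match_brute_force_oracle(rng):
    """100 random S=16 mask pairs: every metric matches the voxel loop to
    1e-12, and the Dice/VOP/VOR identity holds whenever |G| > 0."""
    for trial in range(100):
        P = rng.random((16, 16, 16)) < rng.uniform(0.0, 0.3)
        G = rng.random((16, 16, 16)) < rng.uniform(0.0, 0.3)
        row = evaluate_pair(P, G).as_dict()
        oracle = brute_force_metrics(P, G)
        for name in METRIC_NAMES:
            if np.isnan(oracle[name]):
                assert np.isnan(row[name])
            else:
                assert abs(row[name] - oracle[name]) < 1e-12
        if G.sum() > 0:
            assert abs(
                2 * row["vop"] / (1 + row["vop"] + row["vor"]) - row["dice"]
            ) < 1e-12


def test_dice_jaccard_symmetry_vor_nonneg(rng):
    for _ in range(20):
        P = rng.random((8, 8, 8)) < 0.2
        G = rng.random((8, 8, 8)) < 0.2
        if not (P.any() and G.any()):
            continue
        a, b = evaluate_pair(P, G), evaluate_pair(G, P)
        assert np.isclose(a.dice, b.dice) and np.isclose(a.jaccard, b.jaccard)
        assert a.vor >= 0.0
    # VOR = 0 iff P is a subset of G
    G = np.zeros((4, 4, 4), bool)
    G[:2] = True
    P = G.copy()
    P[0, 0, 0] = False
    assert evaluate_pair(P, G).vor == 0.0
    P[3, 3, 3] = True
    assert evaluate_pair(P, G).vor > 0.0


# --------------------------------------------------------------------------- #
# aggregation
# --------------------------------------------------------------------------- #

def test_aggregate_single_row():
    df = pd.DataFrame([{"dice": 0.8, "vop": 0.9, "vor": 0.1,
                        "specificity": 1.0, "precision": 0.9, "jaccard": 0.7}])
    out = aggregate(df)
    assert np.isclose(out["dice_mean"].iloc[0], 0.8)
    assert out["dice_sd"].iloc[0] == 0.0


def test_aggregate_sample_sd():
    df = pd.DataFrame({"dice": [0.7, 0.9]})
    out = aggregate(df)
    assert np.isclose(out["dice_mean"].iloc[0], 0.8)
    assert np.isclose(out["dice_sd"].iloc[0], np.std([0.7, 0.9], ddof=1))
    assert np.isclose(out["dice_sd"].iloc[0], 0.14142135, atol=1e-6)


def test_aggregate_excludes_undefined_with_count():
    df = pd.DataFrame({"dice": [0.5, np.nan, 0.7]})
    out = aggregate(df)
    assert np.isclose(out["dice_mean"].iloc[0], 0.6)
    assert out["n_undefined"].iloc[0] == 1


def test_aggregate_by_group():
    df = pd.DataFrame({
        "tract": ["a", "a", "b"],
        "dice": [0.6, 0.8, 1.0],
    })
    out = aggregate(df, by=["tract"])
    assert np.isclose(out.loc["a", "dice_mean"], 0.7)
    assert np.isclose(out.loc["b", "dice_mean"], 1.0)


def test_aggregate_empty_rejected():
    with pytest.raises(ValueError):
        aggregate(pd.DataFrame())


# --------------------------------------------------------------------------- #
# Wilcoxon / Bonferroni
# --------------------------------------------------------------------------- #

def exact_two_sided_p(diffs):
    """Enumerate all sign assignments of |diffs| ranks (small-n oracle)."""
    d = np.abs(np.asarray(diffs, float))
    ranks = pd.Series(d).rank().to_numpy()
    observed = ranks[np.asarray(diffs) > 0].sum()
    n = len(d)
    total = ranks.sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        stats.append(min(w_plus, total - w_plus))
    obs = min(observed, total - observed)
    return sum(s <= obs for s in stats) / 2**n


def test_wilcoxon_all_positive_six_pairs():
    """Six uniformly positive differences: exact two-sided p = 2/64."""
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    b = a - np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
    stat, p_raw, p_adj = compare_methods(a, b)
    assert np.isclose(p_raw, 2.0 / 64.0)
    assert np.isclose(p_raw, exact_two_sided_p(a - b))


def test_wilcoxon_identical_scores():
    a = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
    stat, p_raw, p_adj = compare_methods(a, a.copy())
    assert p_raw == 1.0 and p_adj == 1.0


def test_bonferroni_caps_at_one():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    b = a - 0.1
    _, p_raw, p_adj = compare_methods(a, b, n_comparisons=72)
    assert p_adj == 1.0  # 72 * 0.03125 = 2.25, capped
    _, _, p_adj2 = compare_methods(a, b, n_comparisons=2)
    assert np.isclose(p_adj2, 2 * p_raw)


def test_wilcoxon_matches_enumeration_on_mixed_signs(rng):
    for _ in range(5):
        d = rng.normal(size=7)
        d[d == 0] = 0.1
        a = rng.random(7)
        b = a - d
        _, p_raw, _ = compare_methods(a, b)
        assert np.isclose(p_raw, exact_two_sided_p(a - b), atol=1e-12)


def test_compare_rejects_mismatched_lengths():
    with pytest.raises(ValueError):
        compare_methods(np.zeros(3), np.zeros(4))
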