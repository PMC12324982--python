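"""Decoding, molecule features and the adaptive misidentification filter."""

import numpy as np
import pandas as pd
import pytest

from pmulti.codebook import assign_codewords, generate_constant_weight_code
from pmulti.decode import (
    apply_adaptive_threshold,
    binarize_and_decode,
    compute_molecule_features,
    decode_molecules,
    filter_molecules,
    fit_blank_classifier,
    misidentification_report,
)
from pmulti.simulate import simulate_decoding_benchmark


def test_exact_codeword_decodes_identically(small_book):
    for i, name in enumerate(small_book.names):
        got, corr = binarize_and_decode(small_book.bits[i].astype(float), small_book)
        assert got == name and corr == 0


def test_single_dropped_bit_is_corrected(small_book):
    v = small_book.bits[0].astype(float).copy()
    v[np.nonzero(v)[0][0]] = 0.0
    got, corr = binarize_and_decode(v, small_book)
    assert got == small_book.names[0] and corr == 1


def test_hd2_ambiguous_vector_unassigned(toy_pair_book):
    # 101000 sits at distance 2 from both 110000 and 001100
    got, corr = binarize_and_decode(np.array([1.0, 0, 1, 0, 0, 0]), toy_pair_book)
    assert got is None and corr is None


def test_length_mismatch_raises(small_book):
    with pytest.raises(ValueError, match="length"):
        binarize_and_decode(np.ones(5), small_book)


@pytest.mark.parametrize("n_bits,weight", [(6, 3), (8, 4)])
def test_every_single_bit_corruption_corrects_uniquely(n_bits, weight):
    """For min distance 4, any HD<=1 corruption decodes to the true codeword."""
    book = generate_constant_weight_code(n_bits, weight, 4, 2)
    book = assign_codewords(
        [f"g{i}" for i in range(max(2, len(book) // 2))], book, seed=0
    )
    for i in range(len(book)):
        for bit in range(n_bits):
            v = book.bits[i].astype(float).copy()
            v[bit] = 1.0 - v[bit]
            got, corr = binarize_and_decode(v, book)
            assert got == book.names[i]
            assert corr == 1
        got, corr = binarize_and_decode(book.bits[i].astype(float), book)
        assert got == book.names[i] and corr == 0


def _mol_frame(book, intensities, name, size=5):
    row = {"size_px": size, "assigned_name": name, "is_blank": False}
    for b, v in enumerate(intensities):
        row[f"bit_{b}"] = v
    return pd.DataFrame([row])


def test_features_constant_intensities(toy_pair_book):
    df = _mol_frame(toy_pair_book, [3.0] * 6, "A", size=7)
    f = compute_molecule_features(df, toy_pair_book)
    assert f.iloc[0].tolist() == [3.0, 7.0, 0.0, 0.0]


def test_features_hand_computed(toy_pair_book):
    # intensities (2,2,0,0,0,0) on codeword 110000 of a 4-bit example from
    # the 6-bit book: mean 2/3, population variance, on-off difference 2
    df = _mol_frame(toy_pair_book, [2, 2, 0, 0, 0, 0], "A")
    f = compute_molecule_features(df, toy_pair_book).iloc[0]
    assert f["mean_intensity"] == pytest.approx(4 / 6)
    assert f["intensity_variance"] == pytest.approx(np.var([2, 2, 0, 0, 0, 0]))
    assert f["on_off_difference"] == pytest.approx(2.0)


def test_feature_scaling_homogeneity(toy_pair_book, rng):
    intens = rng.random(6)
    f1 = compute_molecule_features(
        _mol_frame(toy_pair_book, intens, "A"), toy_pair_book
    ).iloc[0]
    f2 = compute_molecule_features(
        _mol_frame(toy_pair_book, 3.0 * intens, "A"), toy_pair_book
    ).iloc[0]
    assert f2["mean_intensity"] == pytest.approx(3 * f1["mean_intensity"])
    assert f2["on_off_difference"] == pytest.approx(3 * f1["on_off_difference"])
    assert f2["intensity_variance"] == pytest.approx(9 * f1["intensity_variance"])


def test_unassigned_molecule_feature_contract(toy_pair_book):
    df = _mol_frame(toy_pair_book, [1.0] * 6, None)
    with pytest.raises(ValueError):
        compute_molecule_features(df, toy_pair_book)


def test_classifier_separable_and_null_cases(rng):
    n = 400
    feats = pd.DataFrame(
        {
            "mean_intensity": rng.random(n),
            "size": rng.integers(1, 10, n).astype(float),
            "intensity_variance": rng.random(n),
            "on_off_difference": np.concatenate(
                [rng.uniform(2, 3, n // 2), rng.uniform(0, 1, n // 2)]
            ),
        }
    )
    is_blank = np.concatenate([np.zeros(n // 2, bool), np.ones(n // 2, bool)])
    model = fit_blank_classifier(feats, is_blank, split_seed=0)
    scores = model.predict_proba(feats.to_numpy())[:, 1]
    from sklearn.metrics import roc_auc_score

    assert roc_auc_score(~is_blank, scores) == 1.0

    shuffled = rng.permutation(is_blank)
    half = n // 2
    perm = rng.permutation(n)
    tr, te = perm[:half], perm[half:]
    model2 = fit_blank_classifier(feats.iloc[tr], shuffled[tr], split_seed=0)
    s2 = model2.predict_proba(feats.iloc[te].to_numpy())[:, 1]
    # held-out ranking under shuffled labels is chance up to binomial error
    auc = roc_auc_score(~shuffled[te], s2)
    assert abs(auc - 0.5) < 0.2

    with pytest.raises(ValueError, match="both blank and coding"):
        fit_blank_classifier(feats, np.zeros(n, bool), split_seed=0)


def test_adaptive_threshold_enumeration_example():
    scores = np.array([0.9] * 19 + [0.2, 0.95])
    is_blank = np.array([False] * 19 + [True, True])
    thr, retained = apply_adaptive_threshold(scores, is_blank, 0.05)
    assert 0.2 < thr <= 0.9
    assert retained.sum() == 20
    assert is_blank[retained].mean() == pytest.approx(0.05)


def test_adaptive_threshold_edge_cases():
    thr, kept = apply_adaptive_threshold(
        np.array([0.3, 0.8]), np.array([False, False]), 0.05
    )
    assert kept.all()
    with pytest.warns(UserWarning, match="retaining nothing"):
        thr, kept = apply_adaptive_threshold(
            np.array([0.3, 0.8]), np.array([True, True]), 0.05
        )
    assert not kept.any() and np.isinf(thr)
    with pytest.raises(ValueError):
        apply_adaptive_threshold(np.array([]), np.array([]), 0.05)


def test_adaptive_threshold_monotone_in_target(rng):
    scores = rng.random(500)
    is_blank = rng.random(500) < 0.3
    prev = -1
    for target in (0.01, 0.05, 0.1, 0.3, 1.0):
        _, kept = apply_adaptive_threshold(scores, is_blank, target)
        assert kept.sum() >= prev
        prev = kept.sum()


def test_misidentification_report_arithmetic(small_book):
    names = [small_book.coding_names[0]] * 95 + [small_book.blank_names[0]] * 5
    df = pd.DataFrame({"assigned_name": names})
    rep = misidentification_report(df, small_book)
    assert rep.blank_fraction == pytest.approx(0.05)
    # 1 coding codeword at 95 vs mean over 2 coding; 1 blank at 5 vs 2 blanks
    mean_coding = 95 / 2
    mean_blank = 5 / 2
    assert rep.blank_rate_normalized == pytest.approx(mean_blank / mean_coding)
    df0 = pd.DataFrame({"assigned_name": [small_book.coding_names[0]] * 10})
    assert misidentification_report(df0, small_book).blank_fraction == 0.0


def test_zero_bit_error_round_trip(barcode_book):
    """Without bit flips every assignment is correct and no blanks appear.

    Lognormal intensity tails can very rarely leave a molecule unassigned
    (a detection loss); they must never produce a wrong or blank call.
    """
    mols = simulate_decoding_benchmark(barcode_book, 2000, 0.0, 0.0, seed=3)
    d = decode_molecules(mols, barcode_book)
    assigned = d[d["assigned_name"].notna()]
    assert len(assigned) >= 0.995 * len(d)
    assert (assigned["assigned_name"] == assigned["true_name"]).all()
    assert not d["is_blank"].any()


def test_filter_monotonicity_on_simulated_molecules(barcode_book):
    mols = simulate_decoding_benchmark(barcode_book, 8000, 0.08, 0.02, seed=4)
    d = decode_molecules(mols, barcode_book)
    assigned = d[d["assigned_name"].notna()]
    kept = []
    for target in (0.02, 0.05, 0.2):
        filt, _ = filter_molecules(assigned, barcode_book, target, split_seed=0)
        kept.append(int(filt["exported"].sum()))
    assert kept == sorted(kept)
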