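"""Fickett TESTCODE, hexamer bias, logistic classification, training/serialization."""

import math

import numpy as np
import pytest

from orfannotate.fickett import fickett_score
from orfannotate.fixtures import generate_training_sets
from orfannotate.orfs import enumerate_orfs
from orfannotate.scoring import (
    CodingModel,
    FeatureVector,
    HexamerTable,
    build_hexamer_table,
    classify,
    coding_probability,
    extract_features,
    hexamer_score,
    train_model,
)

# ---------------------------------------------------------------------------
# Independent TESTCODE oracle: a direct, separately written transliteration of
# the published tables and lookup procedure (position asymmetry + composition).
_ORACLE_TABLES = {
    "A": ([0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22], 0.26,
          [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21], 0.11),
    "C": ([0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23], 0.18,
          [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31], 0.12),
    "G": ([0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08], 0.31,
          [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29], 0.15),
    "T": ([0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09], 0.33,
          [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58], 0.14),
}
_POS_CUTS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_CUTS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def oracle_testcode(seq):
    seq = seq.upper()
    acgt = [b for b in seq if b in "ACGT"]
    total = 0.0
    for base, (pos_probs, pos_w, cont_probs, cont_w) in _ORACLE_TABLES.items():
        counts = [0, 0, 0]
        for i, b in enumerate(seq):
            if b == base:
                counts[i % 3] += 1
        asym = max(counts) / (min(counts) + 1.0)
        idx = next(k for k, cut in enumerate(_POS_CUTS) if asym >= cut)
        total += pos_probs[idx] * pos_w
        frac = acgt.count(base) / len(acgt) if acgt else 0.0
        idx = next(k for k, cut in enumerate(_CONTENT_CUTS) if frac >= cut)
        total += cont_probs[idx] * cont_w
    return total


def test_fickett_matches_independent_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert fickett_score(seq) == pytest.approx(oracle_testcode(seq), abs=1e-4)


def test_fickett_determinism_and_statistics_dependence():
    seq = "ATGGCGGCGGCTTAA"
    assert fickett_score(seq) == fickett_score(seq)
    # appending a full codon-period block of identical composition pattern
    # changes the statistics, so the score may change; a permutation that
    # preserves position/composition counts must not
    permuted = seq[:3] + seq[6:9] + seq[3:6] + seq[9:]  # swap two codons
    assert fickett_score(permuted) == pytest.approx(oracle_testcode(permuted))
    with pytest.raises(ValueError):
        fickett_score("A")


def test_fickett_ignores_n_bases():
    # N contributes to neither position nor composition counts
    assert fickett_score("ACGTACGTACGT") == fickett_score("ACGTACGTACGTNNN"[:12] + "NNN")


def test_hexamer_table_symmetry_and_normalization():
    from orfannotate.scoring import _count_hexamers

    seqs = ["ATGGCGGCGTTTAAACCC", "ATGTTTCCCGGG"]
    counts = _count_hexamers(seqs, step=3) + 1.0
    table = HexamerTable(counts, counts)  # identical counting mode forced
    assert np.allclose(table._log_ratio, 0.0)
    assert table.coding.sum() == pytest.approx(1.0)
    assert table.noncoding.sum() == pytest.approx(1.0)

    # a sequence shorter than 6 nt contributes nothing
    with_short = _count_hexamers(seqs + ["ATGAA"], step=3)
    assert np.array_equal(with_short, _count_hexamers(seqs, step=3))


def test_build_hexamer_table_contracts():
    with pytest.raises(ValueError):
        build_hexamer_table([], ["ACGTACGT"])
    table = build_hexamer_table(["ATGGCGGCGTAA"], ["TTTTTTTTTT"])
    assert (table.coding > 0).all() and (table.noncoding > 0).all()


def test_hexamer_score_cases():
    uniform = HexamerTable.uniform()
    assert hexamer_score("ATGGCGGCGTAA", uniform) == 0.0
    assert hexamer_score("ATGAA", uniform) == 0.0  # degenerate: < 6 nt
    assert hexamer_score("ATGNNNGCG", uniform) == 0.0  # every hexamer contains N

    # table where every in-frame hexamer of the input has ratio e -> score 1
    coding = np.full(4096, 1.0)
    seq = "ATGGCGGCGTAA"
    from orfannotate.scoring import _hexamer_index

    idxs = {_hexamer_index(seq[i : i + 6]) for i in range(0, len(seq) - 5, 3)}
    for idx in idxs:
        coding[idx] = math.e
    # renormalization rescales both classes; compare ratios directly
    table = HexamerTable(coding, np.full(4096, 1.0))
    expected = math.log(math.e / coding.sum() * 4096.0)
    assert hexamer_score(seq, table) == pytest.approx(expected)


def test_coding_probability_closed_forms():
    uniform = HexamerTable.uniform()
    fv = FeatureVector(orf_length=300, orf_coverage=0.5, fickett=1.0, hexamer=0.2)
    zero = CodingModel(uniform, 0.0, np.zeros(4), cutoff=0.5)
    assert coding_probability(fv, zero) == pytest.approx(0.5)
    ten = CodingModel(uniform, 10.0, np.zeros(4), cutoff=0.5)
    assert coding_probability(fv, ten) == pytest.approx(1.0 / (1.0 + math.exp(-10.0)))


def test_probability_monotone_in_positively_weighted_features():
    uniform = HexamerTable.uniform()
    model = CodingModel(uniform, -1.0, np.array([0.5, 1.0, 0.8, 1.2]), cutoff=0.5)
    grid = [90, 150, 300, 600]
    probs = [
        coding_probability(FeatureVector(L, 0.5, 0.8, 0.1), model) for L in grid
    ]
    assert probs == sorted(probs)
    probs_cov = [
        coding_probability(FeatureVector(300, c, 0.8, 0.1), model) for c in (0.2, 0.5, 0.9)
    ]
    assert probs_cov == sorted(probs_cov)


def test_classify_boundary_and_override():
    assert classify(0.364, 0.364) == "coding"  # boundary counts as coding
    assert classify(0.0, 0.01) == "noncoding"
    assert classify(0.99, 1.0) == "noncoding"
    with pytest.raises(ValueError):
        classify(0.5, 1.5)


def test_feature_extraction_is_pure():
    table = HexamerTable.uniform()
    seq = "CCATGGCGGCGTAACC"
    orf = "ATGGCGGCGTAA"
    first = extract_features(orf, seq, table)
    second = extract_features(orf, seq, table)
    assert first == second
    with pytest.raises(ValueError):
        FeatureVector(10, 0.5, 1.0, 0.0)  # length not multiple of 3
    with pytest.raises(ValueError):
        FeatureVector(9, 1.5, 1.0, 0.0)  # coverage out of range


def test_training_recovery_and_serialization(tmp_path, trained_model):
    """Model trained on separable synthetic sets classifies held-out examples
    correctly >= 95% of the time; save/load reproduces probabilities bit-exactly."""
    coding_test, noncoding_test = generate_training_sets(n_per_class=40, seed=6)
    correct = total = 0
    probs = []
    for label, seqs in ((1, coding_test), (0, noncoding_test)):
        for seq in seqs:
            cands = enumerate_orfs(seq)
            if not cands:
                correct += 1 - label
                total += 1
                continue
            longest = max(cands, key=lambda c: c.length)
            prob = trained_model.score(longest.orf_seq, seq)
            probs.append((longest.orf_seq, seq, prob))
            correct += int((prob >= trained_model.cutoff) == bool(label))
            total += 1
    assert correct / total >= 0.95

    path = tmp_path / "model.json"
    trained_model.to_json(path)
    loaded = CodingModel.from_json(path)
    for orf_seq, seq, prob in probs[:20]:
        assert loaded.score(orf_seq, seq) == prob  # bit-exact


def test_training_determinism():
    coding, noncoding = generate_training_sets(n_per_class=25, seed=9)
    m1 = train_model(coding, noncoding, seed=1)
    m2 = train_model(coding, noncoding, seed=1)
    assert m1.intercept == m2.intercept
    assert np.array_equal(m1.weights, m2.weights)


def test_training_errors_without_orfs():
    with pytest.raises(ValueError, match="no complete ORFs"):
        train_model(["ATGGCGGCGTAA"] * 3, ["CCCCCCCCCCCC"] * 3)
    with pytest.raises(ValueError):
        train_model([], ["ACGT"])


def test_length_dominant_scorer_is_length_only():
    model = CodingModel.length_dominant(pivot_nt=100)
    fv_a = FeatureVector(300, 0.2, 0.3, -1.0)
    fv_b = FeatureVector(300, 0.9, 1.3, 2.0)
    assert coding_probability(fv_a, model) == coding_probability(fv_b, model)
    assert coding_probability(fv_a, model) == pytest.approx(300 / 400)
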