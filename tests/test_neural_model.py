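"""Forward-pass correctness, training contracts, lossless serialization."""

import io
import json
import math

import numpy as np
import pytest

import nolscan as n
from nolscan.encoding import DEFAULT_ALPHABET, encode_window
from nolscan.neural_model import (
    Hyperparameters,
    Model,
    ModelError,
    TrainingError,
    load_model,
    save_model,
    score_windows,
    train,
)
from nolscan.sequence_io import SequenceRecord


def zero_model(hidden=4):
    return Model(alphabet=DEFAULT_ALPHABET, hidden_sizes=(hidden,),
                 weights=[np.zeros((156, hidden)), np.zeros((hidden, 1))],
                 biases=[np.zeros(hidden), np.zeros(1)])


def test_all_zero_weights_score_half_everywhere():
    m = zero_model()
    for w in ("K" * 13, "MKRDESTNQILVF"):
        assert m.score_window(w) == pytest.approx(0.5)


def test_hand_calculated_forward_pass():
    """One hidden unit with hand-set weights, verified by closed form."""
    W1 = np.zeros((156, 1))
    g = next(i for i, grp in enumerate(DEFAULT_ALPHABET.groups) if "K" in grp)
    for p in range(13):
        W1[p * 12 + g, 0] = 0.1
    m = Model(alphabet=DEFAULT_ALPHABET, hidden_sizes=(1,),
              weights=[W1, np.array([[2.0]])],
              biases=[np.array([0.0]), np.array([-1.0])])
    a1 = 1 / (1 + math.exp(-1.3))          # 13 bits * 0.1
    expected = 1 / (1 + math.exp(-(2.0 * a1 - 1.0)))
    assert m.score_window("K" * 13) == pytest.approx(expected, abs=1e-12)


def test_output_bounded_for_arbitrary_finite_weights():
    rng = np.random.default_rng(0)
    for _ in range(20):
        m = Model(alphabet=DEFAULT_ALPHABET, hidden_sizes=(5,),
                  weights=[rng.normal(scale=50, size=(156, 5)),
                           rng.normal(scale=50, size=(5, 1))],
                  biases=[rng.normal(scale=50, size=5),
                          rng.normal(scale=50, size=1)])
        s = m.score_window("".join(rng.choice(list("KRDEAG"), 13)))
        assert 0.0 <= s <= 1.0


def test_dimension_mismatch_names_sizes():
    with pytest.raises(ModelError, match="156"):
        zero_model().forward(np.zeros(195))


def test_input_size_must_match_alphabet_feature_length():
    with pytest.raises(ModelError, match="feature length"):
        Model(alphabet=DEFAULT_ALPHABET, hidden_sizes=(2,),
              weights=[np.zeros((100, 2)), np.zeros((2, 1))],
              biases=[np.zeros(2), np.zeros(1)])


def test_score_windows_equals_per_window_loop(trained_model):
    rec = SequenceRecord("p", "MGRNKKKKRDGDDRRPRLVLSFDEEKRREYLTG")
    profile = score_windows(trained_model, rec)
    assert len(profile.scores) == len(rec) - 12
    for i, score in enumerate(profile.scores):
        window = rec.residues[i:i + 13]
        assert score == pytest.approx(trained_model.score_window(window))


def test_score_windows_too_short_flags_instead_of_raising(trained_model):
    profile = score_windows(trained_model, SequenceRecord("tiny", "MKRLV"))
    assert profile.too_short and profile.scores == ()


def test_training_separable_toy_reaches_perfect_accuracy():
    pos = ["K" * 13] * 20
    neg = ["D" * 13] * 20
    m = train(pos, neg, Hyperparameters(epochs=50, validation_fraction=0),
              seed=1)
    assert m.score_window("K" * 13) > 0.5 > m.score_window("D" * 13)


def test_training_is_deterministic_given_seed():
    ts = n.generate_training_set(80, 80, seed=5)
    tp, tn, _, _ = ts.split()
    hp = Hyperparameters(epochs=20)
    m1, m2 = train(tp, tn, hp, seed=9), train(tp, tn, hp, seed=9)
    for a, b in zip(m1.weights, m2.weights):
        assert np.array_equal(a, b)


def test_training_loss_decreases():
    ts = n.generate_training_set(200, 200, seed=3)
    tp, tn, _, _ = ts.split()
    m = train(tp, tn, Hyperparameters(epochs=30), seed=3)
    first, last = m.training_metadata["train_losses"]
    assert last < first


def test_empty_class_rejected():
    with pytest.raises(TrainingError):
        train([], ["D" * 13], seed=0)


def test_label_flip_anticorrelates_scores():
    ts = n.generate_training_set(300, 300, seed=11)
    tp, tn, hp, hn = ts.split()
    hyper = Hyperparameters(epochs=30)
    m = train(tp, tn, hyper, seed=11)
    m_flip = train(tn, tp, hyper, seed=11)
    held = hp + hn
    a = np.array([m.score_window(w) for w in held])
    b = np.array([m_flip.score_window(w) for w in held])
    assert np.corrcoef(a, b)[0, 1] < -0.5


def test_heldout_window_auroc_above_09():
    from sklearn.metrics import roc_auc_score

    ts = n.generate_training_set(500, 500, seed=21)
    tp, tn, hp, hn = ts.split()
    m = train(tp, tn, seed=21)
    scores = [m.score_window(w) for w in hp + hn]
    labels = [1] * len(hp) + [0] * len(hn)
    assert roc_auc_score(labels, scores) > 0.9


def test_serialization_round_trip_is_bit_identical(trained_model):
    buf = io.StringIO()
    save_model(trained_model, buf)
    back = load_model(io.StringIO(buf.getvalue()))
    for a, b in zip(trained_model.weights, back.weights):
        assert np.array_equal(a, b)
    rng = np.random.default_rng(17)
    for _ in range(100):
        w = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 13))
        assert trained_model.score_window(w) == back.score_window(w)


def test_load_rejects_tampered_and_corrupt_files(trained_model, tmp_path):
    buf = io.StringIO()
    save_model(trained_model, buf)
    doc = json.loads(buf.getvalue())

    doc_bad = dict(doc, format_version=99)
    with pytest.raises(ModelError, match="version"):
        load_model(io.StringIO(json.dumps(doc_bad)))

    # swap two alphabet groups without updating the checksum
    groups = list(doc["alphabet"]["groups"])
    groups[0], groups[1] = groups[1], groups[0]
    doc_bad = dict(doc, alphabet=dict(doc["alphabet"], groups=groups))
    with pytest.raises(ModelError, match="checksum"):
        load_model(io.StringIO(json.dumps(doc_bad)))

    p = tmp_path / "broken.json"
    p.write_text(buf.getvalue()[:100])
    with pytest.raises(ModelError, match="corrupted"):
        load_model(p)
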