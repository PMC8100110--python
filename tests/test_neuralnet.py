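"""Random encodings, MLP forward/backward pass, training and ensembles."""

import copy

import numpy as np
import pytest

import evoattract as ea
from evoattract.neuralnet import (
    CODE_BITS,
    EncodingError,
    NetworkModel,
    NetworkParams,
    make_encoding,
    one_hot_targets,
    sigmoid,
    train_online,
)


# ------------------------------------------------------------------ encodings

def test_encoding_is_deterministic_per_seed():
    assert make_encoding(42).code_map == make_encoding(42).code_map


def test_encodings_differ_across_seeds():
    differing = sum(
        make_encoding(s).code_map != make_encoding(s + 1000).code_map for s in range(100)
    )
    assert differing >= 99  # collisions of whole tables are vanishingly rare


def test_encoding_codes_are_distinct_five_bit_words():
    enc = make_encoding(7)
    codes = list(enc.code_map.values())
    assert all(len(c) == CODE_BITS and set(c) <= {0, 1} for c in codes)
    assert len(set(codes)) == len(codes)


def test_alphabet_over_capacity_raises():
    with pytest.raises(EncodingError, match="exceeds"):
        make_encoding(0, alphabet="".join(chr(65 + i) for i in range(26)) + "0123456")


def test_iid_sampling_mode_allows_collisions():
    enc = make_encoding(3, alphabet="AB", distinct=False)
    assert set(enc.code_map) == {"A", "B"}


def test_encode_sequence_length_and_roundtrip():
    enc = make_encoding(5)
    seq = "MKVLH-" * 10
    bits = ea.encode_sequence(seq, enc)
    assert bits.shape == (CODE_BITS * len(seq),)
    assert enc.decode(bits) == seq
    assert ea.encode_sequence("", enc).shape == (0,)


def test_four_hundred_residues_encode_to_2000_bits():
    enc = make_encoding(1)
    assert ea.encode_sequence("A" * 400, enc).shape == (2000,)


def test_unknown_character_names_position():
    enc = make_encoding(1, alphabet="AC")
    with pytest.raises(EncodingError, match=r"'D' at position 2"):
        ea.encode_sequence("AD", enc)


# --------------------------------------------------------------- architecture

@pytest.mark.parametrize("n,k,expected", [(2000, 36, 268), (100, 1, 10), (50, 7, 19)])
def test_pyramid_rule(n, k, expected):
    assert ea.pyramid_hidden_size(n, k) == expected


def test_forward_with_zero_weights_gives_half():
    params = NetworkParams(n=4, m=3, k=2)
    model = NetworkModel(
        params=params,
        W1=np.zeros((4, 3)), b1=np.zeros(3), W2=np.zeros((3, 2)), b2=np.zeros(2),
    )
    assert np.allclose(model.forward(np.ones(4)), 0.5)
    assert sigmoid(np.array(0.0)) == 0.5


def test_outputs_bounded_in_open_unit_interval():
    rng = np.random.default_rng(0)
    model = NetworkModel.initialize(NetworkParams(n=10, m=4, k=3, init_seed=1))
    for _ in range(100):
        y = model.forward(rng.integers(0, 2, size=10).astype(float))
        assert np.all((y > 0.0) & (y < 1.0))


def test_forward_rejects_wrong_input_size():
    model = NetworkModel.initialize(NetworkParams(n=6, m=3, k=2))
    with pytest.raises(Exception, match="shape"):
        model.forward(np.zeros(5))


# ------------------------------------------------------------------- training

def _finite_difference_grads(model, x, t, eps=1e-6):
    """Central-difference gradient of 0.5*||forward(x) - t||^2."""
    def loss():
        return 0.5 * float(np.sum((model.forward(x) - t) ** 2))

    grads = []
    for arr in (model.W1, model.b1, model.W2, model.b2):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            up = loss()
            arr[idx] = orig - eps
            down = loss()
            arr[idx] = orig
            g[idx] = (up - down) / (2 * eps)
        grads.append(g)
    return grads


def test_backprop_matches_finite_differences():
    rng = np.random.default_rng(123)
    model = NetworkModel.initialize(NetworkParams(n=6, m=3, k=2, init_seed=123))
    x = rng.integers(0, 2, size=6).astype(float)
    t = np.array([1.0, 0.0])
    analytic = model.gradients(x, t)
    numeric = _finite_difference_grads(model, x, t)
    for a, n in zip(analytic, numeric):
        assert np.max(np.abs(a - n)) / max(np.max(np.abs(n)), 1e-12) < 1e-5


def test_zero_momentum_updates_are_plain_gradient_steps():
    params = NetworkParams(n=5, m=3, k=2, momentum=0.0, learning_rate=0.3, init_seed=9)
    model = NetworkModel.initialize(params)
    reference = copy.deepcopy(model)
    x = np.array([1.0, 0.0, 1.0, 1.0, 0.0])
    t = np.array([0.0, 1.0])

    for _ in range(2):
        model._update(x, t)
        g = reference.gradients(x, t)
        reference.W1 -= params.learning_rate * g[0]
        reference.b1 -= params.learning_rate * g[1]
        reference.W2 -= params.learning_rate * g[2]
        reference.b2 -= params.learning_rate * g[3]
    assert np.allclose(model.W1, reference.W1) and np.allclose(model.W2, reference.W2)
    assert np.allclose(model.b1, reference.b1) and np.allclose(model.b2, reference.b2)


def test_perfect_model_stops_without_updating():
    """A model already below the RMSE target trains for zero epochs."""
    params = NetworkParams(n=2, m=2, k=1, rmse_target=0.45)
    model = NetworkModel(
        params=params, W1=np.zeros((2, 2)), b1=np.zeros(2), W2=np.zeros((2, 1)), b2=np.zeros(1)
    )
    W1_before = model.W1.copy()
    trained = train_online(model, [(np.zeros(2), np.array([0.5]))])
    assert trained.training_history == [0.0]
    assert np.array_equal(trained.W1, W1_before)


def test_training_reduces_rmse_and_reaches_target(single_net_ensemble, teaching_six):
    model = single_net_ensemble.members[0][1]
    history = model.training_history
    assert history[-1] < model.params.rmse_target
    assert history[-1] < history[0]
    assert len(history) <= model.params.max_epochs


def test_teaching_sequences_recognized_at_own_output(single_net_ensemble, teaching_six):
    for i, seq in enumerate(teaching_six):
        result = ea.recognize(single_net_ensemble, seq)
        assert int(np.argmax(result.similarity)) == i


# ------------------------------------------------------------------ ensembles

def _tiny_teaching_set():
    code = ea.get_genetic_code(1)
    return [
        ea.SequenceRecord(id=f"s{i}", residues=code.translate(ea.random_ancestor(10, code, i)))
        for i in range(2)
    ]


def _tiny_params():
    return NetworkParams(n=50, m=10, k=2, rmse_target=0.05, max_epochs=2000)


def test_same_master_seed_gives_identical_ensembles():
    seqs = _tiny_teaching_set()
    e1 = ea.teach_ensemble(seqs, _tiny_params(), n_versions=2, master_seed=5)
    e2 = ea.teach_ensemble(seqs, _tiny_params(), n_versions=2, master_seed=5)
    for (enc1, m1), (enc2, m2) in zip(e1.members, e2.members):
        assert enc1.code_map == enc2.code_map
        assert np.array_equal(m1.W1, m2.W1) and np.array_equal(m1.W2, m2.W2)
    r1 = ea.recognize(e1, seqs[0]).similarity
    r2 = ea.recognize(e2, seqs[0]).similarity
    assert np.array_equal(r1, r2)


def test_single_member_mean_equals_raw_output():
    seqs = _tiny_teaching_set()
    ens = ea.teach_ensemble(seqs, _tiny_params(), n_versions=1, master_seed=3)
    result = ea.recognize(ens, seqs[1])
    assert np.array_equal(result.similarity, result.per_member[0])


def test_similarity_is_mean_of_member_outputs(five_net_ensemble, teaching_six):
    result = ea.recognize(five_net_ensemble, teaching_six[0])
    assert np.allclose(result.similarity, result.per_member.mean(axis=0), atol=1e-12)
    assert np.all((result.similarity > 0) & (result.similarity < 1))


def test_one_hot_targets_orientation():
    t = one_hot_targets(3)
    assert np.array_equal(t, np.eye(3))


def test_archive_roundtrip_is_bit_exact(tmp_path, five_net_ensemble):
    ea.save_ensemble(five_net_ensemble, tmp_path / "model")
    loaded = ea.load_ensemble(tmp_path / "model")
    assert loaded.teaching_ids == five_net_ensemble.teaching_ids
    for (enc1, m1), (enc2, m2) in zip(five_net_ensemble.members, loaded.members):
        assert enc1 == enc2
        assert m1.params == m2.params
        for name in ("W1", "b1", "W2", "b2"):
            assert np.array_equal(getattr(m1, name), getattr(m2, name))
        assert m1.training_history == m2.training_history
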