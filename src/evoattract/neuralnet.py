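"""Randomly-encoded three-layer sigmoid MLP ensemble for sequence recognition.

Each ensemble member pairs a random five-bit-per-character encoding of the
amino-acid alphabet with a fully-connected input->hidden->output network of
sigmoid units, trained by on-line backpropagation with momentum against
one-hot targets (one output neuron per teaching organism).  Recognition of
an examined sequence is the arithmetic mean of the member outputs, giving a
similarity in [0, 1] to every teaching organism.  Averaging over many
independent random encodings neutralizes the influence any particular
character coding has on the recognized similarities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .seqio import SequenceRecord

CODE_BITS = 5

#: Default encodable alphabet: 20 standard residues, the pad character, and
#: tolerated ambiguity codes (28 symbols, within the 2^5 = 32 code capacity).
DEFAULT_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-XBZJUO*"


class EncodingError(ValueError):
    pass


class NetworkError(ValueError):
    pass


class DivergenceError(RuntimeError):
    """Raised when weights become non-finite during training."""


@dataclass(frozen=True)
class EncodingTable:
    """Seeded map from character to a five-bit binary code."""

    seed: int
    code_map: dict[str, tuple[int, ...]]

    def encode(self, seq: str) -> np.ndarray:
        return encode_sequence(seq, self)

    def decode(self, bits: np.ndarray) -> str:
        """Invert the code table (valid because codes are distinct)."""
        inverse = {code: ch for ch, code in self.code_map.items()}
        flat = np.asarray(bits).ravel()
        if flat.size % CODE_BITS:
            raise EncodingError(f"bit-vector length {flat.size} not divisible by {CODE_BITS}")
        out = []
        for i in range(0, flat.size, CODE_BITS):
            code = tuple(int(b) for b in flat[i : i + CODE_BITS])
            if code not in inverse:
                raise EncodingError(f"code {code} at position {i // CODE_BITS + 1} is unmapped")
            out.append(inverse[code])
        return "".join(out)


def make_encoding(seed: int, alphabet: str = DEFAULT_ALPHABET, distinct: bool = True) -> EncodingTable:
    """Draw a random five-bit code for every character of ``alphabet``.

    By default codes are sampled without replacement from the 32 possible
    five-bit words, so distinct characters never collide; ``distinct=False``
    samples codes independently (collisions possible).
    """
    if len(set(alphabet)) != len(alphabet):
        raise EncodingError("alphabet contains repeated characters")
    if distinct and len(alphabet) > 2**CODE_BITS:
        raise EncodingError(
            f"alphabet of {len(alphabet)} symbols exceeds the {2**CODE_BITS} "
            f"distinct {CODE_BITS}-bit codes"
        )
    rng = np.random.default_rng(seed)
    if distinct:
        words = rng.choice(2**CODE_BITS, size=len(alphabet), replace=False)
    else:
        words = rng.integers(0, 2**CODE_BITS, size=len(alphabet))
    code_map = {
        ch: tuple((int(w) >> (CODE_BITS - 1 - b)) & 1 for b in range(CODE_BITS))
        for ch, w in zip(alphabet, words)
    }
    return EncodingTable(seed=seed, code_map=code_map)


def encode_sequence(seq: str, enc: EncodingTable) -> np.ndarray:
    """Concatenate per-character codes into a float bit vector of length 5*len(seq)."""
    out = np.empty(len(seq) * CODE_BITS, dtype=np.float64)
    for i, ch in enumerate(seq):
        code = enc.code_map.get(ch)
        if code is None:
            raise EncodingError(f"character {ch!r} at position {i + 1} has no code")
        out[i * CODE_BITS : (i + 1) * CODE_BITS] = code
    return out


def pyramid_hidden_size(n: int, k: int) -> int:
    """Geometric pyramid rule: hidden size = round(sqrt(n * k))."""
    if n < 1 or k < 1:
        raise NetworkError("layer sizes must be >= 1")
    return round(float(np.sqrt(n * k)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class NetworkParams:
    """Architecture and training hyperparameters of one MLP."""

    n: int
    m: int
    k: int
    learning_rate: float = 0.3
    momentum: float = 0.1
    rmse_target: float = 0.001
    max_epochs: int = 10_000
    init_seed: int = 0
    input_activation: str = "sigmoid"  # "sigmoid" | "linear"
    shuffle_seed: int | None = None  # None = fixed pattern order

    def __post_init__(self) -> None:
        if min(self.n, self.m, self.k) < 1:
            raise NetworkError("layer sizes must be >= 1")
        if self.learning_rate <= 0:
            raise NetworkError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise NetworkError("momentum must be in [0, 1)")
        if self.rmse_target <= 0:
            raise NetworkError("rmse_target must be > 0")
        if self.input_activation not in ("sigmoid", "linear"):
            raise NetworkError("input_activation must be 'sigmoid' or 'linear'")


@dataclass
class NetworkModel:
    """Weights (with biases) and state of one three-layer sigmoid MLP."""

    params: NetworkParams
    W1: np.ndarray  # (n, m)
    b1: np.ndarray  # (m,)
    W2: np.ndarray  # (m, k)
    b2: np.ndarray  # (k,)
    prev_dW1: np.ndarray = field(default=None)  # type: ignore[assignment]
    prev_db1: np.ndarray = field(default=None)  # type: ignore[assignment]
    prev_dW2: np.ndarray = field(default=None)  # type: ignore[assignment]
    prev_db2: np.ndarray = field(default=None)  # type: ignore[assignment]
    training_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = self.params
        if self.W1.shape != (p.n, p.m) or self.W2.shape != (p.m, p.k):
            raise NetworkError(
                f"weight shapes {self.W1.shape}/{self.W2.shape} inconsistent with "
                f"params n={p.n}, m={p.m}, k={p.k}"
            )
        for name in ("prev_dW1", "prev_db1", "prev_dW2", "prev_db2"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros_like(getattr(self, name.removeprefix("prev_d"))))

    @classmethod
    def initialize(cls, params: NetworkParams) -> "NetworkModel":
        """Seeded uniform [-0.5, 0.5] initialization of all weights and biases."""
        rng = np.random.default_rng(params.init_seed)
        return cls(
            params=params,
            W1=rng.uniform(-0.5, 0.5, size=(params.n, params.m)),
            b1=rng.uniform(-0.5, 0.5, size=params.m),
            W2=rng.uniform(-0.5, 0.5, size=(params.m, params.k)),
            b2=rng.uniform(-0.5, 0.5, size=params.k),
        )

    def _input_layer(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(x) if self.params.input_activation == "sigmoid" else x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Propagate one input pattern; outputs strictly in (0, 1)."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (self.params.n,):
            raise NetworkError(f"input shape {x.shape} != ({self.params.n},)")
        a0 = self._input_layer(x)
        h = sigmoid(a0 @ self.W1 + self.b1)
        return sigmoid(h @ self.W2 + self.b2)

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        a0 = self._input_layer(X)
        H = sigmoid(a0 @ self.W1 + self.b1)
        return sigmoid(H @ self.W2 + self.b2)

    def gradients(
        self, x: np.ndarray, t: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Backpropagated gradients of 0.5*||y - t||^2 for one pattern."""
        a0 = self._input_layer(np.asarray(x, dtype=np.float64))
        h = sigmoid(a0 @ self.W1 + self.b1)
        y = sigmoid(h @ self.W2 + self.b2)
        delta_o = (y - t) * y * (1.0 - y)
        delta_h = (self.W2 @ delta_o) * h * (1.0 - h)
        return (
            np.outer(a0, delta_h),
            delta_h,
            np.outer(h, delta_o),
            delta_o,
        )

    def _update(self, x: np.ndarray, t: np.ndarray) -> None:
        gW1, gb1, gW2, gb2 = self.gradients(x, t)
        lr, mom = self.params.learning_rate, self.params.momentum
        self.prev_dW1 = -lr * gW1 + mom * self.prev_dW1
        self.prev_db1 = -lr * gb1 + mom * self.prev_db1
        self.prev_dW2 = -lr * gW2 + mom * self.prev_dW2
        self.prev_db2 = -lr * gb2 + mom * self.prev_db2
        self.W1 += self.prev_dW1
        self.b1 += self.prev_db1
        self.W2 += self.prev_dW2
        self.b2 += self.prev_db2

    def rmse(self, X: np.ndarray, T: np.ndarray) -> float:
        """Root mean squared error over all patterns and output units."""
        Y = self.forward_batch(X)
        return float(np.sqrt(np.mean((Y - T) ** 2)))


def train_online(
    model: NetworkModel,
    patterns: list[tuple[np.ndarray, np.ndarray]],
) -> NetworkModel:
    """On-line backpropagation until epoch RMSE < rmse_target or max_epochs.

    Weights are updated after every pattern presentation; the update is
    ``-lr * gradient + momentum * previous_update``.  Patterns are presented
    in fixed file order each epoch unless ``params.shuffle_seed`` is set.
    Epoch RMSE is evaluated over all patterns after the epoch's updates and
    appended to ``model.training_history``.
    """
    if not patterns:
        raise NetworkError("no training patterns")
    X = np.stack([x for x, _ in patterns])
    T = np.stack([t for _, t in patterns])
    p = model.params
    order_rng = np.random.default_rng(p.shuffle_seed) if p.shuffle_seed is not None else None

    rmse = model.rmse(X, T)
    if rmse < p.rmse_target:
        model.training_history.append(rmse)
        return model

    for epoch in range(1, p.max_epochs + 1):
        order = (
            order_rng.permutation(len(patterns)) if order_rng is not None else range(len(patterns))
        )
        for i in order:
            model._update(X[i], T[i])
        if not (np.isfinite(model.W1).all() and np.isfinite(model.W2).all()):
            raise DivergenceError(f"non-finite weights at epoch {epoch}")
        rmse = model.rmse(X, T)
        model.training_history.append(rmse)
        if rmse < p.rmse_target:
            break
    return model


def one_hot_targets(k: int) -> np.ndarray:
    """Teaching target matrix: sequence i maps to 1 at output i."""
    return np.eye(k, dtype=np.float64)


@dataclass
class Ensemble:
    """Teaching-set recognizer: many (encoding, network) pairs averaged."""

    members: list[tuple[EncodingTable, NetworkModel]]
    teaching_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for _, model in self.members:
            if model.params.k != len(self.teaching_ids):
                raise NetworkError("member output size != number of teaching organisms")

    @property
    def n_versions(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RecognitionResult:
    """Mean similarity of one examined organism to every teaching organism."""

    organism_id: str
    teaching_ids: tuple[str, ...]
    similarity: np.ndarray  # (k,), ensemble mean, in [0, 1]
    per_member: np.ndarray  # (n_versions, k)

    @property
    def best_match(self) -> str:
        return self.teaching_ids[int(np.argmax(self.similarity))]


def _member_seeds(master_seed: int, n_versions: int) -> list[tuple[int, int]]:
    """Deterministic (encoding_seed, init_seed) pairs derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [
        tuple(int(s) for s in child.generate_state(2) % (2**31))
        for child in ss.spawn(n_versions)
    ]


def teach_ensemble(
    teaching_seqs: list[SequenceRecord],
    params: NetworkParams,
    n_versions: int = 50,
    master_seed: int = 0,
    alphabet: str = DEFAULT_ALPHABET,
) -> Ensemble:
    """Train ``n_versions`` networks, each with its own random character coding.

    ``params.n`` must equal 5x the (already normalized) sequence length and
    ``params.k`` the number of teaching sequences.  A member that exhausts
    ``max_epochs`` without reaching ``rmse_target`` keeps its history (the
    final RMSE documents the shortfall); this is not fatal.
    """
    if not teaching_seqs:
        raise NetworkError("teaching set is empty")
    k = len(teaching_seqs)
    if params.k != k:
        raise NetworkError(f"params.k={params.k} != number of teaching sequences {k}")
    lengths = {len(s.residues) for s in teaching_seqs}
    if len(lengths) != 1 or lengths.pop() * CODE_BITS != params.n:
        raise NetworkError(
            "teaching sequences must share one length equal to params.n / 5 "
            "(normalize with pad_or_trim first)"
        )
    targets = one_hot_targets(k)
    members: list[tuple[EncodingTable, NetworkModel]] = []
    for enc_seed, init_seed in _member_seeds(master_seed, n_versions):
        enc = make_encoding(enc_seed, alphabet)
        model = NetworkModel.initialize(replace(params, init_seed=init_seed))
        patterns = [
            (encode_sequence(s.residues, enc), targets[i]) for i, s in enumerate(teaching_seqs)
        ]
        train_online(model, patterns)
        members.append((enc, model))
    return Ensemble(members=members, teaching_ids=tuple(s.id for s in teaching_seqs))


def recognize(ens: Ensemble, seq: SequenceRecord) -> RecognitionResult:
    """Recognize one examined organism: mean member output per teaching organism."""
    per_member = np.stack(
        [model.forward(encode_sequence(seq.residues, enc)) for enc, model in ens.members]
    )
    return RecognitionResult(
        organism_id=seq.id,
        teaching_ids=ens.teaching_ids,
        similarity=per_member.mean(axis=0),
        per_member=per_member,
    )


# ---------------------------------------------------------------------------
# Model archive: directory with ensemble.json (params, encodings, histories)
# and weights.npz; round-trips bit-exactly.

def save_ensemble(ens: Ensemble, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "teaching_ids": list(ens.teaching_ids),
        "members": [
            {
                "encoding_seed": enc.seed,
                "code_map": {ch: list(code) for ch, code in enc.code_map.items()},
                "params": asdict(model.params),
                "training_history": model.training_history,
            }
            for enc, model in ens.members
        ],
    }
    (path / "ensemble.json").write_text(json.dumps(meta, indent=1))
    arrays = {}
    for i, (_, model) in enumerate(ens.members):
        for name in ("W1", "b1", "W2", "b2"):
            arrays[f"member{i}_{name}"] = getattr(model, name)
    np.savez(path / "weights.npz", **arrays)


def load_ensemble(path: str | Path) -> Ensemble:
    path = Path(path)
    meta = json.loads((path / "ensemble.json").read_text())
    arrays = np.load(path / "weights.npz")
    members = []
    for i, m in enumerate(meta["members"]):
        enc = EncodingTable(
            seed=m["encoding_seed"],
            code_map={ch: tuple(code) for ch, code in m["code_map"].items()},
        )
        model = NetworkModel(
            params=NetworkParams(**m["params"]),
            W1=arrays[f"member{i}_W1"],
            b1=arrays[f"member{i}_b1"],
            W2=arrays[f"member{i}_W2"],
            b2=arrays[f"member{i}_b2"],
            training_history=list(m["training_history"]),
        )
        members.append((enc, model))
    return Ensemble(members=members, teaching_ids=tuple(meta["teaching_ids"]))
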