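"""Feed-forward window scorer: training, inference, text serialization.

The scorer is a small fully connected network with logistic activations
throughout, mapping one encoded window (156 bits, or 195 with the
secondary-structure channel) to a score in [0, 1]. It is trained by
seeded mini-batch gradient descent on weighted cross-entropy with early
stopping on a held-out validation slice. All randomness (initialization,
shuffling, validation split) flows from one explicit seed, so training is
bit-reproducible.

Models serialize to versioned JSON that embeds the reduced alphabet and
feature configuration; ``load_model(save_model(m))`` reproduces forward
outputs exactly (JSON floats round-trip Python floats losslessly).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence, Union

import numpy as np

from .encoding import (
    DEFAULT_ALPHABET,
    ReducedAlphabet,
    encode_sequence,
    encode_window,
    feature_length,
)
from .params import DEFAULT_PARAMETERS, Parameters
from .segment_caller import WindowScoreProfile
from .sequence_io import SequenceRecord

FORMAT_VERSION = 1


class ModelError(ValueError):
    """Invalid model configuration, file, or input dimensions."""


class TrainingError(RuntimeError):
    """Training failed (empty class, non-finite loss...)."""


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # piecewise form is stable for large |z|
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _alphabet_checksum(alphabet: ReducedAlphabet) -> str:
    payload = alphabet.name + ":" + ",".join(alphabet.groups)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Hyperparameters:
    """Training knobs; defaults train in seconds on a desk-scale corpus."""

    hidden_sizes: tuple[int, ...] = (10,)
    learning_rate: float = 0.5
    epochs: int = 200
    batch_size: int = 64
    l2: float = 1e-4
    validation_fraction: float = 0.1
    patience: int = 20
    #: "balanced" gives both classes equal effective weight regardless of
    #: their counts (the negative corpus is typically much larger);
    #: "none" weights every window equally.
    class_weight: str = "balanced"


@dataclass
class Model:
    """A trained window scorer.

    ``weights``/``biases`` hold one matrix/vector per layer, hidden layers
    first, then the single output unit. ``forward`` output is always in
    (0, 1) for finite weights because every layer is logistic.
    """

    alphabet: ReducedAlphabet
    hidden_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    with_structure: bool = False
    window_length: int = 13
    activation: str = "logistic"
    training_metadata: dict = field(default_factory=dict)

    @property
    def input_size(self) -> int:
        return int(self.weights[0].shape[0])

    def __post_init__(self) -> None:
        expected = feature_length(self.alphabet, self.with_structure,
                                  self.window_length)
        if self.input_size != expected:
            raise ModelError(
                f"input size {self.input_size} does not match the encoding's "
                f"feature length {expected} for this alphabet/structure setting"
            )

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Score encoded windows; accepts one vector or a matrix of rows."""
        x = np.asarray(features, dtype=np.float64)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != self.input_size:
            raise ModelError(
                f"feature length mismatch: expected {self.input_size}, "
                f"got {x.shape[1]}"
            )
        a = x
        for W, b in zip(self.weights, self.biases):
            a = _sigmoid(a @ W + b)
        scores = a[:, 0]
        return scores[0] if single else scores

    def score_window(self, window: str, structure: str | None = None) -> float:
        """Convenience: encode one 13-mer and score it."""
        feats = encode_window(window, self.alphabet, structure,
                              window_length=self.window_length)
        return float(self.forward(feats.bits))


def score_windows(model: Model, record: SequenceRecord,
                  structure: str | None = None,
                  params: Parameters = DEFAULT_PARAMETERS) -> WindowScoreProfile:
    """Score every sliding window of a record.

    Sequences shorter than one window yield an empty profile flagged
    ``too_short`` rather than an error, so batch runs never abort.
    """
    L = len(record.residues)
    if L < params.window_length:
        return WindowScoreProfile(sequence_name=record.name, length=L,
                                  scores=(), too_short=True)
    X = encode_sequence(record, model.alphabet, structure, params)
    scores = model.forward(X)
    return WindowScoreProfile(sequence_name=record.name, length=L,
                              scores=tuple(float(s) for s in scores))


def _init_layers(sizes: Sequence[int], rng: np.random.Generator
                 ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        scale = 1.0 / np.sqrt(n_in)
        weights.append(rng.uniform(-scale, scale, size=(n_in, n_out)))
        biases.append(np.zeros(n_out))
    return weights, biases


def _forward_pass(X: np.ndarray, weights, biases) -> list[np.ndarray]:
    acts = [X]
    for W, b in zip(weights, biases):
        acts.append(_sigmoid(acts[-1] @ W + b))
    return acts


def _bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))) / np.sum(w))


def train(positives: Sequence[str], negatives: Sequence[str],
          hyperparams: Hyperparameters | None = None,
          seed: int = 0,
          alphabet: ReducedAlphabet = DEFAULT_ALPHABET,
          window_length: int = 13) -> Model:
    """Train a scorer from labeled 13-mer windows.

    Parameters
    ----------
    positives, negatives:
        Window strings (each of ``window_length`` standard residues) for
        the NoLS and background classes. Both must be non-empty.
    seed:
        Drives initialization, shuffling and the validation split;
        identical inputs and seed give identical weights.

    Returns
    -------
    Model with ``training_metadata`` recording the seed, epochs run, final
    losses and corpus summary.
    """
    hp = hyperparams or Hyperparameters()
    if len(positives) == 0 or len(negatives) == 0:
        raise TrainingError("both classes must be non-empty")

    enc = lambda wins: np.vstack([
        encode_window(w, alphabet, window_length=window_length).bits
        for w in wins
    ])
    X = np.vstack([enc(positives), enc(negatives)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    if hp.class_weight == "balanced":
        n = len(y)
        w = np.where(y == 1, n / (2.0 * len(positives)), n / (2.0 * len(negatives)))
    else:
        w = np.ones_like(y)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    X, y, w = X[order], y[order], w[order]
    n_val = max(1, int(round(hp.validation_fraction * len(y)))) \
        if hp.validation_fraction > 0 and len(y) >= 10 else 0
    X_val, y_val, w_val = X[:n_val], y[:n_val], w[:n_val]
    X_tr, y_tr, w_tr = X[n_val:], y[n_val:], w[n_val:]

    sizes = [X.shape[1], *hp.hidden_sizes, 1]
    weights, biases = _init_layers(sizes, rng)

    best_val = np.inf
    best = None
    since_best = 0
    train_losses: list[float] = []
    n_tr = len(y_tr)
    for epoch in range(hp.epochs):
        perm = rng.permutation(n_tr)
        for lo in range(0, n_tr, hp.batch_size):
            idx = perm[lo:lo + hp.batch_size]
            Xb, yb, wb = X_tr[idx], y_tr[idx], w_tr[idx]
            acts = _forward_pass(Xb, weights, biases)
            p = acts[-1][:, 0]
            # weighted-BCE + logistic output: delta = w * (p - y) / sum(w)
            delta = (wb * (p - yb) / np.sum(wb))[:, None]
            for layer in range(len(weights) - 1, -1, -1):
                gW = acts[layer].T @ delta + hp.l2 * weights[layer]
                gb = delta.sum(axis=0)
                if layer > 0:
                    a = acts[layer]
                    delta = (delta @ weights[layer].T) * a * (1 - a)
                weights[layer] -= hp.learning_rate * gW
                biases[layer] -= hp.learning_rate * gb
        p_tr = _forward_pass(X_tr, weights, biases)[-1][:, 0]
        loss_tr = _bce(p_tr, y_tr, w_tr)
        if not np.isfinite(loss_tr):
            raise TrainingError(
                f"non-finite training loss at epoch {epoch}: {loss_tr}"
            )
        train_losses.append(loss_tr)
        if n_val:
            p_val = _forward_pass(X_val, weights, biases)[-1][:, 0]
            loss_val = _bce(p_val, y_val, w_val)
            if loss_val < best_val - 1e-6:
                best_val = loss_val
                best = ([W.copy() for W in weights], [b.copy() for b in biases])
                since_best = 0
            else:
                since_best += 1
                if since_best >= hp.patience:
                    break
    if best is not None:
        weights, biases = best

    meta = {
        "seed": int(seed),
        "epochs_run": len(train_losses),
        "final_train_loss": train_losses[-1],
        "best_validation_loss": None if not n_val else best_val,
        "train_losses": [train_losses[0], train_losses[-1]],
        "n_positive": len(positives),
        "n_negative": len(negatives),
        "hyperparameters": {
            "hidden_sizes": list(hp.hidden_sizes),
            "learning_rate": hp.learning_rate,
            "epochs": hp.epochs,
            "batch_size": hp.batch_size,
            "l2": hp.l2,
            "class_weight": hp.class_weight,
        },
    }
    return Model(alphabet=alphabet, hidden_sizes=tuple(hp.hidden_sizes),
                 weights=weights, biases=biases, window_length=window_length,
                 training_metadata=meta)


def save_model(model: Model, sink: Union[str, Path, IO[str]]) -> None:
    """Write a model as versioned, self-describing JSON text."""
    doc = {
        "format": "nolscan-model",
        "format_version": FORMAT_VERSION,
        "alphabet": model.alphabet.to_dict(),
        "alphabet_checksum": _alphabet_checksum(model.alphabet),
        "window_length": model.window_length,
        "with_structure": model.with_structure,
        "activation": model.activation,
        "hidden_sizes": list(model.hidden_sizes),
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "training_metadata": model.training_metadata,
    }
    if hasattr(sink, "write"):
        json.dump(doc, sink)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)


def load_model(source: Union[str, Path, IO[str]]) -> Model:
    """Read a model written by :func:`save_model`, validating integrity."""
    try:
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise ModelError(f"corrupted model file: {e}") from e
    if doc.get("format") != "nolscan-model":
        raise ModelError("not a nolscan model file")
    if doc.get("format_version") != FORMAT_VERSION:
        raise ModelError(
            f"unsupported model format version {doc.get('format_version')!r} "
            f"(expected {FORMAT_VERSION})"
        )
    alphabet = ReducedAlphabet.from_dict(doc["alphabet"])
    if doc.get("alphabet_checksum") != _alphabet_checksum(alphabet):
        raise ModelError("alphabet checksum mismatch: model file is inconsistent")
    return Model(
        alphabet=alphabet,
        hidden_sizes=tuple(doc["hidden_sizes"]),
        weights=[np.asarray(W, dtype=np.float64) for W in doc["weights"]],
        biases=[np.asarray(b, dtype=np.float64) for b in doc["biases"]],
        with_structure=bool(doc["with_structure"]),
        window_length=int(doc["window_length"]),
        activation=doc.get("activation", "logistic"),
        training_metadata=doc.get("training_metadata", {}),
    )
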