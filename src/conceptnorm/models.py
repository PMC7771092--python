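"""Shallow neural architectures mapping mention matrices to concept vectors.

Three architectures share one input, a zero-padded (L, D) matrix of token
embeddings with a validity mask:

* ``slfnn`` — masked mean over real token rows followed by a dense linear
  map to the N-dimensional concept space (no nonlinearity);
* ``cnn`` — a 1-D convolution (N filters of a single width over the token
  axis), max-pooling over valid positions per filter, then an activation;
* ``cnorm`` — both branches in parallel on the same input, combined by an
  elementwise averaging layer and trained end-to-end through the single
  averaged output.

Training minimizes the log-cosh regression loss between the model output
and the target concept's hierarchy-encoded vector, with the Nadam
optimizer.  Everything is plain numpy with hand-derived gradients — the
models are small enough that no autodiff framework is warranted, and this
keeps the forward pass trivially auditable against the straight-line
oracles in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from conceptnorm.errors import ValidationError
from conceptnorm.corpus_io import TrainingExample
from conceptnorm.ontology import ConceptVectorSpace
from conceptnorm.text import EmbeddingTable, batch_matrices

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "build_slfnn",
    "build_cnn",
    "build_cnorm",
    "build_model",
    "train",
    "predict_vectors",
    "default_epochs",
]

logger = logging.getLogger(__name__)

ARCHITECTURES = ("slfnn", "cnn", "cnorm")

#: Epoch counts tuned per architecture and entity class.
_DEFAULT_EPOCHS = {
    ("slfnn", "habitat"): 50,
    ("slfnn", "phenotype"): 100,
    ("cnn", "habitat"): 150,
    ("cnn", "phenotype"): 50,
    ("cnorm", "habitat"): 200,
    ("cnorm", "phenotype"): 30,
}


def default_epochs(architecture: str, entity_class: str = "habitat") -> int:
    """Default training epochs for an architecture/entity-class pair."""
    return _DEFAULT_EPOCHS[(architecture, entity_class)]


@dataclass
class ModelConfig:
    architecture: str = "cnorm"
    epochs: int = 200
    optimizer: str = "nadam"
    loss: str = "log_cosh"
    filter_size: int = 1
    activation: str = "leaky_relu"
    leaky_slope: float = 0.3
    pad_length: int | None = None
    batch_size: int = 32
    learning_rate: float = 0.005
    seed: int = 0
    decay: float = 0.6

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.filter_size < 1:
            raise ValueError("filter_size must be >= 1")


# ---------------------------------------------------------------------------
# activations

_ACTIVATIONS = {"leaky_relu", "relu", "tanh", "linear"}


def _activate(z: np.ndarray, name: str, slope: float) -> np.ndarray:
    if name == "leaky_relu":
        return np.where(z > 0, z, slope * z)
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    if name == "linear":
        return z
    raise ValueError(f"unknown activation {name!r}")


def _activate_grad(z: np.ndarray, name: str, slope: float) -> np.ndarray:
    if name == "leaky_relu":
        return np.where(z > 0, 1.0, slope)
    if name == "relu":
        return np.where(z > 0, 1.0, 0.0)
    if name == "tanh":
        return 1.0 - np.tanh(z) ** 2
    if name == "linear":
        return np.ones_like(z)
    raise ValueError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# architectures


class _Architecture:
    """Common interface: parameter dict, batched forward, backward."""

    name: str
    params: dict[str, np.ndarray]

    def forward(self, x: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, dict]:
        raise NotImplementedError

    def backward(self, cache: dict, grad_out: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class SLFNN(_Architecture):
    """Masked mean over real token rows, then a dense linear map to N dims."""

    name = "slfnn"

    def __init__(self, embedding_dim: int, n_concepts: int, rng: np.random.Generator | None = None):
        if embedding_dim < 1 or n_concepts < 1:
            raise ValueError("dimensions must be >= 1")
        self.embedding_dim = embedding_dim
        self.n_concepts = n_concepts
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": _glorot(rng, (n_concepts, embedding_dim), embedding_dim, n_concepts),
            "b": np.zeros(n_concepts),
        }

    def forward(self, x: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, dict]:
        counts = mask.sum(axis=1)  # (B,)
        safe = np.maximum(counts, 1)
        mean = (x * mask[:, :, None]).sum(axis=1) / safe[:, None]  # (B, D)
        out = mean @ self.params["W"].T + self.params["b"]
        return out, {"mean": mean}

    def backward(self, cache: dict, grad_out: np.ndarray) -> dict[str, np.ndarray]:
        return {
            "W": grad_out.T @ cache["mean"],
            "b": grad_out.sum(axis=0),
        }


class ShallowCNN(_Architecture):
    """Width-``filter_size`` convolution, masked max-pool, activation.

    One filter per concept; pooling runs over windows lying entirely inside
    the real (non-pad) token rows.  A mention shorter than the filter has no
    valid window, in which case pooling falls back to the first (partially
    padded) window.
    """

    name = "cnn"

    def __init__(
        self,
        embedding_dim: int,
        n_concepts: int,
        pad_length: int,
        filter_size: int = 1,
        activation: str = "leaky_relu",
        leaky_slope: float = 0.3,
        rng: np.random.Generator | None = None,
    ):
        if filter_size > pad_length:
            raise ValueError(
                f"filter_size {filter_size} exceeds pad_length {pad_length}"
            )
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.embedding_dim = embedding_dim
        self.n_concepts = n_concepts  # == number of filters
        self.pad_length = pad_length
        self.filter_size = filter_size
        self.activation = activation
        self.leaky_slope = leaky_slope
        rng = rng or np.random.default_rng(0)
        fan_in = filter_size * embedding_dim
        self.params = {
            "F": _glorot(
                rng, (n_concepts, filter_size, embedding_dim), fan_in, n_concepts
            ),
            "c": np.zeros(n_concepts),
        }

    def forward(self, x: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, dict]:
        b, length, _ = x.shape
        f = self.filter_size
        n_windows = length - f + 1
        # (B, n_windows, f, D) view of consecutive token rows
        windows = np.lib.stride_tricks.sliding_window_view(x, f, axis=1)
        windows = windows.transpose(0, 1, 3, 2)
        pre = (
            np.einsum("btfd,kfd->btk", windows, self.params["F"])
            + self.params["c"]
        )  # (B, n_windows, N)
        counts = mask.sum(axis=1)  # (B,)
        # window t is valid iff t + f <= n_tokens
        t_idx = np.arange(n_windows)
        valid = t_idx[None, :] + f <= counts[:, None]  # (B, n_windows)
        no_valid = ~valid.any(axis=1)
        if no_valid.any():
            # short mention: pool over the first (padded) window
            valid = valid.copy()
            valid[no_valid, 0] = True
        masked = np.where(valid[:, :, None], pre, -np.inf)
        argmax = masked.argmax(axis=1)  # (B, N)
        z = np.take_along_axis(masked, argmax[:, None, :], axis=1)[:, 0, :]
        out = _activate(z, self.activation, self.leaky_slope)
        return out, {"windows": windows, "argmax": argmax, "z": z}

    def backward(self, cache: dict, grad_out: np.ndarray) -> dict[str, np.ndarray]:
        z = cache["z"]
        gz = grad_out * _activate_grad(z, self.activation, self.leaky_slope)
        windows, argmax = cache["windows"], cache["argmax"]
        batch = np.arange(windows.shape[0])
        # window that won the max-pool for each (example, filter)
        gathered = windows[batch[:, None], argmax]  # (B, N, f, D)
        return {
            "F": np.einsum("bk,bkfd->kfd", gz, gathered),
            "c": gz.sum(axis=0),
        }


class CNormEnsemble(_Architecture):
    """Feedforward and convolutional branches averaged elementwise.

    The two branches share nothing but the input; during training the
    gradient of the single loss flows to both through the averaging layer.
    """

    name = "cnorm"

    def __init__(
        self,
        embedding_dim: int,
        n_concepts: int,
        pad_length: int,
        filter_size: int = 1,
        activation: str = "leaky_relu",
        leaky_slope: float = 0.3,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.linear = SLFNN(embedding_dim, n_concepts, rng)
        self.conv = ShallowCNN(
            embedding_dim,
            n_concepts,
            pad_length,
            filter_size,
            activation,
            leaky_slope,
            rng,
        )
        self.embedding_dim = embedding_dim
        self.n_concepts = n_concepts
        self.pad_length = pad_length

    @property
    def params(self) -> dict[str, np.ndarray]:
        out = {f"linear.{k}": v for k, v in self.linear.params.items()}
        out.update({f"conv.{k}": v for k, v in self.conv.params.items()})
        return out

    @params.setter
    def params(self, values: dict[str, np.ndarray]) -> None:
        for key, v in values.items():
            branch, name = key.split(".", 1)
            getattr(self, "linear" if branch == "linear" else "conv").params[name] = v

    def forward(self, x: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, dict]:
        o1, c1 = self.linear.forward(x, mask)
        o2, c2 = self.conv.forward(x, mask)
        return 0.5 * (o1 + o2), {"linear": c1, "conv": c2}

    def backward(self, cache: dict, grad_out: np.ndarray) -> dict[str, np.ndarray]:
        half = 0.5 * grad_out
        g1 = self.linear.backward(cache["linear"], half)
        g2 = self.conv.backward(cache["conv"], half)
        out = {f"linear.{k}": v for k, v in g1.items()}
        out.update({f"conv.{k}": v for k, v in g2.items()})
        return out


def build_slfnn(
    embedding_dim: int, n_concepts: int, seed: int = 0
) -> SLFNN:
    """Untrained feedforward model (``D*N + N`` trainable parameters)."""
    return SLFNN(embedding_dim, n_concepts, np.random.default_rng(seed))


def build_cnn(
    embedding_dim: int,
    n_concepts: int,
    pad_length: int,
    filter_size: int = 1,
    activation: str = "leaky_relu",
    leaky_slope: float = 0.3,
    seed: int = 0,
) -> ShallowCNN:
    """Untrained convolutional model with one filter per concept."""
    return ShallowCNN(
        embedding_dim,
        n_concepts,
        pad_length,
        filter_size,
        activation,
        leaky_slope,
        np.random.default_rng(seed),
    )


def build_cnorm(
    embedding_dim: int,
    n_concepts: int,
    pad_length: int,
    filter_size: int = 1,
    activation: str = "leaky_relu",
    leaky_slope: float = 0.3,
    seed: int = 0,
) -> CNormEnsemble:
    """Untrained averaging ensemble of the two branch architectures."""
    return CNormEnsemble(
        embedding_dim,
        n_concepts,
        pad_length,
        filter_size,
        activation,
        leaky_slope,
        np.random.default_rng(seed),
    )


def build_model(
    embedding_dim: int, n_concepts: int, config: ModelConfig
) -> _Architecture:
    """Dispatch on ``config.architecture``; ``pad_length`` must be set for cnn/cnorm."""
    if config.architecture == "slfnn":
        return build_slfnn(embedding_dim, n_concepts, config.seed)
    if config.pad_length is None:
        raise ValueError("pad_length must be set before building a cnn/cnorm model")
    builder = build_cnn if config.architecture == "cnn" else build_cnorm
    return builder(
        embedding_dim,
        n_concepts,
        config.pad_length,
        config.filter_size,
        config.activation,
        config.leaky_slope,
        config.seed,
    )


# ---------------------------------------------------------------------------
# loss and optimizer


def _log_cosh(err: np.ndarray) -> np.ndarray:
    # log(cosh(x)) = |x| + log1p(exp(-2|x|)) - log 2, stable for large |x|
    a = np.abs(err)
    return a + np.log1p(np.exp(-2.0 * a)) - np.log(2.0)


class _Nadam:
    """Nesterov-momentum Adam with bias correction (library-default constants)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        learning_rate: float = 0.002,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.lr = learning_rate
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        for key, g in grads.items():
            m = self.m[key] = b1 * self.m[key] + (1 - b1) * g
            v = self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = b1 * m / (1 - b1 ** (t + 1)) + (1 - b1) * g / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# training and prediction


@dataclass
class TrainedModel:
    """A trained architecture bound to a concept order and embedding config."""

    config: ModelConfig
    model: _Architecture
    concept_ids: list[str]
    embedding_dim: int
    epoch_losses: list[float] = field(default_factory=list)
    concept_space_ref: str = ""

    def save(self, path: str | Path) -> None:
        """Serialize config + weights + concept order as JSON (round-trip exact)."""
        payload = {
            "config": asdict(self.config),
            "concept_ids": self.concept_ids,
            "embedding_dim": self.embedding_dim,
            "epoch_losses": self.epoch_losses,
            "concept_space_ref": self.concept_space_ref,
            "params": {k: v.tolist() for k, v in self.model.params.items()},
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        config = ModelConfig(**payload["config"])
        model = build_model(
            payload["embedding_dim"], len(payload["concept_ids"]), config
        )
        model.params = {
            k: np.asarray(v, dtype=np.float64)
            for k, v in payload["params"].items()
        }
        return cls(
            config=config,
            model=model,
            concept_ids=payload["concept_ids"],
            embedding_dim=payload["embedding_dim"],
            epoch_losses=payload["epoch_losses"],
            concept_space_ref=payload["concept_space_ref"],
        )


def train(
    examples: Sequence[TrainingExample],
    space: ConceptVectorSpace,
    table: EmbeddingTable,
    config: ModelConfig,
) -> TrainedModel:
    """Fit one architecture to (mention, concept-vector) regression targets.

    Minimizes the log-cosh loss between the model output and the target
    concept's vector with Nadam over ``config.epochs`` epochs of seeded
    minibatch shuffling.  Deterministic for a fixed seed under
    single-threaded execution.

    Raises
    ------
    ValidationError
        On an empty example list or a target concept missing from the space.
    RuntimeError
        If the loss becomes NaN.
    """
    if not examples:
        raise ValidationError("cannot train on an empty example list")
    missing = sorted(
        {e.target_concept for e in examples} - set(space.index)
    )
    if missing:
        raise ValidationError(
            f"target concepts not in the concept space: {', '.join(missing)}"
        )
    if config.loss != "log_cosh":
        raise ValueError(f"unsupported loss {config.loss!r}")
    if config.optimizer != "nadam":
        raise ValueError(f"unsupported optimizer {config.optimizer!r}")

    config = ModelConfig(**asdict(config))  # private copy
    if config.pad_length is None:
        config.pad_length = max(
            config.filter_size, max((len(e.tokens) for e in examples), default=1), 1
        )

    x, mask = batch_matrices([e.tokens for e in examples], table, config.pad_length)
    targets = space.vectors[[space.index[e.target_concept] for e in examples]]
    n_empty = int((~mask.any(axis=1)).sum())
    if n_empty:
        logger.warning("%d training examples have no in-vocabulary token", n_empty)

    model = build_model(table.dimension, space.n_concepts, config)
    optimizer = _Nadam(model.params, learning_rate=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = len(examples)
    losses: list[float] = []
    params = model.params
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            out, cache = model.forward(x[idx], mask[idx])
            err = out - targets[idx]
            loss = float(_log_cosh(err).mean())
            if np.isnan(loss):
                raise RuntimeError(
                    f"NaN loss at epoch {epoch + 1}; try lowering the learning rate"
                )
            epoch_loss += loss * len(idx)
            grad_out = np.tanh(err) / err.size
            grads = model.backward(cache, grad_out)
            optimizer.step(params, grads)
        if isinstance(model, CNormEnsemble):
            model.params = params  # push updates into the branch dicts
        losses.append(epoch_loss / n)
    return TrainedModel(
        config=config,
        model=model,
        concept_ids=list(space.concept_ids),
        embedding_dim=table.dimension,
        epoch_losses=losses,
    )


def predict_vectors(
    trained: TrainedModel,
    token_lists: Sequence[Sequence[str]],
    table: EmbeddingTable,
) -> np.ndarray:
    """Forward pass: one N-dimensional output vector per mention, in order."""
    if table.dimension != trained.embedding_dim:
        raise ValidationError(
            f"embedding dimension {table.dimension} does not match the "
            f"model's {trained.embedding_dim}"
        )
    if not token_lists:
        return np.zeros((0, len(trained.concept_ids)))
    pad = trained.config.pad_length or 1
    x, mask = batch_matrices(token_lists, table, pad)
    out, _ = trained.model.forward(x, mask)
    return out
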