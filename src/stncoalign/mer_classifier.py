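"""Depth classification of NRMS sequences: a threshold baseline and a small
attention-based sequence encoder trained with cross-entropy.

The encoder labels every depth of a trajectory jointly, attending to the
surrounding depths (bidirectional context, optionally limited to +-k
steps). All hyperparameter defaults are deliberately tiny so training runs
in seconds on one CPU; they are implementation choices, not published
values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .mer_signal import NrmsSequence

__all__ = [
    "ClassifierConfig",
    "DepthLabels",
    "SequenceClassifier",
    "classify_threshold",
    "train_sequence_classifier",
    "classify_sequence",
    "evaluate_classifier",
]

DEFAULT_TAU = 1.5  # threshold-baseline cutoff on NRMS


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters for both classifiers; the seed is always recorded."""

    context_k: int | None = None  # None = whole-track bidirectional context
    n_layers: int = 2
    n_heads: int = 4
    embed_dim: int = 32
    ffn_dim: int = 64
    tau: float = DEFAULT_TAU
    seed: int = 0
    epochs: int = 40
    learning_rate: float = 1e-3

    def __post_init__(self):
        if self.context_k is not None and self.context_k < 0:
            raise ValueError("context_k must be >= 0")
        if not self.tau > 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class DepthLabels:
    """Binary inside/outside-STN label per depth, optionally with probabilities."""

    trajectory_id: str
    depths: np.ndarray
    labels: np.ndarray  # {0, 1}
    probabilities: np.ndarray | None = None  # P(STN), in [0, 1]

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=np.float64)
        y = np.asarray(self.labels, dtype=np.int64)
        if d.shape != y.shape or d.ndim != 1:
            raise ValueError("depths and labels must be matching 1-D arrays")
        if not np.all(np.isin(y, (0, 1))):
            raise ValueError("labels must be binary")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "labels", y)
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=np.float64)
            if p.shape != y.shape:
                raise ValueError("probabilities shape mismatch")
            if np.any((p < 0) | (p > 1)):
                raise ValueError("probabilities must lie in [0, 1]")
            if not np.array_equal((p >= 0.5).astype(np.int64), y):
                raise ValueError("labels inconsistent with probabilities at 0.5")
            object.__setattr__(self, "probabilities", p)

    def __len__(self) -> int:
        return len(self.depths)


def classify_threshold(nrms: NrmsSequence, tau: float = DEFAULT_TAU) -> DepthLabels:
    """Label 1 wherever NRMS >= tau."""
    if not tau > 0:
        raise ValueError("tau must be positive")
    labels = (nrms.nrms >= tau).astype(np.int64)
    return DepthLabels(
        trajectory_id=nrms.trajectory_id, depths=nrms.depths, labels=labels
    )


@dataclass
class SequenceClassifier:
    """Trained attention encoder plus its config, seed and loss trace."""

    params: dict[str, np.ndarray]
    config: ClassifierConfig
    loss_trace: list[float] = field(default_factory=list)
    best_loss_trace: list[float] = field(default_factory=list)

    def predict(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-depth (labels, P(STN)) for a 1-D NRMS value array."""
        x = np.asarray(values, dtype=np.float64).reshape(-1, 1)
        if len(x) < 1:
            raise ValueError("sequence must contain at least one depth")
        logits, _ = _nn.forward(
            self.params, x, self.config.n_layers, self.config.n_heads,
            context_k=self.config.context_k,
        )
        z = logits - logits.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        probs = (ez / ez.sum(axis=-1, keepdims=True))[:, 1]
        return (probs >= 0.5).astype(np.int64), probs

    def save(self, path) -> None:
        """Checkpoint: npz of weights plus the embedded JSON config."""
        cfg = json.dumps(asdict(self.config))
        np.savez(
            Path(path),
            __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
            __loss_trace__=np.asarray(self.loss_trace),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "SequenceClassifier":
        with np.load(Path(path)) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            trace = [float(x) for x in data["__loss_trace__"]]
            params = {
                k: data[k] for k in data.files
                if k not in ("__config__", "__loss_trace__")
            }
        model = cls(params=params, config=ClassifierConfig(**cfg), loss_trace=trace)
        model.best_loss_trace = list(np.minimum.accumulate(trace)) if trace else []
        return model


def _corpus_arrays(dataset) -> list[tuple[np.ndarray, np.ndarray]]:
    """Accept (NrmsSequence, DepthLabels) pairs or raw (values, labels) pairs."""
    out = []
    for seq, lab in dataset:
        values = seq.nrms if isinstance(seq, NrmsSequence) else np.asarray(seq)
        labels = lab.labels if isinstance(lab, DepthLabels) else np.asarray(lab)
        if len(values) != len(labels):
            raise ValueError("sequence and labels differ in length")
        out.append((np.asarray(values, dtype=np.float64),
                    np.asarray(labels, dtype=np.int64)))
    return out


def train_sequence_classifier(
    dataset, config: ClassifierConfig | None = None
) -> SequenceClassifier:
    """Train the encoder with (unweighted) cross-entropy; deterministic per seed.

    Returns the parameters with the best epoch-mean training loss; the full
    per-epoch loss trace and its running best are kept on the model.
    """
    config = config or ClassifierConfig()
    corpus = _corpus_arrays(dataset)
    if not corpus:
        raise ValueError("empty training dataset")
    all_labels = np.concatenate([lab for _, lab in corpus])
    if len(np.unique(all_labels)) < 2:
        raise ValueError("training dataset contains a single class")

    rng = np.random.default_rng(config.seed)
    params = _nn.init_params(
        config.embed_dim, config.n_layers, config.n_heads, config.ffn_dim,
        n_features=1, n_classes=2, rng=rng,
    )
    opt = _nn.Adam(params, lr=config.learning_rate)
    trace: list[float] = []
    best_loss = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    order = np.arange(len(corpus))
    for _ in range(config.epochs):
        rng.shuffle(order)
        epoch_loss = 0.0
        for idx in order:
            values, labels = corpus[idx]
            x = values.reshape(-1, 1)
            logits, cache = _nn.forward(
                params, x, config.n_layers, config.n_heads,
                context_k=config.context_k,
            )
            loss, dlogits, _ = _nn.softmax_cross_entropy(logits, labels)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf training loss at step {opt.t}; "
                    f"lr={config.learning_rate}, seed={config.seed}"
                )
            grads = _nn.backward(params, cache, dlogits,
                                 config.n_layers, config.n_heads)
            opt.step(params, grads)
            epoch_loss += loss
        epoch_loss /= len(corpus)
        trace.append(epoch_loss)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_params = {k: v.copy() for k, v in params.items()}
    model = SequenceClassifier(params=best_params, config=config, loss_trace=trace)
    model.best_loss_trace = list(np.minimum.accumulate(trace))
    return model


def classify_sequence(model: SequenceClassifier, nrms: NrmsSequence) -> DepthLabels:
    """Label every depth of one NRMS sequence with the trained encoder."""
    labels, probs = model.predict(nrms.nrms)
    return DepthLabels(
        trajectory_id=nrms.trajectory_id,
        depths=nrms.depths,
        labels=labels,
        probabilities=probs,
    )


def evaluate_classifier(predicted, truth) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) over aligned label collections.

    Accepts lists of :class:`DepthLabels` or of plain label arrays.
    Sensitivity is the detected fraction of true STN depths; specificity the
    analogue for non-STN. Either is NaN when its class is absent.
    """
    def flatten(collection):
        parts = []
        for item in collection:
            parts.append(item.labels if isinstance(item, DepthLabels)
                         else np.asarray(item))
        return np.concatenate([np.atleast_1d(p) for p in parts])

    p = flatten(predicted)
    t = flatten(truth)
    if p.shape != t.shape:
        raise ValueError(f"prediction/truth length mismatch: {p.shape} vs {t.shape}")
    accuracy = float((p == t).mean())
    pos = t == 1
    neg = t == 0
    sensitivity = float((p[pos] == 1).mean()) if pos.any() else float("nan")
    specificity = float((p[neg] == 0).mean()) if neg.any() else float("nan")
    return accuracy, sensitivity, specificity
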