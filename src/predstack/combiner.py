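"""The combined stacking model and the two naive ensemble baselines.

A fully-connected network maps the concatenated 20-way outputs of four
base predictors (an 80-vector) through relu layers of 120 and 60 units to
a 20-way softmax. Training uses categorical cross-entropy with Adam at a
fixed learning rate, a fixed epoch count, and per-epoch shuffling — all
deterministic for a given seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from predstack.alphabet import AA_TO_INDEX, CANONICAL_AA, N_AA
from predstack.errors import (
    CorruptModelError,
    InputError,
    TrainingDivergenceError,
)
from predstack.formats_io import PredictionSet, SiteRecord

logger = logging.getLogger(__name__)

LAYER_SIZES = (4 * N_AA, 120, 60, N_AA)  # 80 -> 120 -> 60 -> 20


@dataclass
class CombinerParams:
    """Weights and biases of the stacking network plus input-order metadata.

    model_order fixes how the four base-model vectors are concatenated:
    components 20k..20k+19 of the input belong to model_order[k].
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    model_order: tuple[str, str, str, str]
    alphabet: str = CANONICAL_AA

    def __post_init__(self) -> None:
        expected = {
            "W1": (LAYER_SIZES[0], LAYER_SIZES[1]), "b1": (LAYER_SIZES[1],),
            "W2": (LAYER_SIZES[1], LAYER_SIZES[2]), "b2": (LAYER_SIZES[2],),
            "W3": (LAYER_SIZES[2], LAYER_SIZES[3]), "b3": (LAYER_SIZES[3],),
        }
        for name, shape in expected.items():
            actual = getattr(self, name).shape
            if actual != shape:
                raise CorruptModelError(f"{name} has shape {actual}, expected {shape}")
        if len(self.model_order) != 4:
            raise CorruptModelError("model_order must list exactly 4 model ids")
        if self.alphabet != CANONICAL_AA:
            raise CorruptModelError("alphabet mismatch")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 150
    batch_size: int = 128
    seed: int = 0
    # Adam moment constants; the loss is fixed to categorical cross-entropy.
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise InputError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise InputError("epochs and batch_size must be >= 1")


def concat_inputs(
    site_vectors: Mapping[str, np.ndarray],
    model_order: Sequence[str],
) -> np.ndarray:
    """Concatenate four 20-vectors into the 80-way network input."""
    if set(site_vectors) != set(model_order) or len(site_vectors) != len(model_order):
        missing = set(model_order) - set(site_vectors)
        extra = set(site_vectors) - set(model_order)
        parts = []
        if missing:
            parts.append(f"missing {sorted(missing)}")
        if extra:
            parts.append(f"unexpected {sorted(extra)}")
        raise InputError("model id mismatch: " + "; ".join(parts))
    return np.concatenate([np.asarray(site_vectors[m], dtype=float) for m in model_order])


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(params: CombinerParams, x: np.ndarray) -> np.ndarray:
    """softmax(W3·relu(W2·relu(W1·x + b1) + b2) + b3); accepts (80,) or (n, 80)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != LAYER_SIZES[0]:
        raise InputError(f"input must have {LAYER_SIZES[0]} components, got {x.shape}")
    h1 = np.maximum(x @ params.W1 + params.b1, 0.0)
    h2 = np.maximum(h1 @ params.W2 + params.b2, 0.0)
    return _softmax(h2 @ params.W3 + params.b3)


def init_params(model_order: Sequence[str], seed: int = 0) -> CombinerParams:
    """He-style uniform initialization, deterministic in the seed."""
    rng = np.random.default_rng(seed)
    weights = []
    for fan_in, fan_out in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:]):
        limit = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
    return CombinerParams(
        W1=weights[0], b1=np.zeros(LAYER_SIZES[1]),
        W2=weights[1], b2=np.zeros(LAYER_SIZES[2]),
        W3=weights[2], b3=np.zeros(LAYER_SIZES[3]),
        model_order=tuple(model_order),
    )


def loss_and_grads(
    params: CombinerParams, X: np.ndarray, Y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean categorical cross-entropy and its gradients over a batch.

    Y is one-hot, shape (n, 20).
    """
    n = X.shape[0]
    z1 = X @ params.W1 + params.b1
    h1 = np.maximum(z1, 0.0)
    z2 = h1 @ params.W2 + params.b2
    h2 = np.maximum(z2, 0.0)
    p = _softmax(h2 @ params.W3 + params.b3)
    loss = float(-np.sum(Y * np.log(np.clip(p, 1e-300, None))) / n)

    dz3 = (p - Y) / n
    grads = {"W3": h2.T @ dz3, "b3": dz3.sum(axis=0)}
    dh2 = dz3 @ params.W3.T
    dz2 = dh2 * (z2 > 0)
    grads["W2"] = h1.T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    dh1 = dz2 @ params.W2.T
    dz1 = dh1 * (z1 > 0)
    grads["W1"] = X.T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    return loss, grads


def build_design_matrix(
    pset: PredictionSet,
    labels: Sequence[SiteRecord],
    model_order: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, list[SiteRecord]]:
    """Stack per-site 80-vectors and one-hot targets; drops non-canonical sites."""
    used: list[SiteRecord] = []
    rows, targets = [], []
    n_dropped = 0
    for site in labels:
        if site.wt_aa not in AA_TO_INDEX:
            n_dropped += 1
            continue
        try:
            x = np.concatenate([
                pset.entries[(site.protein_id, site.position, m)] for m in model_order
            ])
        except KeyError as exc:
            raise InputError(f"incomplete predictions for site "
                             f"({site.protein_id}, {site.position}): {exc}") from None
        rows.append(x)
        y = np.zeros(N_AA)
        y[AA_TO_INDEX[site.wt_aa]] = 1.0
        targets.append(y)
        used.append(site)
    if n_dropped:
        logger.info("excluded %d site(s) with non-canonical wildtype", n_dropped)
    if not rows:
        raise InputError("no usable training sites")
    return np.asarray(rows), np.asarray(targets), used


def train_combiner(
    pset: PredictionSet,
    labels: Sequence[SiteRecord],
    cfg: TrainConfig | None = None,
) -> tuple[CombinerParams, list[float]]:
    """Train the stacking network; returns final parameters and per-epoch loss.

    model_order is the sorted list of the four base model ids, frozen into
    the returned parameters. One training example per site, target one-hot
    at the wildtype amino acid; examples are shuffled globally each epoch.
    """
    cfg = cfg or TrainConfig()
    if len(pset.model_ids) != 4:
        raise InputError(f"combiner needs exactly 4 base models, got {pset.model_ids}")
    model_order = tuple(sorted(pset.model_ids))
    X, Y, _ = build_design_matrix(pset, labels, model_order)

    params = init_params(model_order, seed=cfg.seed)
    # shuffle stream kept separate from the init stream
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed % 2**32, 1]))
    moments = {k: (np.zeros_like(getattr(params, k)), np.zeros_like(getattr(params, k)))
               for k in ("W1", "b1", "W2", "b2", "W3", "b3")}
    t = 0
    n = X.shape[0]
    loss_trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = loss_and_grads(params, X[idx], Y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch + 1)
            epoch_loss += loss * len(idx)
            t += 1
            for name, g in grads.items():
                m, v = moments[name]
                m *= cfg.beta1
                m += (1 - cfg.beta1) * g
                v *= cfg.beta2
                v += (1 - cfg.beta2) * g * g
                m_hat = m / (1 - cfg.beta1 ** t)
                v_hat = v / (1 - cfg.beta2 ** t)
                getattr(params, name)[...] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.eps)
        loss_trace.append(epoch_loss / n)
    return params, loss_trace


def predict_combined(
    params: CombinerParams,
    pset: PredictionSet,
    model_id: str = "combined",
) -> PredictionSet:
    """Run the stack over every complete site of pset."""
    out = PredictionSet(model_ids=[model_id])
    for pid, pos in pset.sites():
        try:
            x = np.concatenate([
                pset.entries[(pid, pos, m)] for m in params.model_order
            ])
        except KeyError:
            raise InputError(f"incomplete predictions for site ({pid}, {pos})") from None
        out.entries[(pid, pos, model_id)] = forward(params, x)
    return out


def ensemble_average(site_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Componentwise mean of four probability vectors."""
    if len(site_vectors) != 4:
        raise InputError(f"expected 4 vectors, got {len(site_vectors)}")
    return np.mean([np.asarray(v, dtype=float) for v in site_vectors], axis=0)


def ensemble_max(
    site_vectors: Mapping[str, np.ndarray],
    model_order: Sequence[str],
) -> tuple[str, float]:
    """Amino acid with the globally highest probability across four models.

    Ties break by alphabet order first, then by position in model_order.
    """
    if len(site_vectors) != 4 or set(site_vectors) != set(model_order):
        raise InputError("expected vectors for exactly the 4 models in model_order")
    best: tuple[int, int, float] | None = None  # (aa_idx, model_rank, prob)
    for rank, mid in enumerate(model_order):
        v = np.asarray(site_vectors[mid], dtype=float)
        for aa_idx in range(N_AA):
            prob = float(v[aa_idx])
            if best is None or prob > best[2] or (
                prob == best[2] and (aa_idx, rank) < (best[0], best[1])
            ):
                best = (aa_idx, rank, prob)
    assert best is not None
    return CANONICAL_AA[best[0]], best[2]


def predict_average(pset: PredictionSet, model_id: str = "avg_ensemble") -> PredictionSet:
    """Probability-averaging baseline as a PredictionSet."""
    if len(pset.model_ids) != 4:
        raise InputError("averaging baseline needs exactly 4 base models")
    out = PredictionSet(model_ids=[model_id])
    for pid, pos in pset.sites():
        vectors = [pset.entries[(pid, pos, m)] for m in pset.model_ids]
        out.entries[(pid, pos, model_id)] = ensemble_average(vectors)
    return out


def predict_max(pset: PredictionSet, model_id: str = "max_ensemble") -> PredictionSet:
    """Max-probability-vote baseline as a PredictionSet.

    The winning amino acid carries its winning probability; the remainder
    is spread uniformly so the vector stays a distribution.
    """
    if len(pset.model_ids) != 4:
        raise InputError("max baseline needs exactly 4 base models")
    order = list(pset.model_ids)
    out = PredictionSet(model_ids=[model_id])
    for pid, pos in pset.sites():
        vectors = {m: pset.entries[(pid, pos, m)] for m in order}
        aa, conf = ensemble_max(vectors, order)
        v = np.full(N_AA, (1.0 - conf) / (N_AA - 1))
        v[AA_TO_INDEX[aa]] = conf
        out.entries[(pid, pos, model_id)] = v
    return out


def save_combiner(params: CombinerParams, path: str | Path) -> None:
    """Serialize parameters to an .npz archive with a JSON metadata record."""
    meta = json.dumps({
        "model_order": list(params.model_order),
        "alphabet": params.alphabet,
        "layer_sizes": list(LAYER_SIZES),
    })
    np.savez(
        path,
        W1=params.W1, b1=params.b1, W2=params.W2, b2=params.b2,
        W3=params.W3, b3=params.b3, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
    )


def load_combiner(path: str | Path) -> CombinerParams:
    try:
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["meta"]).decode())
            arrays = {k: archive[k] for k in ("W1", "b1", "W2", "b2", "W3", "b3")}
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise CorruptModelError(f"cannot load combiner from {path}: {exc}") from exc
    if meta.get("layer_sizes") != list(LAYER_SIZES):
        raise CorruptModelError(f"layer sizes {meta.get('layer_sizes')} do not match {LAYER_SIZES}")
    return CombinerParams(
        **arrays,
        model_order=tuple(meta["model_order"]),
        alphabet=meta.get("alphabet", CANONICAL_AA),
    )
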