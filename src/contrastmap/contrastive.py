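"""Contrastive training of a spatially informed expression encoder.

The model follows the encoder/projector pattern: an MLP encoder (dense ->
batchnorm -> leaky ReLU per layer) produces the representation kept for
inference, and an MLP projection head (ReLU after its first layer only)
feeds the infoNCE loss during training and is discarded afterwards.

Training batches are built from the reference's spatial k-nearest-neighbor
graph: half the batch are anchors, each paired with one positive drawn
uniformly from its k spatial neighbors; the remaining in-batch cells act as
negatives. With temperature tau, the per-sample loss is

    L_q = -log( exp(q.k+ / tau) / sum_i exp(q.k_i / tau) )

where the denominator runs over the other in-batch projections — including
the positive in the default ``with_positive`` mode, or the N-2 negatives
only in ``negatives_only`` mode. Projections are L2-normalized so dot
products are cosine similarities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from . import _mlp
from .data_io import ExpressionProfile, SpatialDataset, ValidationError

logger = logging.getLogger(__name__)

DENOMINATOR_MODES = ("with_positive", "negatives_only")

#: spatial-kNN positive-pool size per reference platform; the coarser the
#: platform resolution, the fewer neighbors count as "proximate"
DEFAULT_POSITIVE_KNN = {"single_cell": 80, "spot": 20}


@dataclass
class ModelConfig:
    """Hyperparameters of the encoder/projector and its training loop."""

    encoder_dims: List[int] = field(default_factory=lambda: [1024, 512])
    projector_dims: List[int] = field(default_factory=lambda: [256, 128])
    temperature: float = 0.05
    batch_size: int = 64
    positive_knn: int = 80
    lr0: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 5e-4
    epochs: int = 3000
    seed: int = 0
    denominator_mode: str = "with_positive"

    def __post_init__(self):
        if self.batch_size < 4 or self.batch_size % 2:
            raise ValidationError("batch_size must be even and >= 4")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if any(d <= 0 for d in self.encoder_dims + self.projector_dims):
            raise ValidationError("all layer dims must be positive")
        if self.denominator_mode not in DENOMINATOR_MODES:
            raise ValidationError(
                f"denominator_mode must be one of {DENOMINATOR_MODES}"
            )

    @classmethod
    def for_platform(cls, platform: str, **kwargs) -> "ModelConfig":
        kwargs.setdefault("positive_knn", DEFAULT_POSITIVE_KNN[platform])
        return cls(**kwargs)


@dataclass
class SpatialKnnGraph:
    """Row i lists the k spatially nearest cells to i (self excluded),
    sorted by ascending Euclidean distance, ties broken by lower index."""

    neighbor_idx: np.ndarray
    k: int


@dataclass
class ContrastiveBatch:
    """Anchor/positive index pairs; cell j's partner is row N/2 + j.

    The batch contains the 2*len(anchor_idx) listed cells; every cell is a
    sample whose pair partner is the positive and whose other in-batch
    cells are negatives.
    """

    anchor_idx: np.ndarray
    positive_idx: np.ndarray

    @property
    def indices(self) -> np.ndarray:
        return np.concatenate([self.anchor_idx, self.positive_idx])


def build_spatial_knn(coords: np.ndarray, k: int) -> SpatialKnnGraph:
    """Euclidean k-nearest-neighbor graph over reference coordinates."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than n_cells={n}")
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    # stable argsort on distances -> ties resolved toward the lower index
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    return SpatialKnnGraph(neighbor_idx=order, k=k)


def sample_batch(graph: SpatialKnnGraph, anchors: Sequence[int],
                 rng: np.random.Generator) -> ContrastiveBatch:
    """Draw one positive per anchor, uniformly from its spatial neighbors."""
    anchors = np.asarray(anchors, int)
    if len(np.unique(anchors)) != len(anchors):
        raise ValidationError("anchors must be distinct")
    if len(anchors) > graph.neighbor_idx.shape[0]:
        raise ValidationError("more anchors than cells in the graph")
    choice = rng.integers(0, graph.k, size=len(anchors))
    positives = graph.neighbor_idx[anchors, choice]
    return ContrastiveBatch(anchor_idx=anchors, positive_idx=positives)


# ---------------------------------------------------------------------------
# infoNCE
# ---------------------------------------------------------------------------

def _l2_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValidationError("zero projection vector in batch")
    return X / norms


def _nce_loss_grad(Z: np.ndarray, tau: float, mode: str):
    """Mean infoNCE loss over all N samples and its gradient wrt Z.

    Z must be row-normalized; the gradient returned is wrt the normalized
    projections (chain through the normalization separately).
    """
    N = Z.shape[0]
    half = N // 2
    partner = np.concatenate([np.arange(half, N), np.arange(half)])
    sim = Z @ Z.T / tau
    pos_logit = sim[np.arange(N), partner]
    neg_inf = -np.inf
    logits = sim.copy()
    logits[np.arange(N), np.arange(N)] = neg_inf
    if mode == "negatives_only":
        denom = logits.copy()
        denom[np.arange(N), partner] = neg_inf
    else:
        denom = logits
    lse = logsumexp(denom, axis=1)
    loss = float(np.mean(lse - pos_logit))
    # softmax over the denominator set, minus the one-hot positive
    G = np.exp(denom - lse[:, None])
    G[~np.isfinite(denom)] = 0.0
    G[np.arange(N), partner] -= 1.0
    G /= N
    dZ = (G + G.T) @ Z / tau
    return loss, dZ


def info_nce_loss(projections: np.ndarray, batch: ContrastiveBatch,
                  tau: float, denominator_mode: str = "with_positive") -> float:
    """Batch-mean infoNCE loss of raw (unnormalized) projections.

    ``projections`` rows are ordered as ``batch.indices``: the anchors
    first, then their positives. Rows are L2-normalized internally.
    """
    if tau <= 0:
        raise ValidationError("temperature must be positive")
    if denominator_mode not in DENOMINATOR_MODES:
        raise ValidationError(f"unknown denominator_mode {denominator_mode!r}")
    projections = np.asarray(projections, float)
    if not np.isfinite(projections).all():
        raise ValidationError("projections contain NaN/inf")
    if projections.shape[0] != len(batch.indices):
        raise ValidationError("projection rows do not match batch size")
    Z = _l2_rows(projections)
    loss, _ = _nce_loss_grad(Z, tau, denominator_mode)
    return loss


def info_nce_loss_single(q, positive, negatives, tau: float,
                         denominator_mode: str = "with_positive") -> float:
    """Loss of one sample against an explicit negative list (reference form).

    Handy as a transparent oracle: the batch loss equals the mean of this
    over every in-batch sample with its implied negatives.
    """
    q = np.asarray(q, float)
    q = q / np.linalg.norm(q)
    pos = np.asarray(positive, float)
    pos = pos / np.linalg.norm(pos)
    negs = [np.asarray(v, float) / np.linalg.norm(v) for v in negatives]
    pos_logit = q @ pos / tau
    logits = [q @ v / tau for v in negs]
    if denominator_mode == "with_positive":
        logits.append(pos_logit)
    return float(logsumexp(logits) - pos_logit)


# ---------------------------------------------------------------------------
# encoder state & training
# ---------------------------------------------------------------------------

@dataclass
class EncoderState:
    """A trained (or freshly initialized) encoder with its gene space."""

    network: _mlp.Sequential
    input_gene_ids: np.ndarray
    config: ModelConfig
    loss_history: List[float] = field(default_factory=list)

    @property
    def output_dim(self) -> int:
        for layer in reversed(self.network.layers):
            if isinstance(layer, _mlp.Linear):
                return layer.W.shape[1]
        raise ValueError("encoder has no linear layer")

    def save(self, path) -> None:
        arrays, meta = {}, []
        for i, layer in enumerate(self.network.layers):
            if isinstance(layer, _mlp.Linear):
                meta.append({"kind": "linear"})
                arrays[f"l{i}_W"] = layer.W
                arrays[f"l{i}_b"] = layer.b
            elif isinstance(layer, _mlp.BatchNorm):
                meta.append({"kind": "batchnorm"})
                for name in ("gamma", "beta", "running_mean", "running_var"):
                    arrays[f"l{i}_{name}"] = getattr(layer, name)
            elif isinstance(layer, _mlp.ReLU):
                meta.append({"kind": "relu"})
            elif isinstance(layer, _mlp.LeakyReLU):
                meta.append({"kind": "leaky_relu", "slope": layer.slope})
        header = {
            "layers": meta,
            "gene_ids": [str(g) for g in self.input_gene_ids],
            "config": asdict(self.config),
            "loss_history": self.loss_history,
        }
        arrays["header"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "EncoderState":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            layers = []
            for i, meta in enumerate(header["layers"]):
                if meta["kind"] == "linear":
                    W = data[f"l{i}_W"]
                    layer = _mlp.Linear(W.shape[0], W.shape[1], np.random.default_rng(0))
                    layer.W, layer.b = W, data[f"l{i}_b"]
                elif meta["kind"] == "batchnorm":
                    layer = _mlp.BatchNorm(len(data[f"l{i}_gamma"]))
                    for name in ("gamma", "beta", "running_mean", "running_var"):
                        setattr(layer, name, data[f"l{i}_{name}"])
                elif meta["kind"] == "relu":
                    layer = _mlp.ReLU()
                else:
                    layer = _mlp.LeakyReLU(meta["slope"])
                layers.append(layer)
        config = ModelConfig(**header["config"])
        state = cls(
            network=_mlp.Sequential(layers),
            input_gene_ids=np.asarray(header["gene_ids"], dtype=object),
            config=config,
        )
        state.loss_history = list(header["loss_history"])
        return state


def _resolve_encoder_dims(config: ModelConfig, n_genes: int) -> List[int]:
    """Shrink the first encoder layer for narrow gene panels.

    The default 1024-wide first layer is sized for transcriptome-scale
    input; for panels under 1024 genes the width is capped at 4x the panel
    size to keep the parameter count proportionate.
    """
    dims = list(config.encoder_dims)
    if n_genes < 1024 and dims and dims[0] > 4 * n_genes:
        dims[0] = min(dims[0], 4 * n_genes)
        logger.info(
            "encoder first layer shrunk to %d for %d input genes", dims[0], n_genes
        )
    return dims


def _build_networks(config: ModelConfig, n_genes: int, rng: np.random.Generator):
    enc_layers = []
    d_in = n_genes
    for d_out in _resolve_encoder_dims(config, n_genes):
        enc_layers += [
            _mlp.Linear(d_in, d_out, rng),
            _mlp.BatchNorm(d_out),
            _mlp.LeakyReLU(),
        ]
        d_in = d_out
    encoder = _mlp.Sequential(enc_layers)
    proj_layers = []
    for j, d_out in enumerate(config.projector_dims):
        proj_layers.append(_mlp.Linear(d_in, d_out, rng))
        if j == 0:
            proj_layers.append(_mlp.ReLU())
        d_in = d_out
    projector = _mlp.Sequential(proj_layers)
    return encoder, projector


def train(reference: SpatialDataset, config: ModelConfig,
          progress_log: Optional[list] = None) -> EncoderState:
    """Train the encoder on a log-normalized spatial reference.

    Each epoch partitions the cells into anchor groups of batch_size/2
    without replacement (so every cell anchors once per epoch), draws one
    spatial-kNN positive per anchor, and takes one SGD step per batch under
    a cosine-decayed learning rate. Returns the encoder only; per-epoch
    mean losses are appended to ``progress_log`` and kept on the state.
    """
    profile = reference.profile
    if not profile.is_lognorm:
        raise ValidationError("reference must be log-normalized before training")
    n = profile.n_cells
    if n <= config.batch_size:
        raise ValidationError(
            f"need more cells ({n}) than batch_size ({config.batch_size})"
        )
    rng = np.random.default_rng(config.seed)
    graph = build_spatial_knn(reference.coords, config.positive_knn)
    encoder, projector = _build_networks(config, profile.n_genes, rng)
    opt = _mlp.SGD([encoder, projector], momentum=config.momentum,
                   weight_decay=config.weight_decay)
    X = profile.values
    half = config.batch_size // 2
    state = EncoderState(
        network=encoder,
        input_gene_ids=profile.gene_ids.copy(),
        config=config,
    )
    for epoch in range(config.epochs):
        lr = _mlp.cosine_lr(config.lr0, epoch, config.epochs)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, half):
            anchors = order[start:start + half]
            if len(anchors) < 2:
                continue  # a 1-anchor batch has no negatives
            batch = sample_batch(graph, anchors, rng)
            x = X[batch.indices]
            h = encoder.forward(x, train=True)
            p = projector.forward(h, train=True)
            norms = np.linalg.norm(p, axis=1, keepdims=True)
            if (norms == 0).any():
                raise ArithmeticError("zero projection norm during training")
            Z = p / norms
            loss, dZ = _nce_loss_grad(Z, config.temperature, config.denominator_mode)
            if not np.isfinite(loss):
                raise ArithmeticError(
                    f"non-finite loss at epoch {epoch}; training aborted"
                )
            # back through row L2 normalization
            dp = (dZ - Z * (dZ * Z).sum(axis=1, keepdims=True)) / norms
            dh = projector.backward(dp)
            encoder.backward(dh)
            opt.step(lr)
            epoch_losses.append(loss)
        mean_loss = float(np.mean(epoch_losses)) if epoch_losses else np.nan
        state.loss_history.append(mean_loss)
        if progress_log is not None:
            progress_log.append(mean_loss)
        if epoch % 100 == 0 or epoch == config.epochs - 1:
            logger.info("epoch %d: lr=%.4f loss=%.4f", epoch, lr, mean_loss)
    return state


def encode(state: EncoderState, profile: ExpressionProfile) -> np.ndarray:
    """Deterministic inference-mode forward pass through the encoder."""
    if not profile.is_lognorm:
        raise ValidationError("profile must be log-normalized before encoding")
    if (len(profile.gene_ids) != len(state.input_gene_ids)
            or (profile.gene_ids != state.input_gene_ids).any()):
        missing = sorted(set(state.input_gene_ids) - set(profile.gene_ids))
        raise ValidationError(
            "profile genes do not match the encoder's input genes "
            f"(missing or misordered; missing: {missing[:10]})"
        )
    reps = state.network.forward(profile.values, train=False)
    if not np.isfinite(reps).all():
        raise ArithmeticError("non-finite encoder output")
    return reps
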