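"""Gated late fusion of per-view embeddings, alternatives, and aggregator
pre-training.

The main aggregator combines the per-view embeddings z_m with softmax gate
weights computed from a batch:

    w_m   = (1/B) * sum_i  q . tanh(W z_im / ||z_im||_2 + b)
    alpha = softmax(w)
    z_mv  = MLP( sum_m alpha_m z_im )

The alpha weights are the interpretability surface: they report how much
each view contributes.  Because each embedding is L2-normalized inside the
gate, alpha is invariant to per-sample embedding scale, and the batch mean
makes it invariant to batch ordering.

Three alternative late-fusion schemes are provided for comparison
(:func:`alt_fuse`): projected gating and unprojected gating, both emitting
a weighted concatenation of the view outputs, and projected gating with
feature addition, emitting a weighted sum.

The aggregator can be pre-trained with an embedding-reconstruction task
(:func:`pretrain_aggregator`): per-view linear heads must reconstruct each
input embedding from the fused embedding under squared error.  After the
pre-training reported in the reference setting at full scale, the gate
weights ordered image > graph > text; those reference values are recorded
in :data:`ALPHA_PRETRAIN_REFERENCE` and are not a target of this package's
desk-scale training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from mvmol import nn
from mvmol.nn import Tensor

#: Reference gate weights (image, graph, text) observed after full-scale
#: aggregator reconstruction pre-training; recorded for comparison only.
ALPHA_PRETRAIN_REFERENCE = {"image": 0.6, "graph": 0.3, "text": 0.1}


class ZeroNormEmbeddingError(ValueError):
    """Raised when an embedding has zero L2 norm (normalization undefined)."""


@dataclass
class FusionOutput:
    """Fused embedding with the per-view gate diagnostics.

    ``alpha`` sums to one over the view set; ``w`` holds the pre-softmax
    batch-mean gate scores; ``z_mv`` is (B, output_dim).
    """

    z_mv: np.ndarray
    alpha: np.ndarray
    w: np.ndarray
    views: tuple[str, ...]
    batch_size: int

    def alpha_by_view(self) -> dict[str, float]:
        return {v: float(a) for v, a in zip(self.views, self.alpha)}


class GatingParams(nn.Module):
    """Parameters of the gated aggregator: gate (q, W, b) plus the MLP head.

    The MLP applied to the alpha-weighted sum has two layers with hidden
    width equal to the embedding width.
    """

    def __init__(self, dim: int, output_dim: int | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        output_dim = dim if output_dim is None else output_dim
        self.dim = dim
        self.output_dim = output_dim
        self.q = Tensor(rng.normal(0.0, 1.0 / np.sqrt(dim), size=dim), requires_grad=True)
        self.W = Tensor(rng.normal(0.0, 1.0 / np.sqrt(dim), size=(dim, dim)), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)
        self.mlp1 = nn.Linear(dim, dim, rng)
        self.mlp2 = nn.Linear(dim, output_dim, rng)
        #: Batch-mean gate scores frozen at the end of training; used for
        #: deterministic single-molecule inference.
        self.frozen_w: np.ndarray | None = None

    def gate_scores(self, z: Tensor) -> Tensor:
        """Per-sample gate scores q . tanh(W z/||z|| + b) for z of (B, D)."""
        norms = np.linalg.norm(z.data, axis=-1, keepdims=True)
        if np.any(norms < 1e-12):
            raise ZeroNormEmbeddingError("zero-norm embedding in gate input")
        z_unit = z / Tensor(norms)
        # row-vector form of q . tanh(W z/||z|| + b)
        return ((z_unit @ self.W.transpose(1, 0)) + self.b).tanh() @ self.q


def _fuse_tensors(
    embeddings: Sequence[Tensor],
    params: GatingParams,
    frozen_w: np.ndarray | None = None,
) -> tuple[Tensor, Tensor, Tensor]:
    """Differentiable fusion: returns (z_mv, alpha, w) as tensors.

    When ``frozen_w`` is given the gate scores are fixed constants (frozen-
    gate inference); otherwise they are batch means of the gate operation.
    """
    if frozen_w is not None:
        w = Tensor(np.asarray(frozen_w, dtype=np.float64))
    else:
        w = nn.stack([params.gate_scores(z).mean() for z in embeddings])
    alpha = nn.softmax(w, axis=0)
    mix = None
    for m, z in enumerate(embeddings):
        term = z * alpha[m]
        mix = term if mix is None else mix + term
    z_mv = params.mlp2(params.mlp1(mix).tanh())
    return z_mv, alpha, w


def gated_fusion(
    embeddings: dict[str, np.ndarray] | Sequence[np.ndarray],
    params: GatingParams,
    frozen: bool = False,
) -> FusionOutput:
    """Fuse per-view embedding batches with the gated aggregator.

    ``embeddings`` maps view name -> (B, D) array (or is an ordered
    sequence of such arrays).  With ``frozen=True`` the stored end-of-
    training gate scores are used instead of the batch statistic, making
    single-molecule inference deterministic and independent of batch
    composition.
    """
    if isinstance(embeddings, dict):
        views = tuple(embeddings)
        arrays = [np.atleast_2d(np.asarray(embeddings[v], dtype=np.float64)) for v in views]
    else:
        arrays = [np.atleast_2d(np.asarray(z, dtype=np.float64)) for z in embeddings]
        views = tuple(f"view{i}" for i in range(len(arrays)))
    if not arrays or arrays[0].shape[0] == 0:
        raise ValueError("batch must be non-empty")
    sizes = {a.shape for a in arrays}
    if len({a.shape[0] for a in arrays}) != 1 or len({a.shape[1] for a in arrays}) != 1:
        raise ValueError(f"view embedding shapes differ: {sizes}")
    frozen_w = None
    if frozen:
        if params.frozen_w is None:
            raise ValueError("no frozen gate scores recorded on params")
        frozen_w = params.frozen_w
    z_mv, alpha, w = _fuse_tensors([Tensor(a) for a in arrays], params, frozen_w)
    return FusionOutput(
        z_mv=z_mv.data,
        alpha=alpha.data,
        w=w.data,
        views=views,
        batch_size=arrays[0].shape[0],
    )


# ---------------------------------------------------------------------------
# Alternative late-fusion schemes
# ---------------------------------------------------------------------------

AltScheme = Literal[
    "projected_gating", "unprojected_gating", "projected_gating_feature_addition"
]


@dataclass(frozen=True)
class AltFusionConfig:
    """Configuration of an alternative late-fusion scheme.

    The gate-network input width D follows from the scheme: projected
    gating concatenates three projections to min(d_i), so
    D = min(d1, d2, d3) * 3; unprojected gating concatenates the raw
    outputs, D = d1 + d2 + d3.
    """

    scheme: AltScheme
    dims: tuple[int, int, int]
    seed: int = 0

    @property
    def gate_input_dim(self) -> int:
        if self.scheme == "unprojected_gating":
            return int(sum(self.dims))
        return int(min(self.dims) * 3)


class AltFusionParams(nn.Module):
    def __init__(self, config: AltFusionConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        d_proj = min(config.dims)
        self.projections = [nn.Linear(d, d_proj, rng) for d in config.dims]
        self.gate = nn.Linear(config.gate_input_dim, 3, rng)


def alt_fuse(
    embeddings: Sequence[np.ndarray],
    config: AltFusionConfig,
    params: AltFusionParams | None = None,
) -> FusionOutput:
    """Fuse a batch of three view embeddings with an alternative scheme.

    Schemes ``projected_gating`` and ``unprojected_gating`` emit the
    weighted concatenation w1*z1 (+) w2*z2 (+) w3*z3 of the raw view
    outputs; ``projected_gating_feature_addition`` emits the weighted sum
    of the projected outputs and reports batch-average weights.
    """
    arrays = [np.atleast_2d(np.asarray(z, dtype=np.float64)) for z in embeddings]
    if len(arrays) != 3:
        raise ValueError("alternative schemes fuse exactly three views")
    if tuple(a.shape[1] for a in arrays) != tuple(config.dims):
        raise ValueError(
            f"embedding dims {tuple(a.shape[1] for a in arrays)} do not match config {config.dims}"
        )
    if params is None:
        params = AltFusionParams(config)
    tensors = [Tensor(a) for a in arrays]
    projected = [p(t).tanh() for p, t in zip(params.projections, tensors)]
    if config.scheme == "unprojected_gating":
        gate_in = nn.concatenate(tensors, axis=-1)
    else:
        gate_in = nn.concatenate(projected, axis=-1)
    weights = nn.softmax(params.gate(gate_in), axis=-1)  # (B, 3) per-sample

    if config.scheme == "projected_gating_feature_addition":
        parts = [projected[i] * weights[:, i].reshape(-1, 1) for i in range(3)]
        z_final = parts[0] + parts[1] + parts[2]
    else:
        parts = [tensors[i] * weights[:, i].reshape(-1, 1) for i in range(3)]
        z_final = nn.concatenate(parts, axis=-1)
    w_bar = weights.data.mean(axis=0)
    return FusionOutput(
        z_mv=z_final.data,
        alpha=w_bar,
        w=w_bar,
        views=("view0", "view1", "view2"),
        batch_size=arrays[0].shape[0],
    )


# ---------------------------------------------------------------------------
# Aggregator reconstruction pre-training
# ---------------------------------------------------------------------------


@dataclass
class AggregatorPretrainResult:
    params: GatingParams
    final_losses: dict[str, float]
    initial_losses: dict[str, float]
    alpha: np.ndarray
    alpha_history: list[np.ndarray] = field(default_factory=list)
    views: tuple[str, ...] = ()


def pretrain_aggregator(
    triples: dict[str, np.ndarray] | Sequence[np.ndarray],
    params: GatingParams | None = None,
    epochs: int = 50,
    batch_size: int = 64,
    lr: float = 1e-3,
    seed: int = 0,
) -> AggregatorPretrainResult:
    """Pre-train the aggregator with the embedding-reconstruction task.

    One linear head per view maps the fused embedding z_mv back to that
    view's input embedding; the loss is the summed per-view mean squared
    error.  Returns the trained params (with end-of-training gate scores
    frozen for inference), per-view losses before and after training, the
    final alpha, and the alpha trajectory per epoch.
    """
    if isinstance(triples, dict):
        views = tuple(triples)
        arrays = [np.asarray(triples[v], dtype=np.float64) for v in views]
    else:
        arrays = [np.asarray(z, dtype=np.float64) for z in triples]
        views = tuple(f"view{i}" for i in range(len(arrays)))
    n, dim = arrays[0].shape
    if n < 1:
        raise ValueError("need at least one embedding triple")
    if params is None:
        params = GatingParams(dim, output_dim=dim, seed=seed)
    rng = np.random.default_rng(seed)
    heads = [nn.Linear(params.output_dim, dim, rng) for _ in views]

    def epoch_losses() -> dict[str, float]:
        z_mv, _, _ = _fuse_tensors([Tensor(a) for a in arrays], params)
        return {
            v: float(((heads[m](z_mv) - Tensor(arrays[m])) ** 2).mean().data)
            for m, v in enumerate(views)
        }

    initial = epoch_losses()
    opt = nn.Adam(params.parameters() + [p for h in heads for p in h.parameters()], lr=lr)
    history: list[np.ndarray] = []
    last_w = None
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch = [Tensor(a[idx]) for a in arrays]
            z_mv, alpha, w = _fuse_tensors(batch, params)
            loss = None
            for m in range(len(views)):
                term = ((heads[m](z_mv) - batch[m]) ** 2).mean()
                loss = term if loss is None else loss + term
            if not np.isfinite(loss.data):
                raise FloatingPointError("aggregator pre-training diverged (non-finite loss)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            last_w = w.data.copy()
        _, alpha_full, w_full = _fuse_tensors([Tensor(a) for a in arrays], params)
        history.append(alpha_full.data.copy())
        last_w = w_full.data.copy()
    params.frozen_w = last_w
    final = epoch_losses()
    _, alpha_final, _ = _fuse_tensors([Tensor(a) for a in arrays], params)
    return AggregatorPretrainResult(
        params=params,
        final_losses=final,
        initial_losses=initial,
        alpha=alpha_final.data,
        alpha_history=history,
        views=views,
    )
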