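"""Per-view neural encoders mapping each molecular view to a fixed-width embedding.

Three encoders share a common contract: a batched, differentiable forward
pass used during training, and a convenience ``encode`` method returning a
:class:`ViewEmbedding` (with optional per-token attention) for a single
molecule.  All are pure functions of (input, parameters): identical seeds
give identical parameters and repeated calls give bit-identical outputs.

* :class:`GraphEncoder` — a transformer over the molecular graph's node and
  edge tokens.  Each of the five categorical features per token is embedded
  separately (width ``embed_dim // 4``, i.e. 128 when the token width is
  512) and the concatenation is projected to the token width; nodes and
  edges share the transformer and are distinguished by a learned type
  embedding.  Spectral positional encoding comes from the graph-Laplacian
  eigenvectors (a node token uses its own eigenvector row; an edge token the
  mean of its two endpoints' rows, which is invariant to endpoint order).
* :class:`ImageEncoder` — a small residual convolutional network over the
  normalized 224x224 depiction: a fixed 4x average-pool stem, two strided
  convolutions around a residual block, global average pooling.
* :class:`TextEncoder` — a transformer over the SMILES token-id sequence
  with learned positional embeddings; default token width 768.

Desk-scale defaults (depth 2, heads 4, output width 256) keep every model
trainable on one CPU; the config documents how to scale up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Literal

import numpy as np

from mvmol import nn
from mvmol.nn import Tensor
from mvmol.views import (
    ATOM_FEATURE_SIZES,
    BOND_FEATURE_SIZES,
    EVAL_SIZE,
    GraphView,
    ImageView,
    TextView,
    Vocabulary,
)

_DEFAULT_EMBED = {"graph": 512, "text": 768, "image": 16}


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters for one view encoder.

    ``embed_dim`` is the token width for graph/text and the base channel
    count for the image CNN; view defaults are 512 / 768 / 16 respectively.
    """

    view: Literal["graph", "image", "text"]
    embed_dim: int = 0  # 0 -> view default
    depth: int = 2
    heads: int = 4
    output_dim: int = 256
    seed: int = 0
    laplacian_k: int = 8
    max_len: int = 256

    def __post_init__(self):
        if self.embed_dim == 0:
            object.__setattr__(self, "embed_dim", _DEFAULT_EMBED[self.view])
        if min(self.embed_dim, self.depth, self.heads, self.output_dim) <= 0:
            raise ValueError("all dimensions must be positive")


@dataclass
class ViewEmbedding:
    """A single molecule's embedding from one view.

    ``per_token_attention``, when recorded, holds nonnegative weights over
    the view's input tokens (graph/text) or spatial cells (image) that sum
    to one.
    """

    z: np.ndarray
    view: Literal["graph", "image", "text"]
    per_token_attention: np.ndarray | None = None


class _TransformerCore(nn.Module):
    def __init__(self, dim: int, depth: int, heads: int, out_dim: int, rng):
        self.blocks = [nn.TransformerBlock(dim, heads, rng) for _ in range(depth)]
        self.norm = nn.LayerNorm(dim)
        self.out = nn.Linear(dim, out_dim, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None) -> Tensor:
        for blk in self.blocks:
            x = blk(x, pad_mask)
        pooled = nn.masked_mean_pool(self.norm(x), pad_mask)
        return self.out(pooled)

    def set_record_attention(self, on: bool) -> None:
        self.blocks[-1].attn.record_attention = on

    def pooled_attention(self, pad_mask: np.ndarray) -> np.ndarray:
        """Per-token weights: last-layer attention averaged over heads and
        over the queries that feed the mean pool, renormalized over real
        tokens."""
        probs = self.blocks[-1].attn.last_attention  # (B, H, T, T)
        if probs is None:
            raise RuntimeError("attention recording was not enabled")
        w = probs.mean(axis=1)  # avg heads -> (B, T, T)
        m = pad_mask.astype(float)
        denom = np.maximum(m.sum(axis=1, keepdims=True), 1.0)
        w = (w * m[:, :, None]).sum(axis=1) / denom  # avg over real queries
        w = w * m
        return w / np.maximum(w.sum(axis=1, keepdims=True), 1e-12)


class GraphEncoder(nn.Module):
    """Transformer over node + edge tokens with spectral positional encoding."""

    def __init__(self, config: EncoderConfig):
        if config.view != "graph":
            raise ValueError("config.view must be 'graph'")
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.embed_dim
        feat_dim = max(1, d // 4)
        # +1 slot per categorical table: the mask sentinel used in
        # masked-feature pre-training
        self.atom_embeds = [nn.Embedding(s + 1, feat_dim, rng) for s in ATOM_FEATURE_SIZES]
        self.bond_embeds = [nn.Embedding(s + 1, feat_dim, rng) for s in BOND_FEATURE_SIZES]
        self.atom_proj = nn.Linear(5 * feat_dim, d, rng)
        self.bond_proj = nn.Linear(5 * feat_dim, d, rng)
        self.type_embed = nn.Embedding(2, d, rng)  # 0 = node token, 1 = edge token
        self.pe_proj = nn.Linear(config.laplacian_k, d, rng, bias=False)
        self.core = _TransformerCore(d, config.depth, config.heads, config.output_dim, rng)

    # -- batching ------------------------------------------------------------
    @staticmethod
    def prepare(views: list[GraphView], k: int = 8) -> dict:
        """Pad a list of graph views into dense batch arrays.

        Requires Laplacian PE attached (``laplacian_pe``) with the same k.
        """
        B = len(views)
        t_max = max(v.n_tokens for v in views)
        feats = np.zeros((B, t_max, 5), dtype=np.int64)
        types = np.zeros((B, t_max), dtype=np.int64)
        pe = np.zeros((B, t_max, k), dtype=np.float64)
        mask = np.zeros((B, t_max), dtype=np.float64)
        for b, v in enumerate(views):
            if v.laplacian_eigenvectors is None:
                raise ValueError("laplacian_pe must be attached before encoding")
            na, ne = v.n_atoms, v.n_edges
            feats[b, :na] = v.node_features
            types[b, :na] = 0
            pe[b, :na] = v.laplacian_eigenvectors[:, :k]
            if ne:
                feats[b, na : na + ne] = v.edge_features
                types[b, na : na + ne] = 1
                ends = v.laplacian_eigenvectors[v.edges]  # (ne, 2, k)
                pe[b, na : na + ne] = ends.mean(axis=1)
            mask[b, : na + ne] = 1.0
        return {"features": feats, "types": types, "pe": pe, "mask": mask}

    def __call__(self, batch: dict, feature_mask: np.ndarray | None = None) -> Tensor:
        """Embed a prepared batch; ``feature_mask`` (B, T) flags tokens whose
        categorical features are replaced by the mask sentinel."""
        feats = batch["features"]
        types = batch["types"]
        B, T, _ = feats.shape
        is_node = types == 0
        parts = []
        for f in range(5):
            idx_atom = feats[:, :, f].copy()
            idx_bond = feats[:, :, f].copy()
            if feature_mask is not None:
                idx_atom = np.where(feature_mask > 0, ATOM_FEATURE_SIZES[f], idx_atom)
                idx_bond = np.where(feature_mask > 0, BOND_FEATURE_SIZES[f], idx_bond)
            ea = self.atom_embeds[f](np.where(is_node, idx_atom, 0))
            eb = self.bond_embeds[f](np.where(is_node, 0, idx_bond))
            sel = Tensor(is_node[:, :, None].astype(np.float64))
            parts.append(ea * sel + eb * (1.0 - sel))
        tok = nn.concatenate(parts, axis=-1)
        sel = Tensor(is_node[:, :, None].astype(np.float64))
        x = self.atom_proj(tok) * sel + self.bond_proj(tok) * (1.0 - sel)
        x = x + self.type_embed(types) + self.pe_proj(Tensor(batch["pe"]))
        return self.core(x, batch["mask"])

    def encode(self, view: GraphView, record_attention: bool = False) -> ViewEmbedding:
        batch = self.prepare([view], k=self.config.laplacian_k)
        self.core.set_record_attention(record_attention)
        z = self(batch)
        attn = self.core.pooled_attention(batch["mask"])[0] if record_attention else None
        self.core.set_record_attention(False)
        return ViewEmbedding(z=z.data[0], view="graph", per_token_attention=attn)


class TextEncoder(nn.Module):
    """Transformer over SMILES token ids with learned positional embeddings."""

    def __init__(self, config: EncoderConfig, vocabulary: Vocabulary):
        if config.view != "text":
            raise ValueError("config.view must be 'text'")
        self.config = config
        self.vocabulary = vocabulary
        rng = np.random.default_rng(config.seed)
        d = config.embed_dim
        self.token_embed = nn.Embedding(len(vocabulary), d, rng)
        self.pos_embed = nn.Embedding(config.max_len, d, rng)
        self.core = _TransformerCore(d, config.depth, config.heads, config.output_dim, rng)

    @property
    def pad_id(self) -> int:
        return self.vocabulary.pad_id

    def prepare(self, views: list[TextView]) -> dict:
        B = len(views)
        t_max = max(len(v) for v in views)
        if t_max > self.config.max_len:
            raise ValueError(f"sequence length {t_max} exceeds max_len {self.config.max_len}")
        ids = np.full((B, t_max), self.pad_id, dtype=np.int64)
        mask = np.zeros((B, t_max), dtype=np.float64)
        for b, v in enumerate(views):
            n = len(v)
            ids[b, :n] = v.token_ids
            mask[b, :n] = 1.0
        return {"ids": ids, "mask": mask}

    def __call__(self, batch: dict, mask_positions: np.ndarray | None = None) -> Tensor:
        ids = batch["ids"]
        if (ids < 0).any() or (ids >= len(self.vocabulary)).any():
            raise ValueError("token id out of vocabulary range")
        if mask_positions is not None:
            ids = np.where(mask_positions > 0, self.vocabulary.mask_id, ids)
        T = ids.shape[1]
        x = self.token_embed(ids) + self.pos_embed(np.arange(T))
        return self.core(x, batch["mask"])

    def encode(self, view: TextView, record_attention: bool = False) -> ViewEmbedding:
        batch = self.prepare([view])
        self.core.set_record_attention(record_attention)
        z = self(batch)
        attn = self.core.pooled_attention(batch["mask"])[0] if record_attention else None
        self.core.set_record_attention(False)
        return ViewEmbedding(z=z.data[0], view="text", per_token_attention=attn)


def _pad_same(x: Tensor, p: int) -> Tensor:
    """Zero-pad H and W by p on each side (channels-last)."""
    B, H, W, C = x.shape
    zh = Tensor(np.zeros((B, p, W, C)))
    x = nn.concatenate([zh, x, zh], axis=1)
    zw = Tensor(np.zeros((B, H + 2 * p, p, C)))
    return nn.concatenate([zw, x, zw], axis=2)


class ImageEncoder(nn.Module):
    """Small residual CNN over the normalized molecular depiction.

    Input is the eval-size 224x224x3 grid (or the precomputed 56x56x3
    output of the fixed 4x average-pool stem, see :meth:`prepare`).
    """

    STEM_POOL = 8

    def __init__(self, config: EncoderConfig):
        if config.view != "image":
            raise ValueError("config.view must be 'image'")
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.embed_dim
        self.conv1 = nn.Conv2d(3, c, kernel=3, stride=2, rng=rng)
        self.res_a = nn.Conv2d(c, c, kernel=3, stride=1, rng=rng)
        self.res_b = nn.Conv2d(c, c, kernel=3, stride=1, rng=rng)
        self.conv2 = nn.Conv2d(c, 2 * c, kernel=3, stride=2, rng=rng)
        self.out = nn.Linear(2 * c, config.output_dim, rng)
        self.record_attention = False
        self.last_saliency: np.ndarray | None = None

    @classmethod
    def prepare(cls, views: list[ImageView]) -> dict:
        """Apply the fixed average-pool stem and stack into a batch array."""
        pooled = []
        for v in views:
            if v.pixels.shape[:2] != (EVAL_SIZE, EVAL_SIZE):
                raise ValueError(f"expected {EVAL_SIZE}x{EVAL_SIZE} input, got {v.pixels.shape[:2]}")
            p = cls.STEM_POOL
            h = EVAL_SIZE // p
            arr = v.pixels.reshape(h, p, h, p, 3).mean(axis=(1, 3))
            pooled.append(arr)
        return {"pixels": np.stack(pooled)}

    def __call__(self, batch: dict) -> Tensor:
        x = Tensor(batch["pixels"])
        x = self.conv1(_pad_same(x, 1)).relu()
        r = self.res_b(_pad_same(self.res_a(_pad_same(x, 1)).relu(), 1))
        x = (x + r).relu()
        x = self.conv2(_pad_same(x, 1)).relu()
        if self.record_attention:
            sal = np.abs(x.data).mean(axis=-1)  # (B, h, w)
            flat = sal.reshape(sal.shape[0], -1)
            self.last_saliency = flat / np.maximum(flat.sum(axis=1, keepdims=True), 1e-12)
        pooled = x.mean(axis=(1, 2)) if x.ndim == 4 else x
        return self.out(pooled)

    def encode(self, view: ImageView, record_attention: bool = False) -> ViewEmbedding:
        batch = self.prepare([view])
        self.record_attention = record_attention
        z = self(batch)
        attn = self.last_saliency[0] if record_attention else None
        self.record_attention = False
        return ViewEmbedding(z=z.data[0], view="image", per_token_attention=attn)


def extract_attention(embedding: ViewEmbedding) -> np.ndarray:
    """Per-token (or per-cell) attention weights recorded during encoding."""
    if embedding.per_token_attention is None:
        raise RuntimeError("encoder was not run with attention recording enabled")
    return embedding.per_token_attention


def build_encoder(config: EncoderConfig, vocabulary: Vocabulary | None = None):
    if config.view == "graph":
        return GraphEncoder(config)
    if config.view == "image":
        return ImageEncoder(config)
    if config.view == "text":
        if vocabulary is None:
            raise ValueError("text encoder needs a vocabulary")
        return TextEncoder(config, vocabulary)
    raise ValueError(f"unknown view {config.view!r}")


def save_checkpoint(encoder, path: str | Path) -> None:
    """Single-file checkpoint: parameter arrays plus the JSON-encoded config."""
    state = encoder.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(encoder.config)).encode(), dtype=np.uint8
    )
    np.savez(Path(path), **state)


def load_checkpoint(path: str | Path, vocabulary: Vocabulary | None = None):
    data = np.load(Path(path))
    config = EncoderConfig(**json.loads(bytes(data["__config__"]).decode()))
    encoder = build_encoder(config, vocabulary)
    encoder.load_state_dict({k: v for k, v in data.items() if k != "__config__"})
    return encoder
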