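"""Dataset splitting, fine-tuning, metrics, model agreement and screening.

Splitting supports a per-record random split and two scaffold-cluster-aware
splits that guarantee no Bemis-Murcko scaffold spans two partitions:

* ``size_ordered_scaffold`` — clusters assigned in descending size order,
  filling train, then validation, then test;
* ``balanced_scaffold`` — clusters larger than the test-partition target are
  forced into train, remaining clusters are shuffled into partitions.

Acyclic molecules (empty scaffold) form one singleton cluster per unique
molecule.

Fine-tuning assembles the view encoders and the gated aggregator into one
model trained end-to-end with per-subnetwork learning rates (up to four
parameter groups: three encoders plus aggregator/head), early stopping on
validation, and seed-averaged reporting (mean and 95% confidence interval
over seeds).  Regression metrics can be rescaled for cross-dataset plotting
via the affine transform m' = 1 - (m - m0)/s with per-dataset registry
constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score, mean_absolute_error, roc_auc_score

from mvmol import nn
from mvmol.chem_io import DatasetTable, MoleculeRecord, murcko_scaffold
from mvmol.encoders import (
    EncoderConfig,
    GraphEncoder,
    ImageEncoder,
    TextEncoder,
)
from mvmol.fusion import GatingParams, _fuse_tensors
from mvmol.nn import Tensor
from mvmol.views import (
    Vocabulary,
    build_vocabulary,
    featurize_graph,
    laplacian_pe,
    render_image,
    tokenize_smiles,
)

SplitMethod = Literal["random", "size_ordered_scaffold", "balanced_scaffold"]
Partition = Literal["train", "validation", "test"]
PARTITIONS: tuple[Partition, ...] = ("train", "validation", "test")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def cluster_key(record: MoleculeRecord) -> str:
    """Scaffold-cluster key: the Murcko scaffold SMILES, or, for acyclic
    molecules, the molecule itself (one singleton cluster per unique
    molecule)."""
    key = murcko_scaffold(record).scaffold_smiles
    return key if key else f"mol:{record.canonical_smiles}"


@dataclass
class SplitAssignment:
    """Per-record partition assignment for one dataset."""

    partition: np.ndarray  # array of strings in {train, validation, test}
    method: SplitMethod
    ratios: tuple[float, float, float]
    seed: int

    def indices(self, part: Partition) -> np.ndarray:
        return np.flatnonzero(self.partition == part)

    def counts(self) -> dict[str, int]:
        return {p: int((self.partition == p).sum()) for p in PARTITIONS}


def split_dataset(
    table: DatasetTable,
    method: SplitMethod = "balanced_scaffold",
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Partition a dataset into train/validation/test.

    ``random`` assigns each record independently by a seeded multinomial
    draw.  The scaffold methods first cluster records by
    :func:`cluster_key` and then assign whole clusters, so no scaffold ever
    spans two partitions.
    """
    n = len(table)
    if n < 3:
        raise ValueError("dataset too small to split (need n >= 3)")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    partition = np.empty(n, dtype=object)

    if method == "random":
        draws = rng.choice(3, size=n, p=list(ratios))
        for i, d in enumerate(draws):
            partition[i] = PARTITIONS[d]
        return SplitAssignment(partition, method, ratios, seed)

    clusters: dict[str, list[int]] = {}
    for i, rec in enumerate(table.records):
        clusters.setdefault(cluster_key(rec), []).append(i)
    items = list(clusters.items())

    if method == "size_ordered_scaffold":
        # descending size; deterministic tie-break on the cluster key
        items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
        train_cap = ratios[0] * n
        val_cap = (ratios[0] + ratios[1]) * n
        assigned = 0
        for key, idxs in items:
            if assigned < train_cap:
                part: Partition = "train"
            elif assigned < val_cap:
                part = "validation"
            else:
                part = "test"
            for i in idxs:
                partition[i] = part
            assigned += len(idxs)
    elif method == "balanced_scaffold":
        test_target = ratios[2] * n
        val_target = ratios[1] * n
        large = [kv for kv in items if len(kv[1]) > test_target]
        small = [kv for kv in items if len(kv[1]) <= test_target]
        # ties among equal-size clusters broken by a seeded shuffle of the
        # key-sorted list
        small.sort(key=lambda kv: kv[0])
        rng.shuffle(small)
        for _, idxs in large:
            for i in idxs:
                partition[i] = "train"
        n_test = n_val = 0
        for key, idxs in small:
            if n_test < test_target:
                part = "test"
                n_test += len(idxs)
            elif n_val < val_target:
                part = "validation"
                n_val += len(idxs)
            else:
                part = "train"
            for i in idxs:
                partition[i] = part
    else:
        raise ValueError(f"unknown split method {method!r}")

    if not (partition == "test").any():
        warnings.warn(
            "degenerate dataset: test partition is empty under scaffold rules",
            stacklevel=2,
        )
    return SplitAssignment(partition, method, ratios, seed)


def split_to_frame(table: DatasetTable, split: SplitAssignment) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "smiles": [r.canonical_smiles for r in table.records],
            "partition": split.partition,
        }
    )


# ---------------------------------------------------------------------------
# Metric scaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaledMetricParams:
    """Offset/scale of the affine metric transform m' = 1 - (m - m0)/s."""

    m0: float
    s: float

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("scale s must be positive")


#: Registry of published offset/scale pairs for regression benchmarks.
SCALED_METRIC_REGISTRY: dict[str, ScaledMetricParams] = {
    "esol": ScaledMetricParams(0.7, 1.0),
    "freesolv": ScaledMetricParams(1.5, 5.0),
    "lipophilicity": ScaledMetricParams(0.50, 1.0),
    "qm7": ScaledMetricParams(55.0, 100.0),
    "computational_adme": ScaledMetricParams(0.30, 1.0),
}


def scale_metric(m: float, params: ScaledMetricParams) -> float:
    """Rescale a regression metric onto the ROC-AUC-comparable scale."""
    return 1.0 - (m - params.m0) / params.s


def inverse_scale_metric(m_prime: float, params: ScaledMetricParams) -> float:
    return params.m0 + params.s * (1.0 - m_prime)


# ---------------------------------------------------------------------------
# Model assembly and featurization
# ---------------------------------------------------------------------------

ALL_VIEWS = ("graph", "image", "text")


@dataclass(frozen=True)
class ModelConfig:
    """Desk-scale multi-view model configuration for fine-tuning runs."""

    views: tuple[str, ...] = ALL_VIEWS
    embed_dim: int = 32
    image_channels: int = 6
    depth: int = 2
    heads: int = 4
    output_dim: int = 32
    laplacian_k: int = 8
    max_len: int = 160
    seed: int = 0

    def encoder_config(self, view: str, seed: int) -> EncoderConfig:
        embed = self.image_channels if view == "image" else self.embed_dim
        return EncoderConfig(
            view=view,  # type: ignore[arg-type]
            embed_dim=embed,
            depth=self.depth,
            heads=self.heads,
            output_dim=self.output_dim,
            seed=seed,
            laplacian_k=self.laplacian_k,
            max_len=self.max_len,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; one learning rate per subnetwork group."""

    lr_graph: float = 1e-3
    lr_image: float = 1e-3
    lr_text: float = 1e-3
    lr_head: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    n_seeds: int = 5


def featurize_table(
    table: DatasetTable,
    views: Sequence[str] = ALL_VIEWS,
    vocabulary: Vocabulary | None = None,
    laplacian_k: int = 8,
) -> dict:
    """Precompute the per-view batch arrays for a whole dataset once.

    Images are rendered in eval mode (deterministic central crop) and passed
    through the image encoder's fixed pooling stem so the cached arrays stay
    small.  The returned dict is reusable across seeds and model variants.
    """
    feats: dict = {"n": len(table)}
    if "graph" in views:
        gviews = [
            laplacian_pe(featurize_graph(r), k=laplacian_k) for r in table.records
        ]
        feats["graph"] = GraphEncoder.prepare(gviews, k=laplacian_k)
    if "text" in views:
        if vocabulary is None:
            vocabulary = build_vocabulary(
                [r.canonical_smiles for r in table.records]
            )
        tviews = [
            tokenize_smiles(r.canonical_smiles, vocabulary) for r in table.records
        ]
        feats["text_views"] = tviews
        feats["vocabulary"] = vocabulary
    if "image" in views:
        iviews = [render_image(r, mode="eval") for r in table.records]
        feats["image"] = ImageEncoder.prepare(iviews)
    return feats


def _slice_graph(batch: dict, idx: np.ndarray) -> dict:
    out = {k: v[idx] for k, v in batch.items()}
    # trim padding to the longest sequence in this batch
    t_max = max(1, int(out["mask"].sum(axis=1).max()))
    return {k: v[:, :t_max] for k, v in out.items()}


class MultiViewModel(nn.Module):
    """View encoders + gated aggregator + prediction head, trained jointly.

    With a single view the aggregator reduces to alpha = (1.0) and the
    model is that view's encoder plus the head.
    """

    def __init__(self, config: ModelConfig, vocabulary: Vocabulary | None = None):
        self.config = config
        self.task_kind: str = "regression"
        rng = np.random.default_rng(config.seed)
        self.encoders: dict[str, nn.Module] = {}
        for i, view in enumerate(config.views):
            enc_cfg = config.encoder_config(view, seed=config.seed + 17 * (i + 1))
            if view == "graph":
                self.encoders[view] = GraphEncoder(enc_cfg)
            elif view == "image":
                self.encoders[view] = ImageEncoder(enc_cfg)
            elif view == "text":
                if vocabulary is None:
                    raise ValueError("text view requires a vocabulary")
                self.encoders[view] = TextEncoder(enc_cfg, vocabulary)
            else:
                raise ValueError(f"unknown view {view!r}")
        self.gating = GatingParams(
            config.output_dim, output_dim=config.output_dim, seed=config.seed + 5
        )
        self.head = nn.Linear(config.output_dim, 1, rng)

    # -- forward -------------------------------------------------------------
    def _view_embeddings(self, feats: dict, idx: np.ndarray) -> list[Tensor]:
        outs = []
        for view in self.config.views:
            enc = self.encoders[view]
            if view == "graph":
                outs.append(enc(_slice_graph(feats["graph"], idx)))
            elif view == "image":
                outs.append(enc({"pixels": feats["image"]["pixels"][idx]}))
            elif view == "text":
                batch = enc.prepare([feats["text_views"][i] for i in idx])
                outs.append(enc(batch))
        return outs

    def forward(
        self, feats: dict, idx: np.ndarray, frozen: bool = False
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Scores plus gate diagnostics for the records at ``idx``.

        ``frozen=True`` uses the end-of-training gate scores, making
        per-molecule predictions independent of batch composition.
        """
        embeddings = self._view_embeddings(feats, idx)
        frozen_w = self.gating.frozen_w if frozen else None
        if frozen and frozen_w is None:
            raise ValueError("no frozen gate scores recorded; train first")
        z_mv, alpha, w = _fuse_tensors(embeddings, self.gating, frozen_w)
        scores = self.head(z_mv).reshape(-1)
        return scores, alpha, w

    def predict(self, feats: dict, idx: np.ndarray | None = None) -> np.ndarray:
        """Deterministic frozen-gate scores (probabilities for classification)."""
        if idx is None:
            idx = np.arange(feats["n"])
        scores, _, _ = self.forward(feats, idx, frozen=True)
        if self.task_kind == "classification":
            return 1.0 / (1.0 + np.exp(-scores.data))
        return scores.data

    @property
    def alpha(self) -> dict[str, float]:
        """Frozen-gate view weights (the interpretability readout)."""
        if self.gating.frozen_w is None:
            raise ValueError("model not trained")
        e = np.exp(self.gating.frozen_w - self.gating.frozen_w.max())
        a = e / e.sum()
        return {v: float(x) for v, x in zip(self.config.views, a)}

    def parameter_groups(self, train_cfg: TrainConfig) -> list[dict]:
        """Up to four optimizer groups: one per encoder plus aggregator+head."""
        lr_of = {
            "graph": train_cfg.lr_graph,
            "image": train_cfg.lr_image,
            "text": train_cfg.lr_text,
        }
        groups = [
            {"params": enc.parameters(), "lr": lr_of[view]}
            for view, enc in self.encoders.items()
        ]
        groups.append(
            {
                "params": self.gating.parameters() + self.head.parameters(),
                "lr": train_cfg.lr_head,
            }
        )
        return groups


# ---------------------------------------------------------------------------
# Metrics and reporting
# ---------------------------------------------------------------------------


def _primary_metric(task_kind: str, y: np.ndarray, pred: np.ndarray) -> float:
    if task_kind == "classification":
        return float(roc_auc_score(y, pred))
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def _metric_better(task_kind: str, a: float, b: float) -> bool:
    """True when metric a is better than b (higher AUC, lower RMSE)."""
    return a > b if task_kind == "classification" else a < b


@dataclass
class MetricReport:
    """Seed-averaged held-out metrics with a 95% confidence interval."""

    task_kind: str
    metric_name: str
    per_seed: list[float]
    mean: float
    ci95: float
    n_seeds: int
    extras: dict[str, float] = field(default_factory=dict)
    scaled_mean: float | None = None

    @classmethod
    def from_runs(
        cls,
        task_kind: str,
        per_seed: Sequence[float],
        extras: dict[str, float] | None = None,
        scale_params: ScaledMetricParams | None = None,
    ) -> "MetricReport":
        values = np.asarray(per_seed, dtype=float)
        if len(values) < 2:
            ci = float("nan")
        else:
            ci = float(1.96 * values.std(ddof=1) / np.sqrt(len(values)))
        mean = float(values.mean())
        return cls(
            task_kind=task_kind,
            metric_name="roc_auc" if task_kind == "classification" else "rmse",
            per_seed=[float(v) for v in values],
            mean=mean,
            ci95=ci,
            n_seeds=len(values),
            extras=dict(extras or {}),
            scaled_mean=None
            if scale_params is None
            else scale_metric(mean, scale_params),
        )


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------


@dataclass
class FinetuneResult:
    report: MetricReport
    best_model: MultiViewModel
    best_seed: int
    val_by_seed: list[float]
    alpha: dict[str, float]
    feats: dict = field(repr=False, default_factory=dict)


def _train_one(
    model: MultiViewModel,
    feats: dict,
    y: np.ndarray,
    split: SplitAssignment,
    train_cfg: TrainConfig,
    rng: np.random.Generator,
) -> float:
    """Train in place with early stopping; returns the best validation metric."""
    train_idx = split.indices("train")
    val_idx = split.indices("validation")
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("empty train or validation partition")
    task = model.task_kind
    opt = nn.Adam(model.parameter_groups(train_cfg))
    best_val = -np.inf if task == "classification" else np.inf
    best_state = model.state_dict()
    best_w = None
    patience_left = train_cfg.patience
    for _ in range(train_cfg.max_epochs):
        order = rng.permutation(len(train_idx))
        w_sum, n_batches = 0.0, 0
        for start in range(0, len(train_idx), train_cfg.batch_size):
            idx = train_idx[order[start : start + train_cfg.batch_size]]
            scores, _, w = model.forward(feats, idx)
            if task == "classification":
                loss = nn.bce_with_logits(scores, y[idx])
            else:
                loss = nn.mse(scores, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError("fine-tuning diverged (non-finite loss)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            w_sum = w_sum + w.data
            n_batches += 1
        # freeze gate scores at this epoch's running mean for evaluation
        model.gating.frozen_w = np.asarray(w_sum) / max(n_batches, 1)
        val_pred = model.predict(feats, val_idx)
        val_metric = _primary_metric(task, y[val_idx], val_pred)
        if _metric_better(task, val_metric, best_val):
            best_val = val_metric
            best_state = model.state_dict()
            best_w = model.gating.frozen_w.copy()
            patience_left = train_cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    model.load_state_dict(best_state)
    model.gating.frozen_w = best_w
    return float(best_val)


def finetune_task(
    table: DatasetTable,
    split: SplitAssignment,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    feats: dict | None = None,
    scale_params: ScaledMetricParams | None = None,
) -> FinetuneResult:
    """Fine-tune the (multi-)view model on a labeled dataset.

    Runs ``n_seeds`` independent trainings, early-stops each on the
    validation partition, reports held-out test metrics as mean with a 95%
    confidence interval, and returns the model instance with the highest
    validation performance across seeds.
    """
    if table.labels is None:
        raise ValueError("table has no labels")
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    y = np.asarray(table.labels, dtype=np.float64)
    if feats is None:
        feats = featurize_table(
            table, views=model_config.views, laplacian_k=model_config.laplacian_k
        )
    vocabulary = feats.get("vocabulary")
    test_idx = split.indices("test")
    if len(test_idx) == 0:
        raise ValueError("empty test partition")

    per_seed_test: list[float] = []
    per_seed_val: list[float] = []
    best: tuple[float, MultiViewModel, int] | None = None
    for s in range(train_config.n_seeds):
        cfg = replace(model_config, seed=model_config.seed + 1000 * s)
        model = MultiViewModel(cfg, vocabulary)
        model.task_kind = table.task_kind
        rng = np.random.default_rng(cfg.seed + 1)
        val_metric = _train_one(model, feats, y, split, train_config, rng)
        test_pred = model.predict(feats, test_idx)
        test_metric = _primary_metric(table.task_kind, y[test_idx], test_pred)
        per_seed_val.append(val_metric)
        per_seed_test.append(test_metric)
        if best is None or _metric_better(table.task_kind, val_metric, best[0]):
            best = (val_metric, model, s)

    assert best is not None
    extras: dict[str, float] = {}
    best_model = best[1]
    test_pred = best_model.predict(feats, test_idx)
    if table.task_kind == "regression":
        extras["pearson_r"] = float(
            stats.pearsonr(test_pred, y[test_idx]).statistic
        )
        extras["mae"] = float(mean_absolute_error(y[test_idx], test_pred))
    report = MetricReport.from_runs(
        table.task_kind, per_seed_test, extras=extras, scale_params=scale_params
    )
    return FinetuneResult(
        report=report,
        best_model=best_model,
        best_seed=best[2],
        val_by_seed=per_seed_val,
        alpha=best_model.alpha,
        feats=feats,
    )


# ---------------------------------------------------------------------------
# Model agreement
# ---------------------------------------------------------------------------


@dataclass
class AgreementResult:
    statistic: float
    kind: str  # "f1" or "pearson"
    p_value: float | None = None
    degenerate: bool = False


def model_agreement(
    preds_a: np.ndarray, preds_b: np.ndarray, task_kind: str
) -> AgreementResult:
    """Agreement between two models' predictions on the same inputs.

    Classification: both score vectors are binarized at 0.5 and the F1 of
    model b's positives against model a's positives is returned — an
    asymmetric measure of how well b predicts a.  Regression: Pearson
    correlation with a chi-squared p-value (statistic n * r^2, 1 dof).
    """
    a = np.asarray(preds_a, dtype=float)
    b = np.asarray(preds_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("prediction vectors must have equal length")
    if task_kind == "classification":
        ya = (a >= 0.5).astype(int)
        yb = (b >= 0.5).astype(int)
        degenerate = len(np.unique(ya)) < 2
        if degenerate:
            warnings.warn("degenerate agreement input: one class only", stacklevel=2)
        return AgreementResult(
            statistic=float(f1_score(ya, yb, zero_division=0.0)),
            kind="f1",
            degenerate=degenerate,
        )
    r = float(stats.pearsonr(a, b).statistic)
    p = float(stats.chi2.sf(len(a) * r * r, df=1))
    return AgreementResult(statistic=r, kind="pearson", p_value=p)


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


def rank_screen(
    model: MultiViewModel,
    library: DatasetTable,
    top_k: int | None = None,
    feats: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Rank a compound library by predicted activity (frozen-gate inference).

    Returns the top-k table (descending score, ties broken by canonical
    SMILES) and the per-view alpha weights of the model.  Unparseable
    library rows were already dropped at load time; the count is carried on
    ``library.dropped_rows``.
    """
    if feats is None:
        vocab = (
            model.encoders["text"].vocabulary if "text" in model.encoders else None
        )
        feats = featurize_table(
            library,
            views=model.config.views,
            vocabulary=vocab,
            laplacian_k=model.config.laplacian_k,
        )
    scores = model.predict(feats)
    df = pd.DataFrame(
        {
            "smiles": [r.canonical_smiles for r in library.records],
            "score": scores,
        }
    )
    df = df.sort_values(
        ["score", "smiles"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    if top_k is not None:
        df = df.head(top_k)
    return df, model.alpha
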