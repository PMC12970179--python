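"""Drug-target interaction head: ligand + protein embeddings -> affinity.

The ligand embedding (from any view encoder, the fused model, or a
descriptor vector) and an externally supplied protein embedding are each
projected to 64 dimensions, concatenated into a 128-D joint embedding, and
passed through a small MLP regression head.  Protein embeddings are inputs
(id -> vector tables); computing them is outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mvmol import nn
from mvmol.chem_io import MoleculeRecord
from mvmol.nn import Tensor

LIGAND_PROJ_DIM = 64
PROTEIN_PROJ_DIM = 64
JOINT_DIM = LIGAND_PROJ_DIM + PROTEIN_PROJ_DIM  # 128


@dataclass(frozen=True)
class ProteinEmbedding:
    """A named protein vector of arbitrary (but dataset-consistent) width."""

    id: str
    vector: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=np.float64))
        if not np.all(np.isfinite(self.vector)):
            raise ValueError(f"non-finite protein embedding for {self.id!r}")


@dataclass(frozen=True)
class DTIPair:
    """One (ligand, protein, affinity) training example; pKd-like units."""

    ligand: MoleculeRecord
    protein_id: str
    affinity: float


class UnknownProteinError(KeyError):
    pass


class DTIModel(nn.Module):
    """Projection pair + MLP head over the 128-D joint embedding."""

    def __init__(self, ligand_dim: int, protein_dim: int, seed: int = 0, hidden: int = 64):
        rng = np.random.default_rng(seed)
        self.ligand_proj = nn.Linear(ligand_dim, LIGAND_PROJ_DIM, rng)
        self.protein_proj = nn.Linear(protein_dim, PROTEIN_PROJ_DIM, rng)
        self.head1 = nn.Linear(JOINT_DIM, hidden, rng)
        self.head2 = nn.Linear(hidden, 1, rng)

    @property
    def joint_dim(self) -> int:
        return JOINT_DIM

    def forward(self, ligand_vecs: np.ndarray, protein_vecs: np.ndarray) -> Tensor:
        lig = self.ligand_proj(Tensor(ligand_vecs)).tanh()
        prot = self.protein_proj(Tensor(protein_vecs)).tanh()
        joint = nn.concatenate([lig, prot], axis=-1)
        return self.head2(self.head1(joint).relu()).reshape(-1)

    def head_parameters(self) -> list[Tensor]:
        return self.head1.parameters() + self.head2.parameters()

    def projection_parameters(self) -> list[Tensor]:
        return self.ligand_proj.parameters() + self.protein_proj.parameters()


def predict_affinity(
    pair: DTIPair,
    model: DTIModel,
    ligand_featurizer: Callable[[MoleculeRecord], np.ndarray],
    proteins: dict[str, np.ndarray],
) -> float:
    """Predict the affinity of one ligand-protein pair."""
    if pair.protein_id not in proteins:
        raise UnknownProteinError(pair.protein_id)
    lig = np.atleast_2d(ligand_featurizer(pair.ligand))
    prot = np.atleast_2d(proteins[pair.protein_id])
    return float(model.forward(lig, prot).data[0])


@dataclass
class DTIFoldMetrics:
    fold: int
    pearson_r: float
    rmse: float
    n_test: int


@dataclass
class DTICrossvalResult:
    folds: list[DTIFoldMetrics]
    mean_pearson_r: float
    mean_rmse: float
    fold_assignments: np.ndarray  # test-fold index per pair

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def _train_model(
    model: DTIModel,
    lig: np.ndarray,
    prot: np.ndarray,
    y: np.ndarray,
    val_idx: np.ndarray,
    train_idx: np.ndarray,
    epochs: int,
    freeze_epochs: int,
    lr: float,
    batch_size: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Staged training: head-only first, then all parameters unfrozen.

    Returns the best state (by validation RMSE) seen during training.
    """
    best_rmse, best_state = np.inf, model.state_dict()
    opt_head = nn.Adam(model.head_parameters(), lr=lr)
    opt_all = nn.Adam(model.parameters(), lr=lr)
    for epoch in range(epochs):
        opt = opt_head if epoch < freeze_epochs else opt_all
        order = rng.permutation(len(train_idx))
        for start in range(0, len(train_idx), batch_size):
            idx = train_idx[order[start : start + batch_size]]
            pred = model.forward(lig[idx], prot[idx])
            loss = nn.mse(pred, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError("DTI training diverged")
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_pred = model.forward(lig[val_idx], prot[val_idx]).data
        val_rmse = float(np.sqrt(np.mean((val_pred - y[val_idx]) ** 2)))
        if val_rmse < best_rmse:
            best_rmse = val_rmse
            best_state = model.state_dict()
    return best_state


def crossval_dti(
    pairs: Sequence[DTIPair],
    proteins: Sequence[ProteinEmbedding] | dict[str, np.ndarray],
    ligand_featurizer: Callable[[MoleculeRecord], np.ndarray],
    epochs: int = 200,
    freeze_epochs: int = 10,
    lr: float = 3e-3,
    batch_size: int = 64,
    seed: int = 0,
) -> DTICrossvalResult:
    """Sixfold cross-validation of the DTI head.

    Pairs are shuffled once and split into six equal folds; in round k,
    fold k is the test set, fold (k+1) mod 6 the validation set and the
    remaining four folds the training set.  Every pair is tested exactly
    once.  Per-fold Pearson r and RMSE are reported along with their
    arithmetic means.
    """
    n = len(pairs)
    if n < 6:
        raise ValueError("need at least 6 pairs for sixfold cross-validation")
    if not isinstance(proteins, dict):
        proteins = {p.id: p.vector for p in proteins}
    lig = np.stack([ligand_featurizer(p.ligand) for p in pairs])
    prot = np.stack([proteins[p.protein_id] for p in pairs])
    y = np.array([p.affinity for p in pairs], dtype=np.float64)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    for k in range(6):
        fold_of[order[k * n // 6 : (k + 1) * n // 6]] = k
    fold_of[order[6 * n // 6 :]] = 5  # remainder (if n % 6) joins the last fold

    folds: list[DTIFoldMetrics] = []
    for k in range(6):
        test_idx = np.flatnonzero(fold_of == k)
        val_idx = np.flatnonzero(fold_of == (k + 1) % 6)
        train_idx = np.flatnonzero((fold_of != k) & (fold_of != (k + 1) % 6))
        model = DTIModel(lig.shape[1], prot.shape[1], seed=seed + 100 + k)
        best_state = _train_model(
            model, lig, prot, y, val_idx, train_idx,
            epochs=epochs, freeze_epochs=freeze_epochs, lr=lr,
            batch_size=batch_size, rng=np.random.default_rng(seed + 200 + k),
        )
        model.load_state_dict(best_state)
        pred = model.forward(lig[test_idx], prot[test_idx]).data
        r = float(stats.pearsonr(pred, y[test_idx]).statistic)
        rmse = float(np.sqrt(np.mean((pred - y[test_idx]) ** 2)))
        folds.append(DTIFoldMetrics(fold=k, pearson_r=r, rmse=rmse, n_test=len(test_idx)))
    return DTICrossvalResult(
        folds=folds,
        mean_pearson_r=float(np.mean([f.pearson_r for f in folds])),
        mean_rmse=float(np.mean([f.rmse for f in folds])),
        fold_assignments=fold_of,
    )


def read_protein_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read a protein-embedding table: CSV with an ``id`` column and one
    numeric column per embedding dimension."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError("protein table needs an 'id' column")
    vec_cols = [c for c in df.columns if c != "id"]
    return {
        str(row["id"]): row[vec_cols].to_numpy(dtype=np.float64)
        for _, row in df.iterrows()
    }


def write_protein_table(proteins: Sequence[ProteinEmbedding], path: str | Path) -> None:
    dim = len(proteins[0].vector)
    df = pd.DataFrame([p.vector for p in proteins], columns=[f"d{i}" for i in range(dim)])
    df.insert(0, "id", [p.id for p in proteins])
    df.to_csv(path, index=False)
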