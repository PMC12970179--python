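"""The three molecular views: token graph, 2D depiction, SMILES token sequence.

Each view is a self-contained featurization of a :class:`~mvmol.chem_io.MoleculeRecord`:

* :func:`featurize_graph` — the heavy-atom molecular graph as a sequence of
  node and edge tokens with five categorical features each, plus spectral
  positional encoding from the combinatorial graph Laplacian
  (:func:`laplacian_pe`).
* :func:`render_image` — a normalized pixel grid of the 2D depiction with
  seeded crop/flip augmentation in train mode and a deterministic 224x224
  central crop in eval mode.
* :func:`tokenize_smiles` — a regex tokenization of the SMILES string whose
  token concatenation reproduces the input exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from rdkit import Chem
from rdkit.Chem import Draw

from mvmol.chem_io import MoleculeRecord

# ---------------------------------------------------------------------------
# Graph view
# ---------------------------------------------------------------------------

# Categorical vocabularies for the five atom and five bond features.  Unknown
# values map to the last index of each table.
ATOMIC_NUMS = list(range(1, 101))
CHIRAL_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.ChiralType.CHI_OTHER,
]
DEGREES = list(range(0, 11))
FORMAL_CHARGES = list(range(-5, 6))
HYBRIDIZATIONS = [
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
    Chem.HybridizationType.UNSPECIFIED,
]
BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
BOND_DIRS = [
    Chem.BondDir.NONE,
    Chem.BondDir.ENDUPRIGHT,
    Chem.BondDir.ENDDOWNRIGHT,
]
BOND_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
]

#: Number of categories per atom feature (+1 for unknown) in featurization order:
#: atomic number, chirality, degree, formal charge, hybridization.
ATOM_FEATURE_SIZES = [
    len(ATOMIC_NUMS) + 1,
    len(CHIRAL_TAGS) + 1,
    len(DEGREES) + 1,
    len(FORMAL_CHARGES) + 1,
    len(HYBRIDIZATIONS) + 1,
]
#: Number of categories per bond feature: bond type, direction, stereo,
#: conjugation flag, in-ring flag.
BOND_FEATURE_SIZES = [
    len(BOND_TYPES) + 1,
    len(BOND_DIRS) + 1,
    len(BOND_STEREO) + 1,
    2,
    2,
]


def _index(table: list, value) -> int:
    try:
        return table.index(value)
    except ValueError:
        return len(table)


@dataclass
class GraphView:
    """Undirected molecular graph as node + edge tokens with spectral PE.

    ``node_features`` is (|V|, 5) and ``edge_features`` (|E|, 5), integer
    categorical indices.  ``edges`` stores each bond once as (i, j) with
    i < j.  After :func:`laplacian_pe`, ``laplacian_eigenvalues`` holds the k
    smallest Laplacian eigenvalues ascending and ``laplacian_eigenvectors``
    the matching eigenvectors as columns of a (|V|, k) matrix (zero-padded
    when |V| < k).
    """

    n_atoms: int
    node_features: np.ndarray
    edges: np.ndarray
    edge_features: np.ndarray
    laplacian_eigenvalues: np.ndarray | None = None
    laplacian_eigenvectors: np.ndarray | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_tokens(self) -> int:
        """Length of the token sequence: one token per atom plus one per bond."""
        return self.n_atoms + self.n_edges


def featurize_graph(record: MoleculeRecord) -> GraphView:
    """Featurize the heavy-atom graph of a molecule as node and edge tokens.

    Hydrogens are implicit.  Each atom carries (atomic number, chirality,
    degree, formal charge, hybridization); each bond carries (bond type,
    bond direction, stereochemistry, conjugated?, in-ring?).  Single-atom
    molecules are valid (zero edges); an empty molecule is rejected.
    """
    mol = record.to_mol()
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError("cannot featurize an empty molecule")

    node_features = np.empty((n, 5), dtype=np.int64)
    for atom in mol.GetAtoms():
        node_features[atom.GetIdx()] = [
            _index(ATOMIC_NUMS, atom.GetAtomicNum()),
            _index(CHIRAL_TAGS, atom.GetChiralTag()),
            _index(DEGREES, atom.GetDegree()),
            _index(FORMAL_CHARGES, atom.GetFormalCharge()),
            _index(HYBRIDIZATIONS, atom.GetHybridization()),
        ]

    edges = np.empty((mol.GetNumBonds(), 2), dtype=np.int64)
    edge_features = np.empty((mol.GetNumBonds(), 5), dtype=np.int64)
    for k, bond in enumerate(mol.GetBonds()):
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges[k] = sorted((i, j))
        edge_features[k] = [
            _index(BOND_TYPES, bond.GetBondType()),
            _index(BOND_DIRS, bond.GetBondDir()),
            _index(BOND_STEREO, bond.GetStereo()),
            int(bond.GetIsConjugated()),
            int(bond.IsInRing()),
        ]
    return GraphView(
        n_atoms=n, node_features=node_features, edges=edges, edge_features=edge_features
    )


def laplacian_pe(view: GraphView, k: int = 8) -> GraphView:
    """Attach the k smallest eigenpairs of the combinatorial graph Laplacian.

    The Laplacian is L = D - A over the undirected heavy-atom graph.  The
    eigenvalue multiset is an isomorphism invariant; eigenvectors give each
    node a spectral coordinate used as positional encoding.  Conventions:
    eigenvalues in stable ascending order; each eigenvector's sign fixed by
    making its first nonzero component positive; zero-padding of both
    eigenvalues and eigenvectors when the graph has fewer than k nodes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = view.n_atoms
    if n == 0:
        raise ValueError("empty graph")
    lap = np.zeros((n, n))
    for i, j in view.edges:
        lap[i, j] -= 1.0
        lap[j, i] -= 1.0
        lap[i, i] += 1.0
        lap[j, j] += 1.0
    eigenvalues, eigenvectors = np.linalg.eigh(lap)
    order = np.argsort(eigenvalues, kind="stable")
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    # Fix sign: first component with magnitude above tolerance made positive.
    for col in range(eigenvectors.shape[1]):
        vec = eigenvectors[:, col]
        nz = np.flatnonzero(np.abs(vec) > 1e-10)
        if len(nz) and vec[nz[0]] < 0:
            eigenvectors[:, col] = -vec

    m = min(k, n)
    vals = np.zeros(k)
    vecs = np.zeros((n, k))
    vals[:m] = eigenvalues[:m]
    vecs[:, :m] = eigenvectors[:, :m]
    return replace(view, laplacian_eigenvalues=vals, laplacian_eigenvectors=vecs)


# ---------------------------------------------------------------------------
# Image view
# ---------------------------------------------------------------------------

RAW_RENDER_SIZE = 256
EVAL_SIZE = 224
#: Per-channel normalization constants (mean, std) on the [0, 1] pixel scale.
#: Molecular depictions are mostly white background, hence means near 1.
IMAGE_NORM_MEAN = (0.95, 0.95, 0.95)
IMAGE_NORM_STD = (0.15, 0.15, 0.15)


class RenderError(RuntimeError):
    """Raised when 2D depiction of a molecule fails."""


@dataclass
class ImageView:
    """Normalized H x W x 3 pixel grid of the molecule's 2D depiction."""

    pixels: np.ndarray
    mode: Literal["train", "eval"]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


def _render_raw(record: MoleculeRecord) -> np.ndarray:
    mol = record.to_mol()
    try:
        img = Draw.MolToImage(mol, size=(RAW_RENDER_SIZE, RAW_RENDER_SIZE))
    except Exception as exc:  # pragma: no cover - rdkit rarely fails here
        raise RenderError(f"depiction failed for {record.canonical_smiles!r}") from exc
    arr = np.asarray(img.convert("RGB"), dtype=np.float64) / 255.0
    if arr.shape != (RAW_RENDER_SIZE, RAW_RENDER_SIZE, 3):  # pragma: no cover
        raise RenderError(f"unexpected render shape {arr.shape}")
    return arr


def _normalize(arr: np.ndarray) -> np.ndarray:
    mean = np.array(IMAGE_NORM_MEAN)
    std = np.array(IMAGE_NORM_STD)
    return (arr - mean) / std


def render_image(
    record: MoleculeRecord,
    mode: Literal["train", "eval"] = "eval",
    seed: int = 0,
    force_flip: bool | None = None,
) -> ImageView:
    """Render the 2D depiction and preprocess it into a normalized pixel grid.

    Eval mode applies a deterministic central crop from the 256x256 raw
    render to 224x224.  Train mode applies a seeded random crop to 224x224
    and a 50% horizontal flip; the same (record, mode, seed) always yields
    bit-identical pixels.  ``force_flip`` overrides the flip coin for tests.
    """
    raw = _render_raw(record)
    margin = RAW_RENDER_SIZE - EVAL_SIZE
    if mode == "eval":
        off = margin // 2
        crop = raw[off : off + EVAL_SIZE, off : off + EVAL_SIZE]
    elif mode == "train":
        rng = np.random.default_rng(seed)
        oy, ox = rng.integers(0, margin + 1, size=2)
        crop = raw[oy : oy + EVAL_SIZE, ox : ox + EVAL_SIZE]
        flip = bool(rng.integers(0, 2)) if force_flip is None else force_flip
        if flip:
            crop = crop[:, ::-1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ImageView(pixels=_normalize(np.ascontiguousarray(crop)), mode=mode)


def image_to_png(view: ImageView, path: str | Path) -> None:
    """Export a rendered view as PNG (denormalized back to [0, 255])."""
    from PIL import Image

    arr = view.pixels * np.array(IMAGE_NORM_STD) + np.array(IMAGE_NORM_MEAN)
    arr = np.clip(arr * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(Path(path))


# ---------------------------------------------------------------------------
# Text view
# ---------------------------------------------------------------------------

#: Regex splitting SMILES into chemically meaningful tokens: bracket atoms,
#: two-letter elements, aromatic atoms, bonds, ring/branch symbols, and
#: two-digit ring closures (%nn).
SMILES_TOKEN_PATTERN = (
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|As|B|C|N|O|P|S|F|I|b|c|n|o|p|s"
    r"|%\d{2}|\d|=|#|\+|-|\(|\)|/|\\|\.|:|~|@|\?|>|\*|\$)"
)
_TOKEN_RE = re.compile(SMILES_TOKEN_PATTERN)

PAD, MASK, UNK, BOS, EOS = "<pad>", "<mask>", "<unk>", "<bos>", "<eos>"
RESERVED_TOKENS = (PAD, MASK, UNK, BOS, EOS)

#: Frozen seed vocabulary of common organic-chemistry tokens; corpus-derived
#: tokens are appended after these so ids are stable across datasets.
SEED_VOCAB = (
    "C", "c", "N", "n", "O", "o", "S", "s", "P", "p", "F", "Cl", "Br", "I", "B",
    "[nH]", "[N+]", "[O-]", "[NH+]", "[NH2+]", "[NH3+]", "[C@H]", "[C@@H]",
    "1", "2", "3", "4", "5", "6", "7", "8", "9",
    "=", "#", "-", "+", "(", ")", "/", "\\", ".", ":",
)


class Vocabulary:
    """Token <-> id map with reserved pad/mask/unknown/begin/end tokens."""

    def __init__(self, tokens: list[str] | None = None):
        self._tokens: list[str] = list(RESERVED_TOKENS) + list(SEED_VOCAB)
        self._ids: dict[str, int] = {t: i for i, t in enumerate(self._tokens)}
        if tokens:
            self.add_tokens(tokens)

    def add_tokens(self, tokens: list[str]) -> None:
        for t in tokens:
            if t not in self._ids:
                self._ids[t] = len(self._tokens)
                self._tokens.append(t)

    def __len__(self) -> int:
        return len(self._tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._ids

    def id_of(self, token: str) -> int:
        return self._ids.get(token, self._ids[UNK])

    def token_of(self, idx: int) -> str:
        return self._tokens[idx]

    @property
    def pad_id(self) -> int:
        return self._ids[PAD]

    @property
    def mask_id(self) -> int:
        return self._ids[MASK]

    @property
    def unk_id(self) -> int:
        return self._ids[UNK]

    @property
    def reserved_ids(self) -> frozenset[int]:
        return frozenset(self._ids[t] for t in RESERVED_TOKENS)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self._tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        tokens = Path(path).read_text().splitlines()
        vocab = cls.__new__(cls)
        vocab._tokens = tokens
        vocab._ids = {t: i for i, t in enumerate(tokens)}
        return vocab


DEFAULT_VOCAB = Vocabulary()


@dataclass
class TextView:
    """SMILES token sequence: surface tokens plus ids under a vocabulary."""

    tokens: list[str]
    token_ids: list[int]
    vocabulary: Vocabulary = field(repr=False, default=DEFAULT_VOCAB)

    def detokenize(self) -> str:
        return "".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def _split_smiles(smiles: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    for match in _TOKEN_RE.finditer(smiles):
        if match.start() > pos:
            tokens.extend(smiles[pos : match.start()])
        tokens.append(match.group())
        pos = match.end()
    tokens.extend(smiles[pos:])
    return tokens


def tokenize_smiles(smiles: str, vocabulary: Vocabulary | None = None) -> TextView:
    """Split a SMILES string into chemical tokens via the regex tokenizer.

    The concatenation of the emitted surface tokens always equals the input
    string: characters the pattern does not recognize become single-character
    tokens mapped to the unknown id (with a warning), never silently dropped.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    vocab = vocabulary if vocabulary is not None else DEFAULT_VOCAB
    tokens = _split_smiles(smiles)
    ids = []
    for t in tokens:
        if t not in vocab:
            import warnings

            warnings.warn(f"unknown SMILES token {t!r} mapped to {UNK}", stacklevel=2)
        ids.append(vocab.id_of(t))
    return TextView(tokens=tokens, token_ids=ids, vocabulary=vocab)


def build_vocabulary(smiles_list: list[str]) -> Vocabulary:
    """Build a vocabulary covering a corpus on top of the frozen seed tokens."""
    vocab = Vocabulary()
    for smi in smiles_list:
        vocab.add_tokens(_split_smiles(smi))
    return vocab
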