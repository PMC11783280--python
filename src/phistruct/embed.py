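"""Fixed-length protein embeddings.

The downstream classifier consumes one fixed-length vector per protein,
obtained by mean-pooling a language model's per-residue hidden states over
the sequence length (1280 dimensions for the structure-aware model this
toolkit is built around).  Running such a model is out of scope here: the
embedder is a narrow contract — structure-aware tokens in, one vector out —
so a real model adapter can be dropped in by users, and a deterministic
synthetic embedder stands behind the contract for testing and simulation.

The synthetic embedder places each host genus at a fixed center in embedding
space, adds per-protein Gaussian noise seeded from (global seed, stable hash
of the protein id) so records embed identically regardless of processing
order, and shifts the vector in proportion to the fraction of masked tokens
so that masking strategies measurably move embeddings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import FormatError
from .structok import StructureAwareSequence

__all__ = [
    "EmbeddedDataset",
    "SyntheticEmbedder",
    "mean_pool",
    "read_embeddings",
    "write_embeddings",
]

OUTGROUP_LABEL = "OUTGROUP"


def mean_pool(per_residue: np.ndarray) -> np.ndarray:
    """Column-wise mean of an n x L per-residue matrix (n >= 1)."""
    arr = np.asarray(per_residue, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError(f"expected a non-empty 2-D matrix, got shape {arr.shape}")
    return arr.mean(axis=0)


@dataclass
class EmbeddedDataset:
    """n proteins x L embedding dimensions, with labels and provenance."""

    ids: list[str]
    labels: list[str]
    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if len(self.labels) != n or self.matrix.shape[0] != n:
            raise ValueError(
                f"row mismatch: {n} ids, {len(self.labels)} labels, "
                f"{self.matrix.shape[0]} matrix rows"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in dataset")
        if n and not np.isfinite(self.matrix).all():
            raise ValueError("non-finite embedding entries")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1]) if self.matrix.ndim == 2 else 0

    def subset(self, ids: list[str]) -> "EmbeddedDataset":
        index = {i: k for k, i in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return EmbeddedDataset(
            ids=list(ids),
            labels=[self.labels[r] for r in rows],
            matrix=self.matrix[rows],
            provenance=dict(self.provenance),
        )


def _stable_hash(text: str) -> int:
    # crc32 is stable across processes (unlike Python's salted hash())
    return zlib.crc32(text.encode("utf-8"))


class SyntheticEmbedder(BaseEstimator):
    """Deterministic genus-conditional Gaussian embedder (model stand-in).

    Parameters
    ----------
    classes : ordered list of genus labels; the outgroup label may be
        included and gets its own center.
    dim : embedding length L (1280 mirrors the real model's hidden size).
    center_separation : typical Euclidean distance between genus centers.
    sigma : within-genus spread around the center.
    mask_sensitivity : magnitude of the shift applied per unit masked-token
        fraction, along a fixed direction, so masking visibly perturbs
        embeddings.
    seed : global seed; combined with a stable per-id hash so embeddings are
        order-independent.
    """

    def __init__(
        self,
        classes=(),
        dim: int = 1280,
        center_separation: float = 10.0,
        sigma: float = 1.0,
        mask_sensitivity: float = 1.0,
        seed: int = 0,
    ):
        self.classes = classes
        self.dim = dim
        self.center_separation = center_separation
        self.sigma = sigma
        self.mask_sensitivity = mask_sensitivity
        self.seed = seed

    def fit(self, X=None, y=None) -> "SyntheticEmbedder":
        """Materialize class centers and the mask-shift direction."""
        if not self.classes:
            raise ValueError("no classes configured")
        rng = np.random.default_rng(np.uint32(self.seed))
        centers = {}
        for label in self.classes:
            direction = rng.standard_normal(self.dim)
            direction /= np.linalg.norm(direction)
            # random unit directions in high dimension are near-orthogonal, so
            # scaling by d/sqrt(2) puts pairwise center distances near d
            centers[label] = direction * (self.center_separation / np.sqrt(2.0))
        self.centers_ = centers
        shift = rng.standard_normal(self.dim)
        self.mask_direction_ = shift / np.linalg.norm(shift)
        return self

    def embed(
        self, protein_id: str, seq: StructureAwareSequence | None, label: str
    ) -> np.ndarray:
        """Embed one protein; deterministic in (id, seq, label, params, seed)."""
        if not hasattr(self, "centers_"):
            self.fit()
        if label not in self.centers_:
            raise KeyError(f"unknown label {label!r}")
        rng = np.random.default_rng([np.uint32(self.seed), _stable_hash(protein_id)])
        vec = self.centers_[label] + self.sigma * rng.standard_normal(self.dim)
        if seq is not None:
            vec = vec + self.mask_sensitivity * seq.masked_fraction() * self.mask_direction_
        return vec

    def transform(self, records) -> EmbeddedDataset:
        """Embed (id, seq-or-None, label) triples into an EmbeddedDataset."""
        ids, labels, rows = [], [], []
        for pid, seq, label in records:
            ids.append(pid)
            labels.append(label)
            rows.append(self.embed(pid, seq, label))
        matrix = np.vstack(rows) if rows else np.empty((0, self.dim))
        return EmbeddedDataset(
            ids=ids,
            labels=labels,
            matrix=matrix,
            provenance={
                "embedder": "synthetic",
                "seed": self.seed,
                "dim": self.dim,
                "center_separation": self.center_separation,
                "sigma": self.sigma,
            },
        )


def write_embeddings(dataset: EmbeddedDataset, path) -> None:
    """Write the documented TSV layout: id, label, e0..e{L-1}."""
    cols = [f"e{i}" for i in range(dataset.dim)]
    df = pd.DataFrame(dataset.matrix, columns=cols)
    df.insert(0, "label", dataset.labels)
    df.insert(0, "id", dataset.ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_embeddings(path) -> EmbeddedDataset:
    """Read the TSV layout back; an empty file yields an empty dataset."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "label": str})
    except pd.errors.EmptyDataError:
        return EmbeddedDataset(ids=[], labels=[], matrix=np.empty((0, 0)))
    if list(df.columns[:2]) != ["id", "label"]:
        raise FormatError(f"{path}: expected leading columns 'id', 'label'")
    if "synthetic" in df.columns:  # flag column added by the balance stage
        df = df.drop(columns=["synthetic"])
    matrix = df.iloc[:, 2:].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(matrix).all(axis=1))[0]
    if bad.size:
        raise FormatError(f"{path}: non-numeric or missing values at row {bad[0] + 1}")
    return EmbeddedDataset(
        ids=df["id"].tolist(), labels=df["label"].tolist(), matrix=matrix
    )
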