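"""Fusion of local (atom/bond) and global (descriptor) features.

The aggregation scheme turns variable-size per-molecule matrices into a
fixed-length vector: each molecule's atomic and bond matrices are transposed
(rows = the fixed feature axis, columns = atoms or bonds) and projected onto
their first principal component, yielding a 145-long atomic part and a
12-long bond part — 157 local features per molecule regardless of size.
A dataset-level PCA then compresses the m x 157 local block to 50 scores,
molecular descriptors are z-scored, and the two blocks are concatenated with
zero-variance columns dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .featurization import (
    ATOM_FEATURE_WIDTH,
    BOND_FEATURE_WIDTH,
    AtomFeatureMatrix,
    BondFeatureMatrix,
)

__all__ = [
    "LOCAL_FEATURE_LENGTH",
    "FeatureTable",
    "first_pc_scores",
    "aggregate_local",
    "reduce_local_dataset",
    "zscore_columns",
    "assemble_feature_table",
]

#: length of the aggregated local vector (atomic part + bond part)
LOCAL_FEATURE_LENGTH = ATOM_FEATURE_WIDTH + BOND_FEATURE_WIDTH

# variance below this (after scaling) counts as "zero variance"
_ZERO_VAR_TOL = 1e-12


@dataclass
class FeatureTable:
    """The m x p fused feature matrix fed to embedding and clustering.

    ``provenance`` flags each column as ``"local"`` (aggregated-PC score) or
    ``"global"`` (z-scored descriptor).
    """

    values: np.ndarray
    column_labels: list[str]
    provenance: list[str]
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def first_pc_scores(matrix: np.ndarray) -> np.ndarray:
    """Scores of the rows of *matrix* on its first principal component.

    Columns are the variables (centered, never scaled); rows are the
    observations whose PC1 scores are returned.  The sign is fixed so that
    the loading with the largest absolute value is positive.  Degenerate
    cases: a single column returns that column centered; a matrix with zero
    total variance returns the zero vector.

    Parameters
    ----------
    matrix : (r, c) array
        For per-molecule aggregation the caller passes the *transposed*
        feature matrix: rows = the fixed 145/12-long feature axis,
        columns = atoms or bonds.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.size == 0:
        raise ValueError("first_pc_scores requires a non-empty 2-D matrix")
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    if matrix.shape[1] == 1:
        return centered[:, 0]
    cov = (centered.T @ centered) / matrix.shape[0]
    if np.trace(cov) < _ZERO_VAR_TOL:
        return np.zeros(matrix.shape[0])
    eigvals, eigvecs = np.linalg.eigh(cov)
    pc1 = eigvecs[:, -1]  # eigh returns ascending eigenvalues
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    return centered @ pc1


def aggregate_local(atoms: AtomFeatureMatrix, bonds: BondFeatureMatrix) -> np.ndarray:
    """Fixed-length (157) local vector: PC1 scores of the transposed matrices.

    Molecules without bonds contribute a zero vector for the bond part.
    """
    if atoms.values.shape[0] < 1:
        raise ValueError("molecule must have at least one atom")
    atom_part = first_pc_scores(atoms.values.T)
    if bonds.values.shape[0] == 0:
        bond_part = np.zeros(BOND_FEATURE_WIDTH)
    else:
        bond_part = first_pc_scores(bonds.values.T)
    return np.concatenate([atom_part, bond_part])


def reduce_local_dataset(
    local: np.ndarray, n_components: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Dataset-level PCA of the m x 157 aggregated-local matrix.

    Returns the molecules' scores on the top ``n_components`` principal
    components (columns centered, not scaled) and the explained-variance
    ratios, ordered by decreasing variance.
    """
    local = np.asarray(local, dtype=float)
    m = local.shape[0]
    if m < n_components:
        raise ValueError(
            f"n_components={n_components} exceeds the number of molecules "
            f"({m}); choose n_components <= {m}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(local)
    return scores, pca.explained_variance_ratio_


def zscore_columns(global_: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Z-score each column (population SD); constant columns become all-zero.

    Returns the transformed matrix and the indices of constant columns so
    the assembly step can drop them.
    """
    global_ = np.asarray(global_, dtype=float)
    if global_.shape[0] < 2:
        raise ValueError("z-scoring needs at least two rows")
    mean = global_.mean(axis=0)
    sd = global_.std(axis=0)  # population convention (divide by n)
    constant = np.flatnonzero(sd < _ZERO_VAR_TOL * np.maximum(1.0, np.abs(mean)))
    safe_sd = sd.copy()
    safe_sd[constant] = 1.0
    z = (global_ - mean) / safe_sd
    z[:, constant] = 0.0
    return z, constant.tolist()


def assemble_feature_table(
    local_reduced: np.ndarray,
    global_z: np.ndarray,
    global_names: list[str] | tuple[str, ...] | None = None,
) -> FeatureTable:
    """Concatenate local PC scores with z-scored descriptors and drop
    zero-variance columns.

    Column labels follow the "PCA 1..n" convention for the local block and
    the descriptor names for the global block.
    """
    local_reduced = np.asarray(local_reduced, dtype=float)
    global_z = np.asarray(global_z, dtype=float)
    if local_reduced.shape[0] != global_z.shape[0]:
        raise ValueError(
            f"row mismatch: local has {local_reduced.shape[0]} molecules, "
            f"global has {global_z.shape[0]}"
        )
    n_local = local_reduced.shape[1]
    if global_names is None:
        global_names = [f"desc_{i + 1}" for i in range(global_z.shape[1])]
    labels = [f"PCA {i + 1}" for i in range(n_local)] + list(global_names)
    provenance = ["local"] * n_local + ["global"] * global_z.shape[1]
    values = np.hstack([local_reduced, global_z])

    sd = values.std(axis=0)
    keep = sd >= _ZERO_VAR_TOL
    dropped = [labels[i] for i in np.flatnonzero(~keep)]
    return FeatureTable(
        values=values[:, keep],
        column_labels=[l for l, k in zip(labels, keep) if k],
        provenance=[p for p, k in zip(provenance, keep) if k],
        dropped_columns=dropped,
    )
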