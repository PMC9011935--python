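"""Synthetic inputs for exercising the whole pipeline offline.

Two generators: drug-like SMILES assembled from a curated fragment grammar
(guaranteed to parse, covering the featurizer's degenerate cases down to a
single-atom molecule), and Gaussian mixtures with planted cluster structure
for clustering-recovery tests.  Every generator is a pure function of its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

__all__ = ["MixtureSpec", "fixture_smiles", "gaussian_mixture", "write_smi"]

# mandatory degenerate molecules: 1 atom / 2 atoms, 1 bond / 3 atoms, 2 bonds
_EDGE_CASES = [("EDGE1", "O"), ("EDGE2", "CO"), ("EDGE3", "CCO")]

# fragment grammar: scaffold templates with one substitution site each.
# Motifs: alkyl chains, aromatic rings, carboxylates, sulfonamides,
# aryl halides, plus assorted heterocycles for variety.
_SCAFFOLDS = [
    "c1ccc({sub})cc1",          # monosubstituted benzene
    "c1ccc2ccccc2c1",           # naphthalene (no site)
    "c1ccncc1",                 # pyridine (no site)
    "c1ccc(-c2ccccc2{sub})cc1",  # biphenyl
    "C1CCC({sub})CC1",          # cyclohexane
    "c1ccc2[nH]ccc2c1",         # indole (no site)
    "C1CCN({sub})CC1",          # N-substituted piperidine
    "c1ccsc1",                  # thiophene (no site)
]

_SUBSTITUENTS = [
    "C",
    "CC",
    "CCC",
    "CC(C)C",
    "C(=O)O",      # carboxylate
    "C(=O)OC",     # ester
    "C(=O)N",      # amide
    "S(=O)(=O)N",  # sulfonamide
    "S(=O)(=O)NC", # N-methyl sulfonamide
    "F",
    "Cl",
    "Br",          # aryl halides
    "O",
    "OC",
    "N",
    "N(C)C",
    "C#N",
    "[N+](=O)[O-]",
    "C(F)(F)F",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Planted Gaussian-mixture conditions for clustering tests."""

    n: int
    dim: int
    k_true: int
    #: centroid spacing in units of the within-cluster radial SD (the RMS
    #: point-to-centroid distance, sqrt(dim) for unit per-coordinate SD).
    #: Measuring spacing against the cluster radius keeps the contrast of a
    #: given separation independent of the dimensionality.
    separation: float
    seed: int = 0

    def __post_init__(self):
        if not self.n >= self.k_true >= 1:
            raise ValueError("need n >= k_true >= 1")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.dim < 1:
            raise ValueError("dim must be positive")


def fixture_smiles(n: int, seed: int = 0) -> list[tuple[str, str]]:
    """n valid (id, SMILES) pairs from the fragment grammar.

    The first three entries are always the degenerate trio (1-atom,
    2-atom/1-bond, 3-atom/2-bond molecules); the rest are scaffold +
    substituent combinations.  Deterministic per seed; every output
    re-parses.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = list(_EDGE_CASES[:n])
    i = len(out)
    while len(out) < n:
        scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
        if "{sub}" in scaffold:
            smiles = scaffold.format(sub=_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))])
        else:
            smiles = scaffold
        mol = Chem.MolFromSmiles(smiles)
        assert mol is not None, f"grammar produced invalid SMILES {smiles!r}"
        out.append((f"SYN{i:05d}", Chem.MolToSmiles(mol)))
        i += 1
    return out


def gaussian_mixture(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic unit-SD Gaussian blobs with planted labels.

    Centroid spacing is ``spec.separation`` times the cluster radial SD
    (sqrt(dim) for unit per-coordinate SD), so a given separation produces
    the same cluster contrast at any dimensionality.

    For k <= dim the centroids sit on a regular simplex, so every
    pairwise distance equals the spacing and the planted k is
    unambiguous; for larger k, sampled directions are rescaled so the
    minimum pairwise distance equals the separation.  Separation 0 makes
    all blobs coincide.  Cluster sizes are balanced to within one point.
    """
    rng = np.random.default_rng(spec.seed)
    k, dim = spec.k_true, spec.dim
    spacing = spec.separation * np.sqrt(dim)  # radial-SD units -> coordinates
    if k == 1 or spec.separation == 0:
        centroids = np.zeros((k, dim))
    elif k <= dim:
        # regular simplex: rows of (s/sqrt(2)) * I_k, centered, embedded in dim
        simplex = np.zeros((k, dim))
        simplex[:, :k] = np.eye(k) * (spacing / np.sqrt(2.0))
        centroids = simplex - simplex.mean(axis=0)
    else:
        centroids = rng.standard_normal((k, dim))
        centroids -= centroids.mean(axis=0)
        diffs = centroids[:, None, :] - centroids[None, :, :]
        d = np.linalg.norm(diffs, axis=-1)
        min_d = d[~np.eye(k, dtype=bool)].min()
        if min_d < 1e-9:
            raise ValueError(
                f"cannot place {k} centroids at separation {spec.separation} "
                f"in {dim} dimensions (sampled directions collide)"
            )
        centroids *= spacing / min_d
    labels = np.arange(spec.n) % k
    rng.shuffle(labels)
    X = centroids[labels] + rng.standard_normal((spec.n, dim))
    return X, labels


def write_smi(records: list[tuple[str, str]], path: str | Path) -> Path:
    """Write (id, SMILES) pairs as a .smi file ('SMILES<TAB>id' per line),
    the same dialect the pipeline reads."""
    path = Path(path)
    with path.open("w") as fh:
        for mol_id, smiles in records:
            fh.write(f"{smiles}\t{mol_id}\n")
    return path
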