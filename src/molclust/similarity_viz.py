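"""Fingerprint similarity and qualitative cluster visualizations.

Covers the structural side of cluster inspection: extended-connectivity
(Morgan) fingerprints with atom provenance, Tanimoto similarity (binary and
count variants), pairwise similarity matrices with cluster-block outlines,
per-atom similarity maps, and a t-SNE scatter of the learned embeddings.

An atom's similarity-map weight is the drop in Tanimoto similarity to the
reference molecule when every fingerprint bit whose circular environment
contains that atom is removed from the test molecule's fingerprint; positive
weights mark substructures that increase the similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .featurization import MoleculeRecord

__all__ = [
    "Fingerprint",
    "SimilarityMapResult",
    "ecfp",
    "tanimoto",
    "tanimoto_matrix",
    "similarity_map_weights",
    "tsne_2d",
    "plot_tanimoto_heatmap",
    "plot_tsne",
    "render_similarity_map",
]


@dataclass(frozen=True)
class Fingerprint:
    """A folded circular fingerprint with per-bit atom provenance.

    ``values`` maps set bits to counts (all 1 for the binary kind);
    ``bit_atom_map`` maps each bit to the indices of every atom appearing in
    any circular environment hashed into that bit.
    """

    kind: str  # "binary" | "count"
    radius: int
    n_bits: int
    values: dict[int, int]
    bit_atom_map: dict[int, frozenset[int]]

    def compatible(self, other: "Fingerprint") -> bool:
        return (
            self.kind == other.kind
            and self.radius == other.radius
            and self.n_bits == other.n_bits
        )


@dataclass(frozen=True)
class SimilarityMapResult:
    reference_id: str
    test_id: str
    similarity: float
    atom_weights: np.ndarray  # normalized so max |weight| = 1 (if any nonzero)


def _env_atoms(mol: Chem.Mol, center: int, radius: int) -> frozenset[int]:
    if radius == 0:
        return frozenset([center])
    env = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    amap: dict[int, int] = {}
    Chem.PathToSubmol(mol, env, atomMap=amap)
    return frozenset(amap.keys())


def ecfp(
    mol: MoleculeRecord | Chem.Mol,
    radius: int = 2,
    n_bits: int = 2048,
    counted: bool = True,
) -> Fingerprint:
    """Folded Morgan/ECFP fingerprint with atom provenance retained."""
    rdmol = mol.mol if isinstance(mol, MoleculeRecord) else mol
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    if counted:
        fp = gen.GetCountFingerprint(rdmol, additionalOutput=ao)
        values = {int(b): int(c) for b, c in fp.GetNonzeroElements().items()}
    else:
        fp = gen.GetFingerprint(rdmol, additionalOutput=ao)
        values = {int(b): 1 for b in fp.GetOnBits()}
    bit_atom_map: dict[int, frozenset[int]] = {}
    for bit, envs in ao.GetBitInfoMap().items():
        atoms: set[int] = set()
        for center, rad in envs:
            atoms |= _env_atoms(rdmol, center, rad)
        bit_atom_map[int(bit)] = frozenset(atoms)
    return Fingerprint(
        kind="count" if counted else "binary",
        radius=radius,
        n_bits=n_bits,
        values=values,
        bit_atom_map=bit_atom_map,
    )


def tanimoto(a: Fingerprint | dict[int, int], b: Fingerprint | dict[int, int]) -> float:
    """Tanimoto similarity: |A∩B|/|A∪B| (binary) or Σmin/Σmax (counts).

    Two empty fingerprints compare as 0 (with a warning) rather than 0/0.
    """
    if isinstance(a, Fingerprint) and isinstance(b, Fingerprint):
        if not a.compatible(b):
            raise ValueError("fingerprints differ in kind, radius or n_bits")
        va, vb = a.values, b.values
    else:
        va = a.values if isinstance(a, Fingerprint) else a
        vb = b.values if isinstance(b, Fingerprint) else b
    keys = va.keys() | vb.keys()
    if not keys:
        import warnings

        warnings.warn("both fingerprints empty; similarity defined as 0", stacklevel=2)
        return 0.0
    num = sum(min(va.get(k, 0), vb.get(k, 0)) for k in keys)
    den = sum(max(va.get(k, 0), vb.get(k, 0)) for k in keys)
    return num / den


def tanimoto_matrix(
    mols: list[MoleculeRecord],
    radius: int = 1,
    n_bits: int = 2048,
    counted: bool = False,
) -> np.ndarray:
    """Symmetric pairwise Tanimoto matrix (binary ECFP radius 1 by default)."""
    fps = [ecfp(m, radius=radius, n_bits=n_bits, counted=counted) for m in mols]
    n = len(fps)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = tanimoto(fps[i], fps[j])
    return mat


def similarity_map_weights(
    ref: MoleculeRecord,
    test: MoleculeRecord,
    radius: int = 2,
    n_bits: int = 2048,
    counted: bool = True,
) -> SimilarityMapResult:
    """Per-atom contributions of the test molecule to its reference similarity.

    weight(atom) = sim(ref, test) - sim(ref, test without the atom's bits);
    weights are normalized to max |weight| = 1 before rendering.
    """
    fp_ref = ecfp(ref, radius=radius, n_bits=n_bits, counted=counted)
    fp_test = ecfp(test, radius=radius, n_bits=n_bits, counted=counted)
    base = tanimoto(fp_ref, fp_test)
    weights = np.zeros(test.n_atoms)
    for atom in range(test.n_atoms):
        reduced = {
            b: c
            for b, c in fp_test.values.items()
            if atom not in fp_test.bit_atom_map.get(b, frozenset())
        }
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # reduced fp may be empty
            weights[atom] = base - tanimoto(fp_ref.values, reduced)
    peak = np.max(np.abs(weights))
    if peak > 0:
        weights = weights / peak
    return SimilarityMapResult(
        reference_id=ref.id, test_id=test.id, similarity=base, atom_weights=weights
    )


def tsne_2d(
    embedding: np.ndarray, perplexity: float = 30.0, seed: int = 0
) -> np.ndarray:
    """2-D t-SNE coordinates of the embedding rows (seeded, PCA init)."""
    from sklearn.manifold import TSNE

    embedding = np.asarray(embedding, dtype=float)
    m = embedding.shape[0]
    if m <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {m} points; "
            f"use perplexity < {m / 3:.0f}"
        )
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    return tsne.fit_transform(embedding)


# ---------------------------------------------------------------------------
# rendering helpers (images are not test surfaces)


def plot_tanimoto_heatmap(
    mat: np.ndarray,
    path,
    labels: list[str] | None = None,
    cluster_blocks: list[tuple[int, int]] | None = None,
) -> None:
    """Heatmap of a pairwise similarity matrix; ``cluster_blocks`` are
    (start, stop) index ranges outlined to mark same-cluster groups."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, cmap="Blues", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="Tanimoto similarity")
    if labels is not None:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
        ax.set_yticks(range(len(labels)), labels, fontsize=6)
    for start, stop in cluster_blocks or []:
        size = stop - start
        ax.add_patch(
            plt.Rectangle((start - 0.5, start - 0.5), size, size,
                          fill=False, edgecolor="orange", linewidth=1.5)
        )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tsne(coords: np.ndarray, labels: np.ndarray, path) -> None:
    """Scatter of t-SNE coordinates colored by cluster, cluster ids annotated
    at cluster medians."""
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(coords[:, 0], coords[:, 1], c=labels, cmap="tab20", s=6, alpha=0.7)
    for c in np.unique(labels):
        cx, cy = np.median(coords[labels == c], axis=0)
        ax.annotate(str(c), (cx, cy), fontsize=8, weight="bold")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_similarity_map(
    result: SimilarityMapResult, test: MoleculeRecord, path
) -> None:
    """Colored-structure rendering of the atom weights (green positive,
    red negative), via RDKit's similarity-map drawer."""
    from rdkit.Chem.Draw import SimilarityMaps, rdMolDraw2D

    path = str(path)
    drawer = (
        rdMolDraw2D.MolDraw2DSVG(350, 350)
        if path.endswith(".svg")
        else rdMolDraw2D.MolDraw2DCairo(350, 350)
    )
    if test.n_atoms >= 2:
        SimilarityMaps.GetSimilarityMapFromWeights(
            test.mol, list(result.atom_weights), draw2d=drawer
        )
    else:  # a weight contour needs >= 2 atoms; draw the bare structure
        rdMolDraw2D.PrepareAndDrawMolecule(drawer, test.mol)
    drawer.FinishDrawing()
    mode = "w" if path.endswith(".svg") else "wb"
    with open(path, mode) as fh:
        fh.write(drawer.GetDrawingText())
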