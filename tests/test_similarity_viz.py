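"""Fingerprints, Tanimoto similarity, similarity-map weights, t-SNE."""

import numpy as np
import pytest
from rdkit import Chem

from molclust.featurization import parse_smiles
from molclust.similarity_viz import (
    Fingerprint,
    ecfp,
    similarity_map_weights,
    tanimoto,
    tanimoto_matrix,
    tsne_2d,
)


def make_fp(values, kind="binary", radius=1, n_bits=2048):
    return Fingerprint(
        kind=kind, radius=radius, n_bits=n_bits, values=values, bit_atom_map={}
    )


class TestFingerprint:
    def test_identical_molecules_identical_fps(self):
        a = ecfp(parse_smiles("c1ccccc1C(=O)O", "a"))
        b = ecfp(parse_smiles("OC(=O)c1ccccc1", "b"))  # same molecule
        assert a.values == b.values

    def test_radius_zero_depends_only_on_atom_identity(self):
        # benzene: six equivalent aromatic carbons -> one distinct bit
        fp = ecfp(parse_smiles("c1ccccc1", "bz"), radius=0)
        assert len(fp.values) == 1
        assert sum(fp.values.values()) == 6
        # butane: only terminal CH3 and inner CH2 environments
        fp2 = ecfp(parse_smiles("CCCC", "bu"), radius=0)
        assert len(fp2.values) == 2

    def test_benzene_binary_sparsity(self):
        fp = ecfp(parse_smiles("c1ccccc1", "bz"), radius=2, counted=False)
        assert 1 <= len(fp.values) < 100

    def test_bit_atom_map_covers_all_bits(self):
        rec = parse_smiles("CC(=O)Nc1ccc(O)cc1", "apap")
        fp = ecfp(rec, radius=2)
        assert set(fp.values) == set(fp.bit_atom_map)
        for atoms in fp.bit_atom_map.values():
            assert all(0 <= a < rec.n_atoms for a in atoms)


class TestTanimoto:
    def test_identity(self):
        fp = ecfp(parse_smiles("CCO", "e"))
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint(self):
        assert tanimoto(make_fp({1: 1, 2: 1}), make_fp({3: 1, 4: 1})) == 0.0

    def test_half_overlap(self):
        a = make_fp({1: 1, 2: 1, 3: 1})
        b = make_fp({2: 1, 3: 1, 4: 1})
        assert tanimoto(a, b) == 0.5

    def test_count_variant_min_over_max(self):
        a = make_fp({1: 3, 2: 1}, kind="count")
        b = make_fp({1: 1, 3: 2}, kind="count")
        # min: 1, max: 3 + 1 + 2
        assert tanimoto(a, b) == pytest.approx(1 / 6)

    def test_mismatched_parameters_rejected(self):
        a = ecfp(parse_smiles("CCO", "e"), radius=1)
        b = ecfp(parse_smiles("CCO", "e"), radius=2)
        with pytest.raises(ValueError):
            tanimoto(a, b)

    def test_both_empty_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert tanimoto(make_fp({}), make_fp({})) == 0.0

    def test_symmetry_and_bounds(self):
        mols = [parse_smiles(s, s) for s in ["CCO", "c1ccccc1", "CC(=O)O", "CCN"]]
        fps = [ecfp(m) for m in mols]
        for i in range(4):
            for j in range(4):
                t = tanimoto(fps[i], fps[j])
                assert 0.0 <= t <= 1.0
                assert t == tanimoto(fps[j], fps[i])
                if i == j:
                    assert t == 1.0


from hypothesis import given, settings
from hypothesis import strategies as st

count_maps = st.dictionaries(
    st.integers(min_value=0, max_value=63),
    st.integers(min_value=1, max_value=5),
    max_size=12,
)


@settings(derandomize=True, max_examples=200)
@given(a=count_maps, b=count_maps)
def test_tanimoto_properties_fuzz(a, b):
    """Count-Tanimoto is symmetric, bounded in [0,1], 1 on identical
    non-empty maps, and 0 iff the supports are disjoint."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = tanimoto(a, b)
        assert 0.0 <= t <= 1.0
        assert t == tanimoto(b, a)
        if a:
            assert tanimoto(a, a) == 1.0
        if not (a.keys() & b.keys()):
            assert t == 0.0
        else:
            assert t > 0.0


class TestTanimotoMatrix:
    def test_matrix_properties(self):
        mols = [
            parse_smiles(s, s)
            for s in ["CCO", "CCO", "c1ccccc1", "CC(=O)Nc1ccccc1"]
        ]
        mat = tanimoto_matrix(mols)
        np.testing.assert_array_equal(np.diag(mat), np.ones(4))
        np.testing.assert_array_equal(mat, mat.T)
        # duplicate molecules produce identical rows
        np.testing.assert_array_equal(mat[0], mat[1])


def naive_atom_weights(ref, test, radius=2, n_bits=2048):
    """Independent recomputation of the per-atom bit-removal definition,
    building its own environment->atom map from RDKit primitives."""
    from rdkit.Chem import rdFingerprintGenerator

    def fp_and_bitatoms(mol):
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitInfoMap()
        counts = dict(gen.GetCountFingerprint(mol, additionalOutput=ao).GetNonzeroElements())
        bit_atoms = {}
        for bit, envs in ao.GetBitInfoMap().items():
            atoms = set()
            for center, rad in envs:
                if rad == 0:
                    atoms.add(center)
                else:
                    env = Chem.FindAtomEnvironmentOfRadiusN(mol, rad, center)
                    amap = {}
                    Chem.PathToSubmol(mol, env, atomMap=amap)
                    atoms |= set(amap)
            bit_atoms[bit] = atoms
        return counts, bit_atoms

    def sim(ca, cb):
        keys = set(ca) | set(cb)
        if not keys:
            return 0.0
        return sum(min(ca.get(k, 0), cb.get(k, 0)) for k in keys) / sum(
            max(ca.get(k, 0), cb.get(k, 0)) for k in keys
        )

    c_ref, _ = fp_and_bitatoms(ref.mol)
    c_test, bit_atoms = fp_and_bitatoms(test.mol)
    base = sim(c_ref, c_test)
    w = []
    for atom in range(test.n_atoms):
        kept = {b: c for b, c in c_test.items() if atom not in bit_atoms.get(b, set())}
        w.append(base - sim(c_ref, kept))
    w = np.array(w)
    peak = np.max(np.abs(w))
    return w / peak if peak > 0 else w


class TestSimilarityMap:
    def test_self_similarity_weights_nonnegative(self):
        rec = parse_smiles("CC(=O)Nc1ccc(O)cc1", "apap")
        result = similarity_map_weights(rec, rec)
        assert result.similarity == 1.0
        assert np.all(result.atom_weights >= 0)

    def test_unshared_substructure_weights_nonpositive(self):
        # ref benzene vs toluene: the methyl carbon shares no environment
        ref = parse_smiles("c1ccccc1", "bz")
        test = parse_smiles("Cc1ccccc1", "tol")
        result = similarity_map_weights(ref, test)
        methyl = next(
            a.GetIdx() for a in test.mol.GetAtoms() if not a.GetIsAromatic()
        )
        assert result.atom_weights[methyl] <= 0

    @pytest.mark.parametrize(
        "ref_s,test_s",
        [
            ("c1ccccc1C(=O)O", "Cc1ccccc1C(=O)O"),
            ("CC(=O)Nc1ccc(O)cc1", "CC(=O)Nc1ccc(OC)cc1"),
            ("CCS(=O)(=O)N", "c1ccccc1S(=O)(=O)N"),
        ],
    )
    def test_matches_naive_bit_removal(self, ref_s, test_s):
        ref = parse_smiles(ref_s, "r")
        test = parse_smiles(test_s, "t")
        result = similarity_map_weights(ref, test)
        np.testing.assert_allclose(
            result.atom_weights, naive_atom_weights(ref, test), atol=1e-12
        )

    def test_weights_normalized(self):
        ref = parse_smiles("c1ccccc1C(=O)O", "r")
        test = parse_smiles("Cc1ccccc1", "t")
        w = similarity_map_weights(ref, test).atom_weights
        assert np.max(np.abs(w)) == pytest.approx(1.0)


class TestTsne:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(0)
        E = rng.standard_normal((120, 8))
        c1 = tsne_2d(E, perplexity=10, seed=4)
        c2 = tsne_2d(E, perplexity=10, seed=4)
        assert c1.shape == (120, 2)
        np.testing.assert_array_equal(c1, c2)

    def test_perplexity_guard(self):
        with pytest.raises(ValueError, match="perplexity"):
            tsne_2d(np.zeros((20, 4)), perplexity=30)

    def test_preserves_blob_structure(self, six_blob_mixture):
        X, labels = six_blob_mixture
        idx = np.random.default_rng(1).choice(len(X), 300, replace=False)
        coords = tsne_2d(X[idx], perplexity=20, seed=0)
        lab = labels[idx]
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(coords))
        same = lab[:, None] == lab[None, :]
        off_diag = ~np.eye(len(lab), dtype=bool)
        assert D[same & off_diag].mean() < D[~same].mean()
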