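"""Fingerprint families, PCA reduction, attribute combination."""

import numpy as np
import pytest

from apn.attributes import (
    ATTRIBUTE_DIM,
    FINGERPRINT_KINDS,
    FingerprintMatrix,
    apply_reducer,
    attribute_pipeline,
    classify_relationship,
    combine_attributes,
    compute_fingerprint,
    fingerprint_matrix,
    fit_reducer,
    load_deep_fingerprints,
)
from apn.chem_data import MoleculeRecord

SMILES = ["CCO", "c1ccccc1", "CC(=O)O", "CCN", "CCCC", "C1CCCCC1"]


class TestFingerprintRegistry:
    def test_registry_has_14_kinds(self):
        assert len(FINGERPRINT_KINDS) == 14

    @pytest.mark.parametrize("kind", FINGERPRINT_KINDS)
    def test_dimensions(self, kind):
        fp = compute_fingerprint("CCO", kind)
        assert fp.shape == (167 if kind == "maccs" else 1024,)
        assert set(np.unique(fp)) <= {0.0, 1.0}

    def test_deterministic(self):
        a = compute_fingerprint("CC(=O)Oc1ccccc1C(=O)O", "ecfp4")
        b = compute_fingerprint("CC(=O)Oc1ccccc1C(=O)O", "ecfp4")
        assert np.array_equal(a, b)

    def test_unknown_kind_lists_valid(self):
        with pytest.raises(KeyError, match="maccs"):
            compute_fingerprint("CCO", "nope")

    def test_invalid_smiles(self):
        with pytest.raises(ValueError, match="parse"):
            compute_fingerprint("xx!", "ecfp4")


class TestReducer:
    def test_projection_shape_and_padding(self, rng):
        # 200 x 1024 -> 200 x 100
        X = (rng.random((200, 1024)) < 0.1).astype(float)
        fp = FingerprintMatrix("ecfp4", X)
        attr = apply_reducer(fp, fit_reducer(fp))
        assert attr.values.shape == (200, 100)
        # tiny matrix: only n-1 components exist, rest zero-padded
        fp_small = FingerprintMatrix("ecfp4", X[:5])
        attr_small = apply_reducer(fp_small, fit_reducer(fp_small))
        assert attr_small.values.shape == (5, 100)
        assert np.allclose(attr_small.values[:, 4:], 0.0)

    def test_mean_row_projects_to_zero(self, rng):
        X = rng.random((50, 30))
        params = fit_reducer(FingerprintMatrix("x", X))
        mean_row = FingerprintMatrix("x", X.mean(axis=0, keepdims=True))
        proj = apply_reducer(mean_row, params).values
        assert np.allclose(proj, 0.0, atol=1e-10)

    def test_low_rank_reconstruction_matches_svd_oracle(self, rng):
        # rank-5 matrix: 100 components reconstruct it exactly
        A = rng.standard_normal((60, 5)) @ rng.standard_normal((5, 40))
        params = fit_reducer(FingerprintMatrix("x", A))
        proj = apply_reducer(FingerprintMatrix("x", A), params).values
        k = params.components.shape[0]
        recon = proj[:, :k] @ params.components + params.mean
        assert np.allclose(recon, A, atol=1e-8)
        # oracle: centered SVD captures all variance in 5 components
        U, s, Vt = np.linalg.svd(A - A.mean(axis=0), full_matrices=False)
        assert s[5:].max() < 1e-8

    def test_maccs_reduces_to_100_like_others(self, smiles300):
        fp = fingerprint_matrix(smiles300[:150], "maccs")
        assert fp.dim == 167
        attr = apply_reducer(fp, fit_reducer(fp))
        assert attr.values.shape == (150, 100)

    def test_projection_independent_of_fit_batch_order(self, rng):
        X = rng.random((40, 20))
        params = fit_reducer(FingerprintMatrix("x", X))
        Y = rng.random((7, 20))
        p1 = apply_reducer(FingerprintMatrix("x", Y), params).values
        p2 = apply_reducer(FingerprintMatrix("x", Y[::-1]), params).values
        assert np.allclose(p1, p2[::-1])

    def test_dim_mismatch_fatal(self, rng):
        params = fit_reducer(FingerprintMatrix("x", rng.random((10, 20))))
        with pytest.raises(ValueError, match="20"):
            apply_reducer(FingerprintMatrix("x", rng.random((10, 30))), params)

    def test_single_row_fatal(self):
        with pytest.raises(ValueError):
            fit_reducer(FingerprintMatrix("x", np.ones((1, 10))))


class TestCombine:
    def _attrs(self, rng, n=3):
        from apn.attributes import AttributeMatrix

        return [
            AttributeMatrix([f"k{i}"], "none", rng.standard_normal((8, 100)))
            for i in range(n)
        ]

    def test_addition_identity_and_commutativity(self, rng):
        from apn.attributes import AttributeMatrix

        a, b, _ = self._attrs(rng)
        zero = AttributeMatrix(["z"], "none", np.zeros((8, 100)))
        assert np.allclose(
            combine_attributes([a, zero], "addition").values, a.values
        )
        ab = combine_attributes([a, b], "addition").values
        ba = combine_attributes([b, a], "addition").values
        assert np.allclose(ab, ba)

    def test_concatenation_dims_and_name(self, rng):
        a, b, c = self._attrs(rng)
        pair = combine_attributes([a, b], "concatenation")
        assert pair.dim == 200
        trip = combine_attributes([a, b, c], "addition")
        assert trip.dim == 100
        assert trip.name == "k0_k1_k2"

    def test_bad_inputs(self, rng):
        a, b, c = self._attrs(rng)
        with pytest.raises(ValueError):
            combine_attributes([a], "addition")
        with pytest.raises(ValueError):
            combine_attributes([a, b, c, a], "addition")

    def test_pipeline_on_real_molecules(self, smiles300):
        smiles = smiles300[:80]
        single = attribute_pipeline(smiles, "ecfp4")
        assert single.values.shape == (80, 100)
        trip = attribute_pipeline(smiles, "hashap_avalon_ecfp4", agg="addition")
        assert trip.values.shape == (80, 100)
        assert trip.name == "hashap_avalon_ecfp4"


class TestDeepFingerprints:
    def _records(self):
        return [
            MoleculeRecord(smiles=s, labels={}, mol_id=i)
            for i, s in enumerate(["CCO", "CCN", "c1ccccc1"])
        ]

    def test_keyed_join_ignores_row_order(self, tmp_path, rng):
        V = rng.standard_normal((3, 8)).round(4)
        lines = ["smiles," + ",".join(f"v{i}" for i in range(8))]
        for s, row in zip(["c1ccccc1", "CCO", "CCN"], V[[2, 0, 1]]):
            lines.append(s + "," + ",".join(map(str, row)))
        p = tmp_path / "emb.csv"
        p.write_text("\n".join(lines) + "\n")
        fp = load_deep_fingerprints(p, self._records(), tag="toy")
        assert fp.kind == "deep:toy"
        assert np.allclose(fp.values, V)

    def test_missing_key_fatal(self, tmp_path):
        p = tmp_path / "emb.csv"
        p.write_text("smiles,v0\nCCO,1.0\nCCN,2.0\n")
        with pytest.raises(KeyError, match="c1ccccc1"):
            load_deep_fingerprints(p, self._records())

    def test_deep_vectors_reduce_like_fingerprints(self, tmp_path, rng):
        n = 30
        smiles = [f"{'C' * (i + 1)}O" for i in range(n)]
        records = [MoleculeRecord(s, {}, i) for i, s in enumerate(smiles)]
        V = rng.standard_normal((n, 768))
        lines = ["smiles," + ",".join(f"v{i}" for i in range(768))]
        for s, row in zip(smiles, V):
            lines.append(s + "," + ",".join(f"{x:.6f}" for x in row))
        p = tmp_path / "emb.csv"
        p.write_text("\n".join(lines) + "\n")
        fp = load_deep_fingerprints(p, records)
        attr = apply_reducer(fp, fit_reducer(fp))
        assert attr.values.shape == (n, 100)


class TestRelationshipTaxonomy:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.8352, 0.8254, 0.8221), "R1"),  # combined beats both singles
            ((0.80, 0.82, 0.81), "R3"),
            ((0.82, 0.82, 0.80), "R2"),  # tie with one single -> one-sided
            ((0.81, 0.82, 0.80), "R2"),
        ],
    )
    def test_classification(self, triple, expected):
        assert classify_relationship(*triple) == expected

    def test_heatmap_encoding(self):
        from apn.attributes import HEATMAP_VALUE

        assert HEATMAP_VALUE == {"R1": 1.0, "R2": 0.5, "R3": 0.0}

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_relationship(float("nan"), 0.5, 0.5)
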