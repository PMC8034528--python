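"""Label encodings, the four scores, and the exact permutation null for z."""

from itertools import permutations

import numpy as np
import pytest

import netprop as npg
from netprop.exceptions import (
    DegenerateInputError,
    EmptyOverlapError,
    ParameterError,
)
from netprop.scores import permutation_null_moments


def exhaustive_null_moments(k: np.ndarray, y: np.ndarray):
    """Brute-force mean/variance of K@y over all n! permutations of y."""
    fs = np.array([k @ np.array(p) for p in permutations(y)])
    return fs.mean(axis=0), fs.var(axis=0)


class TestEncoding:
    def test_raw_single_positive(self, path2):
        enc = npg.encode_labels(npg.LabelInput({"A": 1.0}), path2, "raw")
        assert np.array_equal(enc.y, [1.0, 0.0]) and enc.unmatched == []

    def test_unmatched_reported_not_dropped(self, path2):
        enc = npg.encode_labels(npg.LabelInput({"A": 1.0, "C": 1.0}), path2, "raw")
        assert enc.unmatched == ["C"] and enc.matched == {"A"}

    def test_empty_overlap_is_an_error(self, path2):
        with pytest.raises(EmptyOverlapError):
            npg.encode_labels(npg.LabelInput({"X": 1.0}), path2, "raw")

    def test_quantitative_rejected_for_signed_encodings(self, path2):
        labels = npg.LabelInput({"A": 2.5}, "quantitative")
        for method in ("ml", "gm"):
            with pytest.raises(ParameterError, match="quantitative"):
                npg.encode_labels(labels, path2, method)

    def test_ml_signs(self):
        net = npg.build_network([("A", "B"), ("B", "C"), ("C", "D")])
        enc = npg.encode_labels(npg.LabelInput.from_ids(["A"]), net, "ml", negatives={"C"})
        assert dict(zip(net.node_order, enc.y)) == {"A": 1.0, "B": 0.0, "C": -1.0, "D": 0.0}

    def test_gm_bias_constant(self):
        # 3 positives, 1 negative, 4 unlabeled: k = (3 - 1) / (3 + 1) = 0.5
        net = npg.build_network([(f"n{i}", f"n{i+1}") for i in range(7)])
        enc = npg.encode_labels(
            npg.LabelInput.from_ids(["n0", "n1", "n2"]), net, "gm", negatives={"n3"}
        )
        lookup = dict(zip(net.node_order, enc.y))
        assert lookup["n0"] == lookup["n1"] == lookup["n2"] == 1.0
        assert lookup["n3"] == -1.0
        unlabeled = [lookup[f"n{i}"] for i in range(4, 8)]
        assert unlabeled == [0.5] * 4
        # cross-check: the bias equals the mean of the labeled codes
        assert np.isclose(0.5, np.mean([1, 1, 1, -1]))

    def test_quantitative_values_carried_through_raw(self, path2):
        enc = npg.encode_labels(npg.LabelInput({"A": -3.5}, "quantitative"), path2, "raw")
        assert enc.y[path2.node_order.index("A")] == -3.5


class TestRawScore:
    def test_identity_kernel_returns_input(self, identity_kernel):
        net = npg.build_network([("A", "B"), ("B", "C")])
        enc = npg.encode_labels(npg.LabelInput({"A": 1.0, "C": 1.0}), net, "raw")
        res = npg.score_raw(identity_kernel(net), enc)
        assert np.array_equal(res.scores, enc.y)

    def test_two_node_regularized_laplacian(self, path2):
        k = npg.compute_kernel(path2, "regularized_laplacian", sigma2=1.0)
        enc = npg.encode_labels(npg.LabelInput({"A": 1.0}), path2, "raw")
        res = npg.score_raw(k, enc)
        assert np.abs(res.scores - np.array([2 / 3, 1 / 3])).max() < 1e-12

    def test_linearity(self, random_nets, identity_kernel):
        net = random_nets[0]
        k = npg.compute_kernel(net, "diffusion")
        rng = np.random.default_rng(0)
        y1, y2 = rng.normal(size=net.n_nodes), rng.normal(size=net.n_nodes)
        f = lambda y: k.matrix @ y
        assert np.abs(f(2.0 * y1 + 3.0 * y2) - (2.0 * f(y1) + 3.0 * f(y2))).max() < 1e-12

    def test_order_mismatch_rejected(self, path2, triangle):
        k = npg.compute_kernel(triangle, "regularized_laplacian")
        enc = npg.encode_labels(npg.LabelInput({"A": 1.0}), path2, "raw")
        with pytest.raises(npg.AlignmentError):
            npg.score_raw(k, enc)


class TestSignedScores:
    def test_ml_all_positives_gives_row_sums(self, triangle):
        k = npg.compute_kernel(triangle, "regularized_laplacian")
        enc = npg.encode_labels(npg.LabelInput.from_ids(["A", "B", "C"]), triangle, "ml")
        res = npg.score_ml(k, enc)
        assert np.abs(res.scores - 1.0).max() < 1e-10  # rows of the RL kernel sum to 1

    def test_balanced_ml_scores_sum_to_zero_on_cycle(self):
        net = npg.build_network([(f"n{i}", f"n{(i+1) % 6}") for i in range(6)])
        k = npg.compute_kernel(net, "regularized_laplacian")
        enc = npg.encode_labels(
            npg.LabelInput.from_ids(["n0", "n1"]), net, "ml", negatives={"n3", "n4"}
        )
        res = npg.score_ml(k, enc)
        assert abs(res.scores.sum()) < 1e-10

    def test_gm_equals_ml_for_balanced_classes(self):
        net = npg.build_network([("A", "B"), ("B", "C"), ("C", "D")])
        k = npg.compute_kernel(net, "diffusion")
        pos, neg = npg.LabelInput.from_ids(["A"]), {"D"}
        ml = npg.score_ml(k, npg.encode_labels(pos, net, "ml", negatives=neg))
        gm = npg.score_gm(k, npg.encode_labels(pos, net, "gm", negatives=neg))
        assert np.abs(ml.scores - gm.scores).max() < 1e-12


class TestZScore:
    @pytest.mark.parametrize("edges,y_entries", [
        ([("A", "B"), ("B", "C")], {"A": 1.0}),
        ([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")], {"A": 1.0, "C": 1.0}),
        ([(f"n{i}", f"n{j}") for i in range(5) for j in range(i + 1, 5)], {"n0": 2.0, "n3": -1.0}),
        ([("A", "B"), ("C", "D"), ("B", "C"), ("D", "E"), ("E", "F")], {"A": 1.0, "D": 1.0}),
    ])
    def test_analytic_moments_match_exhaustive_enumeration(self, edges, y_entries):
        net = npg.build_network(edges)
        k = npg.compute_kernel(net, "regularized_laplacian")
        labels = npg.LabelInput(dict(y_entries), "quantitative")
        enc = npg.encode_labels(labels, net, "z")
        mean, var = permutation_null_moments(k, enc.y)
        emean, evar = exhaustive_null_moments(k.matrix, enc.y)
        assert np.abs(mean - emean).max() < 1e-10
        assert np.abs(var - evar).max() < 1e-10

    def test_monte_carlo_agrees_with_analytic(self):
        net = npg.generate_network(
            npg.FixtureSpec("erdos_renyi", n=15, params={"p": 0.3}, seed=9)
        ).network
        k = npg.compute_kernel(net, "regularized_laplacian")
        enc = npg.encode_labels(npg.LabelInput.from_ids(["v00", "v03", "v07"]), net, "z")
        analytic = npg.score_z(k, enc)
        mc = npg.score_z_montecarlo(k, enc, n_samples=50_000, seed=1)
        assert np.abs(analytic.scores - mc.scores).max() < 0.1

    def test_affine_invariance(self, random_nets):
        net = random_nets[1]
        k = npg.compute_kernel(net, "diffusion")
        rng = np.random.default_rng(3)
        y = rng.normal(size=net.n_nodes)
        mask = np.ones(net.n_nodes, dtype=bool)

        def z_of(vec):
            f = k.matrix @ vec
            mean, var = permutation_null_moments(k, vec, mask)
            return (f - mean) / np.sqrt(var)

        assert np.abs(z_of(2.5 * y + 1.0) - z_of(y)).max() < 1e-9

    def test_identity_kernel_reduces_to_classical_standardization(self, identity_kernel):
        net = npg.build_network([("A", "B"), ("B", "C"), ("C", "D")])
        labels = npg.LabelInput({"A": 3.0, "C": 1.0}, "quantitative")
        enc = npg.encode_labels(labels, net, "z")
        res = npg.score_z(identity_kernel(net), enc)
        expected = (enc.y - enc.y.mean()) / enc.y.std()
        assert np.abs(res.scores - expected).max() < 1e-10

    def test_constant_labels_rejected(self, triangle):
        enc = npg.encode_labels(npg.LabelInput.from_ids(["A", "B", "C"]), triangle, "z")
        k = npg.compute_kernel(triangle, "regularized_laplacian")
        with pytest.raises(DegenerateInputError, match="constant"):
            npg.score_z(k, enc)

    def test_undefined_entries_flagged_not_zero(self, identity_kernel):
        # a kernel with an all-zero row has zero permutation variance there
        net = npg.build_network([("A", "B"), ("B", "C")])
        k = identity_kernel(net)
        k.matrix[0, :] = 0.0
        enc = npg.encode_labels(npg.LabelInput({"B": 1.0}), net, "z")
        res = npg.score_z(k, enc)
        assert res.undefined[0] and np.isnan(res.scores[0])
        assert np.isfinite(res.scores[~res.undefined]).all()

    def test_modality_restricted_background_changes_null(self):
        net = npg.build_network(
            [("g1", "g2"), ("g2", "m1"), ("m1", "m2"), ("m2", "g3")],
            modalities={"g1": "gene", "g2": "gene", "g3": "gene",
                        "m1": "metabolite", "m2": "metabolite"},
        )
        k = npg.compute_kernel(net, "regularized_laplacian")
        labels = npg.LabelInput.from_ids(["g1", "g3"])
        enc_all = npg.encode_labels(labels, net, "z")
        enc_gene = npg.encode_labels(labels, net, "z", background_modality="gene")
        assert int(enc_gene.background_mask.sum()) == 3
        z_all = npg.score_z(k, enc_all)
        z_gene = npg.score_z(k, enc_gene)
        assert not np.allclose(z_all.scores, z_gene.scores, equal_nan=True)


class TestRanking:
    def test_descending_order(self, identity_kernel):
        net = npg.build_network([("n1", "n2"), ("n2", "n3")])
        res = npg.ScoreResult(np.array([0.9, 0.1, 0.5]), "raw", net.node_order,
                              np.zeros(3, dtype=bool))
        ranked = npg.rank_nodes(res)
        assert [r[0] for r in ranked] == ["n1", "n3", "n2"]
        assert [r[2] for r in ranked] == [1.0, 2.0, 3.0]

    def test_ties_get_mid_rank(self):
        res = npg.ScoreResult(np.array([0.5, 0.5]), "raw", ("a", "b"), np.zeros(2, dtype=bool))
        assert [r[2] for r in npg.rank_nodes(res)] == [1.5, 1.5]

    def test_modality_restriction(self):
        net = npg.build_network([("g1", "m1"), ("m1", "g2")],
                                modalities={"g1": "gene", "g2": "gene", "m1": "metabolite"})
        res = npg.ScoreResult(np.array([3.0, 2.0, 1.0]), "raw", net.node_order,
                              np.zeros(3, dtype=bool))
        ranked = npg.rank_nodes(res, net, restrict_to="metabolite")
        assert [r[0] for r in ranked] == ["m1"]
        with pytest.raises(DegenerateInputError):
            npg.rank_nodes(res, net, restrict_to="mirna")


class TestLabelFiles:
    def test_bare_list_is_binary_ones(self, tmp_path):
        f = tmp_path / "labels.tsv"
        f.write_text("A\nB\n")
        labels = npg.read_labels(f)
        assert labels.declared_type == "binary" and labels.entries == {"A": 1.0, "B": 1.0}

    def test_value_column_detected_quantitative(self, tmp_path):
        f = tmp_path / "labels.csv"
        f.write_text("A,2.5\nB,-1.0\n")
        labels = npg.read_labels(f)
        assert labels.declared_type == "quantitative" and labels.entries["B"] == -1.0

    def test_binary_values_stay_binary(self, tmp_path):
        f = tmp_path / "labels.tsv"
        f.write_text("A\t1\nB\t0\n")
        assert npg.read_labels(f).declared_type == "binary"
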