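"""Network forward operations against brute-force oracles, closed-form loss
checks, and a finite-difference verification of the analytic gradients."""

import numpy as np
import pytest

from omicfuse import (
    attribute_reconstruction_loss,
    build_indicator_matrix,
    build_knn_graph,
    decode_attributes,
    decode_graph,
    encode_omics,
    fuse_consensus,
    graph_reconstruction_loss,
    normalize_adjacency,
    self_supervised_loss,
    soft_assignment,
    target_distribution,
    total_loss,
)
from omicfuse.model import (
    ConsensusEmbedding,
    DecoderStack,
    EncoderStack,
    GraphDecoderWeights,
    init_params,
    loss_and_grads,
    model_forward,
)


def make_fixture(rng, n=5, d_in=4, d=2, depth=2):
    x = rng.standard_normal((n, d_in))
    g = build_knn_graph(x, 2)
    t = normalize_adjacency(g).op
    ws = []
    widths = [d_in] + [3] * (depth - 1) + [d]
    for m in range(depth):
        ws.append(rng.standard_normal((widths[m], widths[m + 1])) * 0.5)
    return x, t, ws


class TestEncoder:
    def test_zero_weights_give_zero_output(self, rng):
        x, t, ws = make_fixture(rng)
        enc = EncoderStack(layers=[[np.zeros_like(w) for w in ws]])
        out = encode_omics(x, t, enc, 0)
        np.testing.assert_array_equal(out, np.zeros((5, 2)))

    def test_tanh_linear_regime_matches_matrix_product(self, rng):
        # edgeless graph => operator is identity; tiny entries => tanh ~ id
        x = rng.standard_normal((4, 3)) * 1e-4
        w = rng.standard_normal((3, 2)) * 1e-2
        enc = EncoderStack(layers=[[w]])
        out = encode_omics(x, np.eye(4), enc, 0)
        np.testing.assert_allclose(out, x @ w, atol=1e-6)

    def test_matches_explicit_message_passing_loop(self, rng):
        x, t, ws = make_fixture(rng)
        enc = EncoderStack(layers=[ws])
        out = encode_omics(x, t, enc, 0)
        z = x.copy()
        for w in ws:
            propagated = np.zeros_like(z)
            for i in range(z.shape[0]):
                for j in range(z.shape[0]):
                    propagated[i] += t[i, j] * z[j]
            z = np.tanh(propagated @ w)
        np.testing.assert_allclose(out, z, atol=1e-10)

    def test_shape_mismatch_cites_layer(self, rng):
        x, t, ws = make_fixture(rng)
        ws[1] = np.zeros((99, 2))
        enc = EncoderStack(layers=[ws])
        with pytest.raises(ValueError, match="layer 2"):
            encode_omics(x, t, enc, 0)


class TestFusion:
    def test_single_full_omics_is_identity(self, rng):
        z = rng.standard_normal((4, 2))
        g = build_indicator_matrix(["a", "b", "c", "d"], ["a", "b", "c", "d"])
        h = fuse_consensus([z], [g])
        np.testing.assert_array_equal(h.H, z)

    def test_two_full_omics_average(self, rng):
        ids = ["a", "b", "c"]
        g = build_indicator_matrix(ids, ids)
        z1, z2 = rng.standard_normal((3, 2)), rng.standard_normal((3, 2))
        h = fuse_consensus([z1, z2], [g, g])
        np.testing.assert_allclose(h.H, (z1 + z2) / 2)

    def test_partial_sample_uses_available_embeddings_only(self, rng):
        intact = ["a", "b", "c"]
        g1 = build_indicator_matrix(["a", "c"], intact)  # b missing here
        g2 = build_indicator_matrix(intact, intact)
        z1 = rng.standard_normal((2, 2))
        z2 = rng.standard_normal((3, 2))
        h = fuse_consensus([z1, z2], [g1, g2]).H
        np.testing.assert_allclose(h[0], (z1[0] + z2[0]) / 2)
        np.testing.assert_allclose(h[1], z2[1])  # only omics 2 measured b
        np.testing.assert_allclose(h[2], (z1[1] + z2[2]) / 2)

    def test_sample_in_no_omics_raises(self, rng):
        intact = ["a", "b"]
        g = build_indicator_matrix(["a"], intact)
        with pytest.raises(ValueError, match="absent"):
            fuse_consensus([rng.standard_normal((1, 2))], [g])


class TestAttributeDecoder:
    def test_zero_weights_give_zero_output(self, rng):
        h = rng.standard_normal((4, 2))
        dec = DecoderStack(layers=[[np.zeros((2, 3)), np.zeros((3, 5))]])
        g = build_indicator_matrix(list("abcd"), list("abcd"))
        out = decode_attributes(h, np.eye(4), dec, g, 0)
        np.testing.assert_array_equal(out, np.zeros((4, 5)))

    def test_identity_indicator_first_layer_is_plain_tanh(self, rng):
        h = rng.standard_normal((4, 2))
        w = rng.standard_normal((2, 3))
        dec = DecoderStack(layers=[[w]])
        g = build_indicator_matrix(list("abcd"), list("abcd"))
        out = decode_attributes(h, np.eye(4), dec, g, 0)
        np.testing.assert_allclose(out, np.tanh(h @ w), atol=1e-12)

    def test_matches_hand_unrolled_two_layer_computation(self, rng):
        x, t, _ = make_fixture(rng, n=4)
        h = rng.standard_normal((6, 2))
        g = build_indicator_matrix(["s0", "s2", "s3", "s5"], [f"s{i}" for i in range(6)])
        w0 = rng.standard_normal((2, 3)) * 0.5
        w1 = rng.standard_normal((3, 4)) * 0.5
        dec = DecoderStack(layers=[[w0, w1]])
        out = decode_attributes(h, t, dec, g, 0)
        hv = h[[0, 2, 3, 5]]
        y0 = np.tanh(hv @ w0)
        y1 = np.zeros((4, 4))
        for i in range(4):
            acc = np.zeros(3)
            for j in range(4):
                acc += t[i, j] * y0[j]
            y1[i] = np.tanh(acc @ w1)
        np.testing.assert_allclose(out, y1, atol=1e-10)


class TestGraphDecoder:
    def test_zero_bilinear_matrix_gives_zero(self, rng):
        h = rng.standard_normal((3, 2))
        g = build_indicator_matrix(list("abc"), list("abc"))
        out = decode_graph(h, GraphDecoderWeights(mats=[np.zeros((2, 2))]), g, 0)
        np.testing.assert_array_equal(out, np.zeros((3, 3)))

    def test_symmetric_bilinear_matrix_gives_symmetric_output(self, rng):
        h = rng.standard_normal((4, 3))
        w = rng.standard_normal((3, 3))
        w = (w + w.T) / 2
        g = build_indicator_matrix(list("abcd"), list("abcd"))
        out = decode_graph(h, GraphDecoderWeights(mats=[w]), g, 0)
        np.testing.assert_allclose(out, out.T, atol=1e-12)

    def test_matches_elementwise_bilinear_oracle(self, rng):
        h = rng.standard_normal((3, 2))
        w = rng.standard_normal((2, 2))
        g = build_indicator_matrix(list("abc"), list("abc"))
        out = decode_graph(h, GraphDecoderWeights(mats=[w]), g, 0)
        for i in range(3):
            for j in range(3):
                assert out[i, j] == pytest.approx(np.tanh(h[i] @ w @ h[j]), abs=1e-12)


class TestReconstructionLosses:
    def test_perfect_reconstruction_is_zero(self, rng):
        x = rng.standard_normal((3, 4))
        assert attribute_reconstruction_loss([x], [x.copy()]) == 0.0
        assert graph_reconstruction_loss([x @ x.T], [x @ x.T]) == 0.0

    def test_single_entry_delta_squared(self):
        x = np.zeros((2, 2))
        xhat = x.copy()
        xhat[0, 1] = 0.3
        assert attribute_reconstruction_loss([x], [xhat]) == pytest.approx(0.09)

    def test_two_unit_entries(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert graph_reconstruction_loss([a], [np.zeros((2, 2))]) == pytest.approx(2.0)

    def test_matches_double_loop_over_omics(self, rng):
        xs = [rng.standard_normal((4, 4)) for _ in range(2)]
        ys = [rng.standard_normal((4, 4)) for _ in range(2)]
        expect = sum(
            (x[i, j] - y[i, j]) ** 2
            for x, y in zip(xs, ys)
            for i in range(4)
            for j in range(4)
        )
        assert attribute_reconstruction_loss(xs, ys) == pytest.approx(expect, abs=1e-12)
        assert graph_reconstruction_loss(xs, ys) == pytest.approx(expect, abs=1e-12)

    def test_graph_loss_strictly_positive_for_nonzero_adjacency(self, rng):
        # tanh outputs never reach 1, so a binary graph with edges can
        # never be reconstructed exactly
        h = rng.standard_normal((4, 2))
        g = build_indicator_matrix(list("abcd"), list("abcd"))
        ahat = decode_graph(h, GraphDecoderWeights(mats=[rng.standard_normal((2, 2))]), g, 0)
        a = build_knn_graph(rng.standard_normal((4, 2)), 1).adj.astype(float)
        assert a.sum() > 0
        assert graph_reconstruction_loss([a], [ahat]) > 0

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="omics 0"):
            attribute_reconstruction_loss([np.zeros((2, 2))], [np.zeros((2, 3))])


class TestSoftAssignment:
    def test_equidistant_centers_give_uniform_row(self):
        h = np.array([[0.0, 0.0]])
        mu = np.array([[1.0, 0.0], [-1.0, 0.0]])
        np.testing.assert_allclose(soft_assignment(h, mu), [[0.5, 0.5]])

    def test_closed_form_two_thirds_one_third(self):
        # h at center 1, squared distance 1 to center 2:
        # (1+0)^-1 = 1 and (1+1)^-1 = 0.5, normalize -> [2/3, 1/3]
        h = np.array([[0.0]])
        mu = np.array([[0.0], [1.0]])
        np.testing.assert_allclose(soft_assignment(h, mu), [[2 / 3, 1 / 3]], atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_rows_sum_to_one_and_entries_positive(self, seed):
        rng = np.random.default_rng(seed)
        q = soft_assignment(rng.standard_normal((20, 3)), rng.standard_normal((4, 3)))
        np.testing.assert_allclose(q.sum(axis=1), np.ones(20), atol=1e-9)
        assert np.all(q > 0)


class TestTargetDistribution:
    def test_single_sample_fixed_point(self, rng):
        # with N=1, f_j = Q_1j so Q^2/f = Q and P == Q
        q = soft_assignment(rng.standard_normal((1, 3)), rng.standard_normal((4, 3)))
        np.testing.assert_allclose(target_distribution(q), q, atol=1e-12)

    def test_uniform_q_stays_uniform(self):
        q = np.full((5, 4), 0.25)
        np.testing.assert_allclose(target_distribution(q), q, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        q = soft_assignment(rng.standard_normal((15, 2)), rng.standard_normal((3, 2)))
        p = target_distribution(q)
        np.testing.assert_allclose(p.sum(axis=1), np.ones(15), atol=1e-9)

    def test_sharpens_assignments(self, rng):
        q = soft_assignment(rng.standard_normal((15, 2)), rng.standard_normal((3, 2)))
        p = target_distribution(q)
        assert p.max(axis=1).mean() >= q.max(axis=1).mean()

    def test_empty_soft_cluster_raises(self):
        q = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="cluster"):
            target_distribution(q)


class TestSelfSupervisedLoss:
    def test_identical_distributions_zero(self, rng):
        q = soft_assignment(rng.standard_normal((6, 2)), rng.standard_normal((2, 2)))
        assert self_supervised_loss(q, q) == pytest.approx(0.0, abs=1e-12)

    def test_log_two_hand_case(self):
        p = np.array([[1.0, 0.0]])
        q = np.array([[0.5, 0.5]])
        assert self_supervised_loss(p, q) == pytest.approx(np.log(2), abs=1e-12)

    def test_nonnegative(self, rng):
        q = soft_assignment(rng.standard_normal((10, 3)), rng.standard_normal((3, 3)))
        p = target_distribution(q)
        assert self_supervised_loss(p, q) >= 0

    def test_infinite_divergence_raises(self):
        with pytest.raises(ValueError, match="zero"):
            self_supervised_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))


class TestTotalLoss:
    def test_default_unit_weights(self):
        assert total_loss(1, 2, 3, 1, 1).total == pytest.approx(6.0)

    def test_all_zero(self):
        assert total_loss(0, 0, 0, 1, 1).total == 0.0

    def test_weighted_combination(self):
        lb = total_loss(1, 2, 3, 0.5, 2)
        assert lb.total == pytest.approx(8.0)
        assert lb.total == pytest.approx(lb.l_nar + lb.alpha * lb.l_gsr + lb.beta * lb.l_ss, abs=1e-9)

    def test_negative_weights_raise(self):
        with pytest.raises(ValueError, match="weights"):
            total_loss(1, 1, 1, -0.1, 1)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Every parameter group's analytic gradient (encoders, decoders,
        bilinear graph decoders, cluster centers) agrees with central
        finite differences of the total loss on a partial-data fixture."""
        rng = np.random.default_rng(0)
        n = 6
        xs = [rng.standard_normal((6, 4)), rng.standard_normal((5, 3))]
        graphs_ = [build_knn_graph(x, 2) for x in xs]
        ts = [normalize_adjacency(g).op for g in graphs_]
        a_list = [g.adj.astype(float) for g in graphs_]
        idx = [np.arange(6), np.array([0, 2, 3, 4, 5])]
        params = init_params([4, 3], [3, 3], 2, rng)
        params["mu"] = rng.standard_normal((2, 2))
        h0 = model_forward(params, xs, ts, idx, n)["H"]
        p_target = target_distribution(soft_assignment(h0, params["mu"]))
        alpha, beta = 0.7, 1.3

        def total():
            lb, _, _ = loss_and_grads(params, xs, ts, idx, a_list, n, alpha, beta, p_target)
            return lb.total

        _, grads, _ = loss_and_grads(params, xs, ts, idx, a_list, n, alpha, beta, p_target)
        eps = 1e-6

        def check(arr, garr):
            for _ in range(4):
                i = tuple(rng.integers(0, s) for s in arr.shape)
                old = arr[i]
                arr[i] = old + eps
                f1 = total()
                arr[i] = old - eps
                f2 = total()
                arr[i] = old
                num = (f1 - f2) / (2 * eps)
                assert garr[i] == pytest.approx(num, rel=1e-4, abs=1e-6)

        for v in range(2):
            for m in range(2):
                check(params["enc"][v][m], grads["enc"][v][m])
                check(params["dec"][v][m], grads["dec"][v][m])
            check(params["graph"][v], grads["graph"][v])
        check(params["mu"], grads["mu"])

    def test_loss_breakdown_matches_public_loss_functions(self):
        rng = np.random.default_rng(3)
        xs = [rng.standard_normal((5, 3))]
        g = build_knn_graph(xs[0], 2)
        ts = [normalize_adjacency(g).op]
        a_list = [g.adj.astype(float)]
        idx = [np.arange(5)]
        params = init_params([3], [3], 2, rng)
        lb, _, aux = loss_and_grads(params, xs, ts, idx, a_list, 5, 1.0, 1.0, None)
        assert lb.l_nar == pytest.approx(
            attribute_reconstruction_loss(xs, aux["Xhat"]), abs=1e-12
        )
        assert lb.l_gsr == pytest.approx(
            graph_reconstruction_loss(a_list, aux["Ahat"]), abs=1e-12
        )
        assert lb.l_ss == 0.0
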