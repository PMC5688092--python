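import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import sparse

from ihnet.io_formats import InteractionSet, OmicsMatrix, SeedSet, ValidationError, normalize_features
from ihnet.network import (
    GeneRegression,
    NormalizedMatrix,
    RegulatoryCoefficients,
    assemble_heterogeneous_network,
    compute_seed_correlations,
    fit_regulatory_regression,
    fuse_expression_edges,
    mask_held_out_seed,
    symmetric_normalize,
)


def _omics(values, entities, samples=None, omics="expression", normalize=True):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(entities, name="id"), columns=samples)
    m = OmicsMatrix(omics, df, normalized=False)
    return normalize_features(m) if normalize else m


class TestSeedCorrelations:
    def test_identical_and_negated_rows_give_entry_one(self, rng):
        base = rng.standard_normal(20)
        m = _omics([base, base, -base, rng.standard_normal(20)],
                   ["seed", "same", "anti", "other"])
        cm = compute_seed_correlations(m, SeedSet([("seed", "expression")]), 0.05)
        M = cm.matrix.toarray()
        assert M[0, 1] == pytest.approx(1.0)
        assert M[0, 2] == pytest.approx(1.0)  # absolute PCC keeps anticorrelation
        assert np.allclose(M, M.T)
        assert np.all(np.diag(M) == 0)

    def test_non_seed_pairs_absent(self, rng):
        base = rng.standard_normal(30)
        # entities 1 and 2 are strongly correlated with each other but are
        # not seeds, so their pair must not appear
        m = _omics([rng.standard_normal(30), base, base + 0.01 * rng.standard_normal(30)],
                   ["seed", "a", "b"])
        cm = compute_seed_correlations(m, SeedSet([("seed", "expression")]), 0.05)
        assert cm.matrix[1, 2] == 0.0

    def test_null_edge_acceptance_near_p_threshold(self, rng):
        m = _omics(rng.standard_normal((100, 200)), [f"g{i}" for i in range(100)])
        seeds = SeedSet([(f"g{i}", "expression") for i in range(10)])
        cm = compute_seed_correlations(m, seeds, 0.05)
        rate = cm.n_kept / cm.n_tested
        assert 0.03 < rate < 0.07

    def test_absent_seed_skipped_with_warning(self, rng, caplog):
        m = _omics(rng.standard_normal((3, 20)), ["a", "b", "c"])
        cm = compute_seed_correlations(
            m, SeedSet([("a", "expression"), ("zzz", "expression")]), 0.05
        )
        assert cm.matrix.shape == (3, 3)

    def test_requires_normalized_matrix(self, rng):
        m = _omics(rng.standard_normal((3, 10)), ["a", "b", "c"], normalize=False)
        with pytest.raises(ValidationError):
            compute_seed_correlations(m, SeedSet([("a", "expression")]))

    def test_mask_equals_recompute_with_reduced_seed_set(self, rng):
        m = _omics(rng.standard_normal((30, 50)), [f"g{i}" for i in range(30)])
        seeds = SeedSet([(f"g{i}", "expression") for i in range(5)])
        full = compute_seed_correlations(m, seeds, 0.2)
        reduced = compute_seed_correlations(m, seeds.without(("g0", "expression")), 0.2)
        masked = mask_held_out_seed(full, "g0", {f"g{i}" for i in range(1, 5)})
        assert (masked.matrix != reduced.matrix).nnz == 0
        a, b = masked.matrix.tocoo(), reduced.matrix.tocoo()
        assert np.array_equal(a.data, b.data)


class TestSymmetricNormalize:
    @pytest.mark.parametrize(
        "matrix, expected",
        [
            ([[0, 2], [2, 0]], [[0, 1.0], [1.0, 0]]),
            ([[0, 1], [1, 0]], [[0, 1.0], [1.0, 0]]),
            (
                [[0, 1, 0], [1, 0, 1], [0, 1, 0]],  # 3-node path
                [[0, 1 / np.sqrt(2), 0], [1 / np.sqrt(2), 0, 1 / np.sqrt(2)],
                 [0, 1 / np.sqrt(2), 0]],
            ),
        ],
    )
    def test_hand_cases(self, matrix, expected):
        out = symmetric_normalize(np.array(matrix, dtype=float)).matrix.toarray()
        assert np.allclose(out, expected, atol=1e-12)

    def test_zero_row_maps_to_zero_row(self):
        M = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=float)
        out = symmetric_normalize(M).matrix.toarray()
        assert np.all(out[2] == 0) and np.all(out[:, 2] == 0)

    def test_d_regular_graph_gives_constant_one_over_d(self):
        # 4-cycle: every node has degree 2
        M = np.zeros((4, 4))
        for i in range(4):
            M[i, (i + 1) % 4] = M[(i + 1) % 4, i] = 1.0
        out = symmetric_normalize(M).matrix.toarray()
        assert np.allclose(out[M > 0], 0.5)

    def test_preserves_symmetry_and_sparsity_pattern(self, rng):
        A = sparse.random(30, 30, density=0.1, random_state=7)
        A = A + A.T
        out = symmetric_normalize(A).matrix
        assert (abs(out - out.T) > 1e-15).nnz == 0
        assert np.array_equal(sorted(zip(*A.tocoo().coords)), sorted(zip(*out.tocoo().coords)))

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValidationError):
            symmetric_normalize(np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_spectral_radius_at_most_one(self, rng):
        for _ in range(10):
            A = sparse.random(40, 40, density=0.15, random_state=rng.integers(2**31))
            A = abs(A + A.T)
            W = symmetric_normalize(A).matrix.toarray()
            assert np.abs(np.linalg.eigvalsh((W + W.T) / 2)).max() <= 1 + 1e-10


class TestFusion:
    def _nm(self, mat, ids):
        return NormalizedMatrix("x", ids, sparse.csr_matrix(np.array(mat, dtype=float)))

    @pytest.mark.parametrize(
        "pcc, ppi, expected",
        [(0.0, 0.0, 0.0), (1.0, 0.3, 1.0), (0.5, 0.5, 0.75), (0.2, 0.0, 0.2)],
    )
    def test_noisy_or_hand_cases(self, pcc, ppi, expected):
        ids = ["a", "b"]
        out = fuse_expression_edges(
            self._nm([[0, pcc], [pcc, 0]], ids), self._nm([[0, ppi], [ppi, 0]], ids)
        )
        assert out.matrix[0, 1] == pytest.approx(expected, abs=1e-12)

    @given(
        a=st.floats(0, 1, allow_nan=False),
        b=st.floats(0, 1, allow_nan=False),
        a2=st.floats(0, 1, allow_nan=False),
    )
    def test_bounded_monotone_and_dominates_max(self, a, b, a2):
        ids = ["x", "y"]
        w = fuse_expression_edges(
            self._nm([[0, a], [a, 0]], ids), self._nm([[0, b], [b, 0]], ids)
        ).matrix[0, 1]
        assert -1e-12 <= w <= 1 + 1e-12
        assert w >= max(a, b) - 1e-12
        w2 = fuse_expression_edges(
            self._nm([[0, max(a, a2)], [max(a, a2), 0]], ids),
            self._nm([[0, b], [b, 0]], ids),
        ).matrix[0, 1]
        assert w2 >= w - 1e-12

    def test_union_of_entity_ids(self):
        pcc = self._nm([[0, 0.4], [0.4, 0]], ["a", "b"])
        ppi = self._nm([[0, 0.5], [0.5, 0]], ["b", "c"])
        out = fuse_expression_edges(pcc, ppi)
        assert out.entity_ids == ["a", "b", "c"]
        i = {e: k for k, e in enumerate(out.entity_ids)}
        assert out.matrix[i["a"], i["b"]] == pytest.approx(0.4)
        assert out.matrix[i["b"], i["c"]] == pytest.approx(0.5)


class TestRegulatoryRegression:
    def _inputs(self, y, xc, xm, mir_rows=None, targets=None, samples=None):
        mir_rows = mir_rows if mir_rows is not None else np.zeros((1, len(y)))
        mirs = [f"m{i}" for i in range(len(mir_rows))]
        return dict(
            expr=_omics([y], ["g"], samples, "expression", normalize=False),
            cnv=_omics([xc], ["g"], samples, "cnv", normalize=False),
            methy=_omics([xm], ["g"], samples, "methylation", normalize=False),
            mirna=_omics(mir_rows, mirs, samples, "mirna", normalize=False),
            targets=targets or InteractionSet("mirna_target", []),
        )

    def test_exact_linear_dependence_recovered(self, rng):
        x = rng.standard_normal(50)
        fits = fit_regulatory_regression(**self._inputs(2.0 * x, x, np.zeros(50)))
        assert fits["g"].beta_cnv == pytest.approx(2.0, abs=1e-9)

    def test_planted_coefficients_recovered(self, rng):
        n = 300
        xc, xm, xr = rng.standard_normal((3, n))
        y = 1.5 * xc - 0.8 * xm + 0.5 * xr + 0.1 * rng.standard_normal(n)
        fits = fit_regulatory_regression(**self._inputs(
            y, xc, xm, mir_rows=[xr],
            targets=InteractionSet("mirna_target", [("m0", "g", 1.0)]),
        ))
        f = fits["g"]
        assert f.beta_cnv == pytest.approx(1.5, abs=0.1)
        assert f.beta_methy == pytest.approx(-0.8, abs=0.1)
        assert f.mir_betas["m0"] == pytest.approx(0.5, abs=0.1)
        assert f.residual_sd == pytest.approx(0.1, rel=0.2)

    def test_null_coefficients_are_small(self, rng):
        n = 300
        count = 0
        for _ in range(100):
            xc, xm = rng.standard_normal((2, n))
            y = rng.standard_normal(n)
            fits = fit_regulatory_regression(**self._inputs(y, xc, xm))
            f = fits["g"]
            count += max(abs(f.beta_cnv), abs(f.beta_methy)) < 0.2
        assert count >= 95

    def test_matches_normal_equations_oracle(self, rng):
        n = 40
        xc, xm, x1, x2 = rng.standard_normal((4, n))
        y = rng.standard_normal(n)
        fits = fit_regulatory_regression(**self._inputs(
            y, xc, xm, mir_rows=[x1, x2],
            targets=InteractionSet("mirna_target", [("m0", "g", 1.0), ("m1", "g", 1.0)]),
        ))
        X = np.column_stack([xc, xm, x1, x2, np.ones(n)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        f = fits["g"]
        got = [f.beta_cnv, f.beta_methy, f.mir_betas["m0"], f.mir_betas["m1"], f.intercept]
        assert np.allclose(got, beta, atol=1e-8)

    def test_gene_missing_a_layer_marked_unfit(self, rng):
        n = 20
        expr = _omics(rng.standard_normal((1, n)), ["g"], None, "expression", normalize=False)
        cnv = _omics(rng.standard_normal((1, n)), ["other"], None, "cnv", normalize=False)
        methy = _omics(rng.standard_normal((1, n)), ["g"], None, "methylation", normalize=False)
        mirna = _omics(rng.standard_normal((1, n)), ["m0"], None, "mirna", normalize=False)
        fits = fit_regulatory_regression(expr, cnv, methy, mirna,
                                         InteractionSet("mirna_target", []))
        assert fits["g"].unfit_reason == "missing_cnv"
        assert not fits["g"].fitted

    def test_fewer_samples_than_predictors_marked_unfit(self, rng):
        n = 3
        mir_rows = rng.standard_normal((5, n))
        targets = InteractionSet(
            "mirna_target", [(f"m{i}", "g", 1.0) for i in range(5)])
        fits = fit_regulatory_regression(**self._inputs(
            rng.standard_normal(n), rng.standard_normal(n), rng.standard_normal(n),
            mir_rows=mir_rows, targets=targets))
        assert fits["g"].unfit_reason == "insufficient_samples"


class TestAssembly:
    def _empty_layer(self, name, ids):
        n = len(ids)
        return NormalizedMatrix(name, ids, sparse.csr_matrix((n, n)))

    def _star_layers_coeffs(self):
        layers = {
            "expression": self._empty_layer("expression", ["g"]),
            "cnv": self._empty_layer("cnv", ["g"]),
            "methylation": self._empty_layer("methylation", ["g"]),
            "mirna": self._empty_layer("mirna", ["m"]),
        }
        coeffs = RegulatoryCoefficients({
            "g": GeneRegression("g", beta_cnv=1.0, beta_methy=-1.0,
                                mir_betas={"m": 1.0}, intercept=0.0, residual_sd=0.0)
        })
        return layers, coeffs

    def test_regulatory_star_normalization(self):
        layers, coeffs = self._star_layers_coeffs()
        net = assemble_heterogeneous_network(layers, coeffs)
        assert net.n_nodes == 4 and net.n_edges == 3
        i = net.node_index[("g", "expression")]
        w = net.wbar.toarray()
        # hub row sum 3, leaves 1 -> every edge 1/sqrt(3)
        off_hub = np.delete(np.arange(4), i)
        assert np.allclose(w[i, off_hub], 1 / np.sqrt(3))
        # signs of the regression betas never reach the edge weights
        assert net.adjacency[i, net.node_index[("g", "methylation")]] == 1.0

    def test_zero_coefficients_leave_layers_disconnected(self, rng):
        A = abs(sparse.random(3, 3, density=0.5, random_state=1))
        A = A + A.T
        A.setdiag(0); A.eliminate_zeros()
        layers = {
            "expression": NormalizedMatrix("expression", ["a", "b", "c"], A.tocsr()),
            "cnv": self._empty_layer("cnv", ["a", "b", "c"]),
            "methylation": self._empty_layer("methylation", ["a", "b", "c"]),
            "mirna": self._empty_layer("mirna", ["m"]),
        }
        coeffs = RegulatoryCoefficients({
            g: GeneRegression(g, 0.0, 0.0, {}, 0.0, 1.0) for g in "abc"})
        net = assemble_heterogeneous_network(layers, coeffs)
        coo = net.adjacency.tocoo()
        omics_of = [o for _, o in net.nodes]
        assert all(omics_of[i] == omics_of[j] for i, j in zip(*coo.coords))

    def test_isolated_node_leaves_other_entries_unchanged(self):
        layers, coeffs = self._star_layers_coeffs()
        net1 = assemble_heterogeneous_network(layers, coeffs)
        layers["mirna"] = self._empty_layer("mirna", ["m", "lonely"])
        net2 = assemble_heterogeneous_network(layers, coeffs)
        sub = [net2.node_index[nd] for nd in net1.nodes]
        assert np.allclose(net2.wbar.toarray()[np.ix_(sub, sub)], net1.wbar.toarray())

    def test_same_id_in_two_layers_is_not_a_collision(self):
        layers, coeffs = self._star_layers_coeffs()
        net = assemble_heterogeneous_network(layers, coeffs)
        assert ("g", "expression") in net.node_index
        assert ("g", "cnv") in net.node_index

    def test_unfit_gene_gets_no_interlayer_edges(self):
        layers, _ = self._star_layers_coeffs()
        coeffs = RegulatoryCoefficients({"g": GeneRegression("g", unfit_reason="missing_cnv")})
        net = assemble_heterogeneous_network(layers, coeffs)
        assert net.n_edges == 0
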