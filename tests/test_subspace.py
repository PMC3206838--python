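"""Metagene subspace fit and the projected/residual decomposition."""

import numpy as np
import pytest

from irstab import fit_subspace, split_expression
from irstab.io_prep import ValidationError

from conftest import make_study, noise_study


def correlation_eig_oracle(expr, n):
    """Brute force: form the full gene-gene correlation matrix and decompose it."""
    C = np.corrcoef(expr)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    return w[order][:n], V[:, order][:, :n]


def principal_angles(A, B):
    qa, _ = np.linalg.qr(A)
    qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.arccos(np.clip(s, -1, 1))


class TestFitSubspace:
    def test_matches_explicit_correlation_eigendecomposition(self, small_study):
        model = fit_subspace(small_study, n=4)
        w, V = correlation_eig_oracle(small_study.expr, 4)
        assert np.allclose(model.eigenvalues, w, rtol=1e-8)
        assert np.max(principal_angles(model.loadings_G, V)) < 1e-6

    def test_rank_one_structure(self, rng):
        u = rng.normal(size=40)
        v = rng.normal(size=15)
        expr = np.outer(u, v) + 1e-6 * rng.normal(size=(40, 15)) + 8
        model = fit_subspace(make_study(expr), n=1)
        # standardized rank-1 data: every gene is +-1 correlated with every
        # other, so the first eigenvalue absorbs (nearly) all of the trace
        assert model.eigenvalues[0] == pytest.approx(40, rel=1e-3)
        signs = np.sign(model.loadings_G[:, 0])
        ref = np.sign(u) * np.sign(u[np.argmax(np.abs(model.loadings_G[:, 0]))])
        assert np.array_equal(signs, ref)

    def test_trace_conservation(self, small_study):
        model = fit_subspace(small_study, n=small_study.n_samples - 1)
        assert np.sum(model.eigenvalues) == pytest.approx(small_study.n_genes,
                                                          rel=1e-6)

    def test_metagene_is_weighted_sum_of_standardized_rows(self, small_study):
        model = fit_subspace(small_study, n=3)
        Z = ((small_study.expr - model.gene_means[:, None])
             / model.gene_sds[:, None])
        assert np.allclose(model.metagene_X, model.loadings_G.T @ Z, atol=1e-10)

    def test_loadings_orthonormal_eigenvalues_sorted(self, small_study):
        model = fit_subspace(small_study, n=5)
        gram = model.loadings_G.T @ model.loadings_G
        assert np.allclose(gram, np.eye(5), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-10)
        assert np.all(model.eigenvalues >= -1e-10)

    def test_n_out_of_range(self, small_study):
        with pytest.raises(ValidationError):
            fit_subspace(small_study, n=0)
        with pytest.raises(ValidationError):
            fit_subspace(small_study, n=small_study.n_samples)

    def test_constant_genes_dropped_with_warning(self, small_study):
        expr = small_study.expr.copy()
        expr[3] = 5.0
        st = make_study(expr)
        with pytest.warns(UserWarning, match="constant gene"):
            model = fit_subspace(st, n=2)
        assert model.loadings_G.shape[0] == st.n_genes - 1
        assert not model.fitted_mask[3]


class TestSplitExpression:
    def test_reconstruction_exact(self, small_study):
        model = fit_subspace(small_study, n=4)
        d = split_expression(small_study, model)
        assert np.allclose(d.x_p + d.x_r, small_study.expr, rtol=1e-10, atol=1e-10)

    def test_residual_orthogonal_to_metagenes(self, small_study):
        model = fit_subspace(small_study, n=4)
        d = split_expression(small_study, model)
        Xc = model.metagene_X - model.metagene_X.mean(axis=1, keepdims=True)
        rc = d.x_r - d.x_r.mean(axis=1, keepdims=True)
        dots = np.abs(rc @ Xc.T)
        bound = 1e-8 * np.outer(np.linalg.norm(rc, axis=1) + 1,
                                np.linalg.norm(Xc, axis=1) + 1)
        assert np.all(dots <= bound)

    def test_variance_additivity(self, small_study):
        model = fit_subspace(small_study, n=4)
        d = split_expression(small_study, model)
        v = small_study.expr.var(axis=1)
        assert np.allclose(v, d.x_p.var(axis=1) + d.x_r.var(axis=1), rtol=1e-8)

    def test_data_inside_span_leaves_constant_residual(self, rng):
        base = noise_study(30, 12, seed=5)
        model = fit_subspace(base, n=3)
        coeff = rng.normal(size=(25, 3))
        const = rng.normal(8, 1, size=25)
        expr = coeff @ model.metagene_X + const[:, None]
        st = make_study(expr, sample_prefix="s")
        st = type(st)(st.study_id, st.expr, st.gene_ids, base.sample_ids,
                      None)  # align sample ids with the fitted model
        d = split_expression(st, model)
        centered_resid = d.x_r - d.x_r.mean(axis=1, keepdims=True)
        assert np.max(np.abs(centered_resid)) < 1e-8

    def test_orthogonal_gene_gets_zero_projection(self, rng):
        st = noise_study(30, 12, seed=6)
        model = fit_subspace(st, n=3)
        Xc = model.metagene_X - model.metagene_X.mean(axis=1, keepdims=True)
        g = rng.normal(size=12)
        g -= g.mean()
        g -= Xc.T @ np.linalg.lstsq(Xc.T, g, rcond=None)[0]  # orthogonalize
        expr = st.expr.copy()
        expr[0] = g + 8.0
        st2 = type(st)(st.study_id, expr, st.gene_ids, st.sample_ids, None)
        d = split_expression(st2, model)
        assert np.max(np.abs(d.x_p[0])) < 1e-8
        assert np.allclose(d.x_r[0], expr[0])

    def test_matches_normal_equations_oracle(self):
        st = noise_study(30, 12, seed=7)
        model = fit_subspace(st, n=3)
        d = split_expression(st, model)
        Xc = model.metagene_X - model.metagene_X.mean(axis=1, keepdims=True)
        P = Xc.T @ np.linalg.inv(Xc @ Xc.T) @ Xc   # explicit projector
        centered = st.expr - st.expr.mean(axis=1, keepdims=True)
        assert np.max(np.abs(d.x_p - centered @ P.T)) < 1e-8

    def test_projection_idempotent(self, small_study):
        model = fit_subspace(small_study, n=4)
        d = split_expression(small_study, model)
        again = make_study(d.x_p + small_study.expr.mean(axis=1, keepdims=True))
        again = type(again)(again.study_id, again.expr, again.gene_ids,
                            small_study.sample_ids, None)
        d2 = split_expression(again, model)
        assert np.allclose(d2.x_p, d.x_p, atol=1e-8)
        centered = d2.x_r - d2.x_r.mean(axis=1, keepdims=True)
        assert np.max(np.abs(centered)) < 1e-8

    def test_rotation_invariance(self, small_study, rng):
        """Only the spanned subspace matters, not the eigenvector basis."""
        model = fit_subspace(small_study, n=4)
        d = split_expression(small_study, model)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        rotated = type(model)(
            n=model.n, loadings_G=model.loadings_G @ Q,
            metagene_X=Q.T @ model.metagene_X,
            eigenvalues=model.eigenvalues, gene_means=model.gene_means,
            gene_sds=model.gene_sds, gene_ids=model.gene_ids,
            sample_ids=model.sample_ids, fitted_mask=model.fitted_mask,
        )
        d2 = split_expression(small_study, rotated)
        assert np.allclose(d2.x_p, d.x_p, atol=1e-8)
        assert np.allclose(d2.x_r, d.x_r, atol=1e-8)

    def test_sample_permutation_equivariance(self, small_study, rng):
        perm = rng.permutation(small_study.n_samples)
        permuted = small_study.subset_samples(
            [small_study.sample_ids[i] for i in perm])
        m1 = fit_subspace(small_study, n=3)
        d1 = split_expression(small_study, m1)
        m2 = fit_subspace(permuted, n=3)
        d2 = split_expression(permuted, m2)
        assert np.allclose(d2.x_p, d1.x_p[:, perm], atol=1e-6)
        assert np.allclose(d2.x_r, d1.x_r[:, perm], atol=1e-6)

    def test_sample_mismatch_errors(self, small_study):
        model = fit_subspace(small_study, n=2)
        other = noise_study(50, 20, seed=9, sample_prefix="x")
        with pytest.raises(ValidationError, match="different sample set"):
            split_expression(other, model)


def test_model_save_load_roundtrip(tmp_path, small_study):
    from irstab import SubspaceModel
    model = fit_subspace(small_study, n=3)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = SubspaceModel.load(path)
    assert loaded.n == 3
    assert np.array_equal(loaded.loadings_G, model.loadings_G)
    assert loaded.gene_ids == model.gene_ids
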