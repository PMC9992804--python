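"""Solver tests: initialization, objective, updates, convergence, reductions."""

import numpy as np
import pytest

from spidnmf import (
    FactorModel,
    Hyperparameters,
    MultiViewDataset,
    OmicsView,
    build_cross_modal_prior,
    build_laplacian,
    build_sample_adjacency,
    compare_methods,
    fit,
    generate_multiview,
    initialize_factors,
    objective,
    relative_error,
    update_step,
)
from spidnmf.priors import CrossModalPrior


def lee_seung_step(x, w, h):
    """Hand-rolled classical multiplicative NMF sweep (W first, then H,
    H using the refreshed W), the independent oracle for the zero-weight
    limit of the joint update."""
    w = w * (x @ h.T) / (w @ (h @ h.T))
    h = h * (w.T @ x) / ((w.T @ w) @ h)
    return w, h


def planted_dataset(n=24, p=(12, 16, 20), k=3, noise=0.0, seed=3):
    return generate_multiview(n=n, p=p, k=k, noise_sigma=noise, seed=seed)


def model_from(dataset, w, hs, method="jnmf", **hp_kwargs):
    hp = Hyperparameters(k=w.shape[1], alpha=0.0, **hp_kwargs)
    return FactorModel(W=w, H=tuple(hs), hyperparameters=hp, method=method)


def split_concat(h_cat, dataset):
    out, start = [], 0
    for v in dataset.views:
        out.append(h_cat[:, start : start + v.n_features])
        start += v.n_features
    return out


def graph_and_prior(dataset):
    graph = build_laplacian(build_sample_adjacency(dataset.stage_labels))
    prior = CrossModalPrior(
        a1=build_cross_modal_prior(dataset.views[0], dataset.views[1]),
        a2=build_cross_modal_prior(dataset.views[0], dataset.views[2]),
    )
    return graph, prior


class TestInitialization:
    def test_deterministic_bit_identical(self):
        ds, _ = planted_dataset()
        m1 = initialize_factors(ds, k=3)
        m2 = initialize_factors(ds, k=3)
        np.testing.assert_array_equal(m1.W, m2.W)
        for h1, h2 in zip(m1.H, m2.H):
            np.testing.assert_array_equal(h1, h2)

    def test_strictly_positive_factors(self):
        ds, _ = planted_dataset()
        m = initialize_factors(ds, k=3)
        assert (m.W > 0).all()
        assert all((h > 0).all() for h in m.H)

    def test_beats_random_initialization_on_planted_data(self):
        """SVD init reconstructs rank-k data better than random init at
        iteration 0 (the stated motivation for avoiding random starts)."""
        ds, _ = planted_dataset(noise=0.0, seed=11)
        svd_model = initialize_factors(ds, k=3)
        rng = np.random.default_rng(0)
        n = ds.n_samples
        w_rand = rng.uniform(0.01, 1.0, (n, 3))
        hs_rand = [
            rng.uniform(0.01, 1.0, (3, v.n_features)) for v in ds.views
        ]
        rand_model = model_from(ds, w_rand, hs_rand)
        assert relative_error(svd_model, ds) < relative_error(rand_model, ds)

    def test_constant_matrix_yields_finite_factors(self):
        sids = tuple(f"s{i}" for i in range(5))
        view = OmicsView("other", np.full((5, 4), 2.0), sids,
                         tuple(f"f{j}" for j in range(4)))
        ds = MultiViewDataset((view,), ("I",) * 5)
        m = initialize_factors(ds, k=2)
        assert np.isfinite(m.W).all()
        assert all(np.isfinite(h).all() and (h >= 0).all() for h in m.H)

    def test_k_too_large_rejected(self):
        ds, _ = planted_dataset(n=6, p=(4, 5, 5), k=2)
        with pytest.raises(ValueError, match="exceeds"):
            initialize_factors(ds, k=7)


class TestObjective:
    def test_exact_factorization_zero_weights_gives_zero(self):
        ds, truth = planted_dataset(noise=0.0)
        m = model_from(ds, truth.W_true, truth.H_true)
        assert objective(m, ds) == pytest.approx(0.0, abs=1e-18)

    def test_matches_entrywise_frobenius_loop(self, rng):
        """Zero-weight objective equals a brute-force entry-wise sum."""
        ds, _ = planted_dataset(noise=0.05, seed=5)
        w = rng.uniform(0.1, 1, (ds.n_samples, 3))
        hs = [rng.uniform(0.1, 1, (3, v.n_features)) for v in ds.views]
        m = model_from(ds, w, hs)
        expected = 0.0
        for x, h in zip(ds.matrices, hs):
            recon = w @ h
            for i in range(x.shape[0]):
                for j in range(x.shape[1]):
                    expected += (x[i, j] - recon[i, j]) ** 2
        assert objective(m, ds) == pytest.approx(expected, rel=1e-12)

    def test_laplacian_term_vanishes_for_stagewise_constant_rows(self, rng):
        ds, _ = planted_dataset()
        graph, prior = graph_and_prior(ds)
        stage_rows = {lab: rng.uniform(0.1, 1, 3) for lab in set(ds.stage_labels)}
        w = np.array([stage_rows[lab] for lab in ds.stage_labels])
        hs = [rng.uniform(0.1, 1, (3, v.n_features)) for v in ds.views]
        base = model_from(ds, w, hs, method="spid")
        with_beta = model_from(ds, w, hs, method="spid", beta=7.3)
        assert objective(with_beta, ds, graph=graph) == pytest.approx(
            objective(base, ds, graph=graph), rel=1e-12
        )

    def test_missing_graph_rejected_for_spid(self):
        ds, truth = planted_dataset()
        m = model_from(ds, truth.W_true, truth.H_true, method="spid", beta=1.0)
        with pytest.raises(ValueError, match="sample graph"):
            objective(m, ds)


class TestUpdateStep:
    def test_zero_weights_match_lee_seung_on_concatenated_matrix(self, rng):
        ds, _ = planted_dataset(noise=0.05, seed=9)
        n, k = ds.n_samples, 3
        w = rng.uniform(0.5, 1.5, (n, k))
        h_cat = rng.uniform(0.5, 1.5, (k, ds.concatenated().shape[1]))
        m = model_from(ds, w, split_concat(h_cat, ds))
        stepped = update_step(m, ds)
        w_ref, h_ref = lee_seung_step(ds.concatenated(), w.copy(), h_cat.copy())
        np.testing.assert_allclose(stepped.W, w_ref, atol=1e-12)
        np.testing.assert_allclose(np.hstack(stepped.H), h_ref, atol=1e-12)

    def test_exact_factorization_is_fixed_point(self):
        ds, truth = planted_dataset(noise=0.0, seed=2)
        # strictly positive factors so the update ratio is exactly 1
        w = truth.W_true + 0.05
        hs = [h + 0.05 for h in truth.H_true]
        x_views = [
            OmicsView(v.view_id, w @ h, v.sample_ids, v.feature_ids)
            for v, h in zip(ds.views, hs)
        ]
        exact_ds = MultiViewDataset(tuple(x_views), ds.stage_labels)
        m = model_from(exact_ds, w, hs)
        stepped = update_step(m, exact_ds)
        np.testing.assert_allclose(stepped.W, w, atol=1e-12)
        for h_new, h in zip(stepped.H, hs):
            np.testing.assert_allclose(h_new, h, atol=1e-12)

    def test_manual_arithmetic_single_view_rank_one(self):
        """3x2 single-view instance, k=1: next iterate computed by hand
        through the numerator/denominator formula."""
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 5.0]])
        w = np.array([[1.0], [2.0], [1.0]])
        h = np.array([[1.0, 2.0]])
        sids = ("s0", "s1", "s2")
        view = OmicsView("other", x, sids, ("f0", "f1"))
        ds = MultiViewDataset((view,), ("I", "I", "II"))
        m = model_from(ds, w, [h])
        stepped = update_step(m, ds)
        # W: numerator X @ H^T, denominator W @ (H H^T) = 5 W
        w_expected = np.array([
            [1.0 * (1 * 1 + 2 * 2) / (5 * 1)],
            [2.0 * (2 * 1 + 4 * 2) / (5 * 2)],
            [1.0 * (3 * 1 + 5 * 2) / (5 * 1)],
        ])
        np.testing.assert_allclose(stepped.W, w_expected, atol=1e-14)
        # H: numerator W_new^T X, denominator (W_new^T W_new) H
        wn = w_expected
        h_expected = h * (wn.T @ x) / ((wn.T @ wn) @ h)
        np.testing.assert_allclose(stepped.H[0], h_expected, atol=1e-14)

    def test_nonnegativity_preserved_across_iterations(self):
        ds, _ = planted_dataset(noise=0.05, seed=13)
        graph, prior = graph_and_prior(ds)
        hp = Hyperparameters(k=3, alpha=0.05, lambda1=0.1, lambda2=0.1,
                             beta=0.1, gamma1=0.01, gamma2=0.01)
        m = initialize_factors(ds, k=3, hyperparameters=hp, method="spid")
        for _ in range(25):
            m = update_step(m, ds, graph=graph, prior=prior)
            assert (m.W >= 0).all()
            assert all((h >= 0).all() for h in m.H)


class TestRelativeError:
    def test_exact_factorization_gives_zero(self):
        ds, truth = planted_dataset(noise=0.0)
        m = model_from(ds, truth.W_true, truth.H_true)
        assert relative_error(m, ds) == pytest.approx(0.0, abs=1e-12)

    def test_zero_basis_gives_one(self):
        ds, truth = planted_dataset()
        m = model_from(ds, np.zeros_like(truth.W_true), truth.H_true)
        assert relative_error(m, ds) == pytest.approx(1.0)

    def test_matches_entrywise_computation(self, rng):
        ds, _ = planted_dataset(noise=0.1, seed=21)
        w = rng.uniform(0.1, 1, (ds.n_samples, 3))
        hs = [rng.uniform(0.1, 1, (3, v.n_features)) for v in ds.views]
        m = model_from(ds, w, hs)
        x_cat = ds.concatenated()
        recon = w @ np.hstack(hs)
        num = np.sqrt(sum(
            (x_cat[i, j] - recon[i, j]) ** 2
            for i in range(x_cat.shape[0]) for j in range(x_cat.shape[1])
        ))
        den = np.sqrt(sum(x_cat[i, j] ** 2
                          for i in range(x_cat.shape[0])
                          for j in range(x_cat.shape[1])))
        assert relative_error(m, ds) == pytest.approx(num / den, rel=1e-10)
        assert relative_error(m, ds, squared=True) == pytest.approx(
            num**2, rel=1e-10
        )


class TestFit:
    def test_planted_model_recovery_noiseless(self):
        ds, _ = generate_multiview(n=30, p=(20, 25, 30), k=3,
                                   noise_sigma=0.0, seed=17)
        hp = Hyperparameters(k=3, alpha=0.0, max_iter=400, tol=1e-10)
        model, report = fit(ds, hp, method="jnmf")
        assert relative_error(model, ds) < 0.01

    def test_max_iter_zero_returns_initialization(self):
        ds, _ = planted_dataset()
        hp = Hyperparameters(k=3, max_iter=0)
        model, report = fit(ds, hp, method="jnmf")
        init = initialize_factors(ds, k=3, hyperparameters=hp, method="jnmf")
        np.testing.assert_array_equal(model.W, init.W)
        assert report.iterations_run == 0
        assert not report.converged
        assert report.relative_error_trajectory == ()

    def test_same_inputs_give_identical_trajectories(self):
        ds, _ = planted_dataset(noise=0.05)
        graph, prior = graph_and_prior(ds)
        hp = Hyperparameters(k=3, lambda1=0.01, lambda2=0.01, beta=0.01,
                             gamma1=0.01, gamma2=0.01, max_iter=40)
        _, r1 = fit(ds, hp, method="spid", graph=graph, prior=prior)
        _, r2 = fit(ds, hp, method="spid", graph=graph, prior=prior)
        assert r1.relative_error_trajectory == r2.relative_error_trajectory
        assert r1.objective_trajectory == r2.objective_trajectory

    def test_classical_limit_objective_non_increasing(self):
        """Zero-weight (Lee-Seung) limit: monotone objective descent."""
        for seed in range(5):
            ds, _ = generate_multiview(n=15, p=(8, 10, 12), k=3,
                                       noise_sigma=0.1, seed=seed)
            hp = Hyperparameters(k=3, alpha=0.0, max_iter=100, tol=1e-14)
            _, report = fit(ds, hp, method="jnmf")
            diffs = np.diff(report.objective_trajectory)
            assert (diffs <= 1e-8).all()


class TestReductionChain:
    def test_spid_with_zero_beta_matches_mdjnmf_bitwise(self):
        ds, _ = planted_dataset(noise=0.05, seed=23)
        graph, prior = graph_and_prior(ds)
        hp = Hyperparameters(k=3, alpha=0.1, lambda1=0.05, lambda2=0.05,
                             beta=0.0, gamma1=0.02, gamma2=0.02, max_iter=30,
                             tol=1e-14)
        m_spid, r_spid = fit(ds, hp, method="spid", graph=graph, prior=prior)
        m_md, r_md = fit(ds, hp, method="mdjnmf", graph=None, prior=prior)
        np.testing.assert_array_equal(m_spid.W, m_md.W)
        for h1, h2 in zip(m_spid.H, m_md.H):
            np.testing.assert_array_equal(h1, h2)
        assert r_spid.relative_error_trajectory == r_md.relative_error_trajectory

    def test_mdjnmf_with_zero_extras_matches_jnmf_bitwise(self):
        ds, _ = planted_dataset(noise=0.05, seed=29)
        hp = Hyperparameters(k=3, alpha=0.0, max_iter=30, tol=1e-14)
        m_md, _ = fit(ds, hp, method="mdjnmf")
        m_j, _ = fit(ds, hp, method="jnmf")
        np.testing.assert_array_equal(m_md.W, m_j.W)
        for h1, h2 in zip(m_md.H, m_j.H):
            np.testing.assert_array_equal(h1, h2)


class TestStagePrior:
    def test_large_beta_separates_stage_groups(self):
        """With a strong graph weight, same-stage rows of W sit closer
        together than different-stage rows."""
        ds, _ = generate_multiview(n=30, p=(15, 20, 25), k=3, n_stages=3,
                                   noise_sigma=0.1, stage_strength=0.8, seed=31)
        graph, prior = graph_and_prior(ds)
        hp = Hyperparameters(k=3, alpha=0.0, beta=5.0, max_iter=150, tol=1e-12)
        model, _ = fit(ds, hp, method="spid", graph=graph, prior=prior)
        w = model.W
        labels = np.asarray(ds.stage_labels)
        within, between = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                d = np.linalg.norm(w[i] - w[j])
                (within if labels[i] == labels[j] else between).append(d)
        assert np.mean(within) < np.mean(between)


class TestCompareMethods:
    def test_zero_weights_make_all_methods_coincide(self):
        ds, _ = planted_dataset(noise=0.05, seed=37)
        graph, prior = graph_and_prior(ds)
        hp = Hyperparameters(k=3, alpha=0.0, max_iter=25, tol=1e-14)
        table = compare_methods(ds, graph, prior, hp)
        assert len(table) == 3
        for col in table.columns:
            assert table[col].nunique() == 1

    def test_perfect_planted_data_reaches_high_correlation(self):
        ds, _ = planted_dataset(noise=0.0, seed=41)
        graph, prior = graph_and_prior(ds)
        hp = Hyperparameters(k=3, alpha=0.0, max_iter=300, tol=1e-12)
        table = compare_methods(ds, graph, prior, hp)
        corr_cols = [c for c in table.columns if c.startswith("corr_")]
        assert (table.loc["jnmf", corr_cols] > 0.99).all()

    def test_table_reproduces_individual_fits(self):
        ds, _ = planted_dataset(noise=0.05, seed=43)
        graph, prior = graph_and_prior(ds)
        hp = Hyperparameters(k=3, alpha=0.01, lambda1=0.01, lambda2=0.01,
                             beta=0.01, gamma1=0.01, gamma2=0.01, max_iter=30,
                             tol=1e-14)
        table = compare_methods(ds, graph, prior, hp)
        model, _ = fit(ds, hp, method="spid", graph=graph, prior=prior)
        assert table.loc["spid", "relative_error"] == pytest.approx(
            relative_error(model, ds), rel=1e-12
        )
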