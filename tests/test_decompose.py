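"""The decomposition solver: regularization, CV, components, spectra."""

import numpy as np
import pytest
from scipy import signal
from sklearn.base import clone

from sideobsp import (
    BlockPartition,
    IllPosedProjectionWarning,
    RegularizerSpec,
    SignalDecomposer,
    SignalDecomposerCV,
    SignalSet,
    build_design,
    cross_validate,
    equivalent_ls_solution,
    frequency_response,
    oblique_projector,
    partition,
    prbs,
    regularization_matrix,
    side_obsp,
    solve_block,
    subsystem_filters,
)
from sideobsp.decompose import _augment_intercept


class TestRegularizationMatrix:
    def test_first_difference_pattern(self):
        np.testing.assert_array_equal(
            regularization_matrix(3), [[-1, 1, 0], [0, -1, 1]]
        )
        np.testing.assert_array_equal(regularization_matrix(2), [[-1, 1]])

    def test_constants_in_nullspace(self):
        G = regularization_matrix(7)
        np.testing.assert_allclose(G @ np.full(7, 3.7), 0.0, atol=1e-12)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            regularization_matrix(1)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            RegularizerSpec(gamma=-1.0, Gamma=regularization_matrix(3))


@pytest.fixture()
def random_partition():
    rng = np.random.default_rng(0)
    shared = rng.standard_normal((60, 1))
    A_k = rng.standard_normal((60, 5)) + shared
    A_rest = rng.standard_normal((60, 8)) + shared
    y = rng.standard_normal(60)
    return BlockPartition(A_k=A_k, A_rest=A_rest, k=0), y


class TestSolveBlock:
    def test_gamma_zero_equals_unregularized_solution(self, random_partition):
        part, y = random_partition
        reg = RegularizerSpec.first_difference(5, 0.0)
        h = solve_block(part, y, reg)
        np.testing.assert_allclose(h, equivalent_ls_solution(part, y), atol=1e-8)

    def test_explicit_and_implicit_projectors_agree(self, random_partition):
        part, y = random_partition
        reg = RegularizerSpec.first_difference(5, 2.5)
        h_e = solve_block(part, y, reg, projector="explicit")
        h_i = solve_block(part, y, reg, projector="implicit")
        np.testing.assert_allclose(h_e, h_i, atol=1e-9)

    def test_penalty_dominant_limit_flattens_h(self, random_partition):
        part, y = random_partition
        G = part.A_k.T @ part.A_k
        reg = RegularizerSpec.first_difference(5, 1e12 * np.linalg.norm(G))
        h = solve_block(part, y, reg)
        assert np.abs(h - h.mean()).max() < 1e-6 * max(1.0, abs(h.mean()))

    def test_single_input_exact_recovery(self):
        rng = np.random.default_rng(1)
        s = prbs(300, seed=rng)
        h_true = np.array([0.8, 0.4, 0.1, -0.2, 0.05])
        from sideobsp import block_hankel

        A1 = block_hankel(s, 5)
        y = A1 @ h_true
        part = BlockPartition(A_k=A1, A_rest=np.empty((A1.shape[0], 0)), k=0)
        h = solve_block(part, y, RegularizerSpec.first_difference(5, 0.0))
        np.testing.assert_allclose(h, h_true, atol=1e-6)


class TestSideObsp:
    def test_noise_free_uncorrelated_recovery(self, bench_clean):
        res = side_obsp(bench_clean.sigset, p=50, gamma=0.0)
        assert np.abs(res.h - bench_clean.true_h).max() < 1e-6
        rms = np.sqrt((res.residual**2).mean())
        assert rms < 1e-8 * np.sqrt((res.y_trimmed**2).mean())
        np.testing.assert_allclose(
            res.components, bench_clean.true_components[50:], atol=1e-6
        )

    def test_correlated_recovery_beats_naive_ols(self, bench_corr_clean):
        """Oblique projection decouples shared dynamics; per-input OLS fails."""
        res = side_obsp(bench_corr_clean.sigset, p=50, gamma=0.0)
        truth = bench_corr_clean.true_components[50:]
        np.testing.assert_allclose(res.components, truth, atol=1e-6)
        design = build_design(bench_corr_clean.sigset, 50)
        err_ols = 0.0
        for k in range(3):
            part = partition(design, k)
            A = np.hstack([part.A_k, np.ones((part.A_k.shape[0], 1))])
            coef, *_ = np.linalg.lstsq(A, design.y_trimmed, rcond=None)
            err_ols += ((part.A_k @ coef[:-1] - truth[:, k]) ** 2).mean()
        assert err_ols > 1e-3  # naive projection leaks between channels

    def test_additivity_identity(self, decomp_noisy, bench_noisy):
        lhs = decomp_noisy.components.sum(axis=1) + decomp_noisy.residual
        rhs = bench_noisy.sigset.y[50:] - decomp_noisy.y_mean
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_gamma_zero_components_equal_oblique_projection(self, bench_noisy):
        """At gamma = 0 each component is the oblique projection of the output."""
        res = side_obsp(bench_noisy.sigset, p=50, gamma=0.0)
        design = build_design(bench_noisy.sigset, 50)
        y_trim = design.y_trimmed
        for k in range(3):
            part = partition(design, k)
            aug = BlockPartition(
                A_k=part.A_k,
                A_rest=_augment_intercept(part.A_rest, part.A_k.shape[0]),
                k=k,
            )
            P = oblique_projector(aug).P_oblique
            np.testing.assert_allclose(res.components[:, k], P @ y_trim, atol=1e-8)

    def test_output_as_input_is_ill_posed(self):
        rng = np.random.default_rng(2)
        x = prbs(400, seed=rng)
        y = signal.lfilter([1.0, 0.5, 0.25], [1.0], x)
        ss = SignalSet(S=np.column_stack([x, y]), y=y, names=["x", "ycopy", "y"])
        with pytest.warns(IllPosedProjectionWarning):
            side_obsp(ss, p=5, gamma=0.0)

    def test_regularization_path_smoothness_monotone(self, bench_noisy):
        from sideobsp import regularization_matrix

        G = regularization_matrix(50)
        norms = []
        for g in np.logspace(0, 6, 7):
            res = side_obsp(bench_noisy.sigset, p=50, gamma=g)
            norms.append(np.linalg.norm(G @ res.h))
        assert all(b <= a * (1 + 1e-9) for a, b in zip(norms, norms[1:]))

    def test_determinism(self, bench_noisy):
        r1 = side_obsp(bench_noisy.sigset, p=50, gamma=10.0)
        r2 = side_obsp(bench_noisy.sigset, p=50, gamma=10.0)
        assert np.array_equal(r1.h, r2.h)
        assert np.array_equal(r1.components, r2.components)


class TestEstimatorAPI:
    def test_sklearn_conventions(self, bench_clean):
        est = SignalDecomposer(order=50, gamma=0.0)
        est2 = clone(est)
        assert est2.get_params()["order"] == 50
        ss = bench_clean.sigset
        est.fit(ss.S, ss.y)
        assert est.impulse_responses_.shape == (50, 3)
        assert est.components_.shape == (974, 3)
        assert est.n_features_in_ == 3
        assert est.score(ss.S, ss.y) > 1.0 - 1e-12

    def test_predict_matches_reconstruction(self, bench_clean):
        ss = bench_clean.sigset
        est = SignalDecomposer(order=50, gamma=0.0).fit(ss.S, ss.y)
        np.testing.assert_allclose(est.predict(ss.S), ss.y[50:], atol=1e-8)

    def test_transform_on_new_data(self, bench_clean):
        ss = bench_clean.sigset
        est = SignalDecomposer(order=50, gamma=0.0).fit(ss.S, ss.y)
        comps = est.transform(ss.S[:600])
        assert comps.shape == (550, 3)

    def test_gamma_per_block(self, bench_noisy):
        ss = bench_noisy.sigset
        est = SignalDecomposer(order=50, gamma=[0.0, 5.0, 50.0]).fit(ss.S, ss.y)
        assert est.impulse_responses_.shape == (50, 3)
        with pytest.raises(ValueError):
            SignalDecomposer(order=50, gamma=[1.0, 2.0]).fit(ss.S, ss.y)


class TestCrossValidation:
    def test_true_order_selected_on_clean_data(self, bench_clean):
        p, g, trace = cross_validate(bench_clean.sigset, [30, 50, 70], [0.0], n_folds=10)
        assert p == 50
        assert g == 0.0
        assert min(t[2] for t in trace) < 1e-10 * bench_clean.sigset.y.var()

    def test_noise_selects_positive_gamma(self, bench_noisy):
        _, g, trace = cross_validate(bench_noisy.sigset, [50], "auto", n_folds=10)
        assert g > 0
        assert len(trace) == 13

    def test_training_error_monotone_in_gamma(self, bench_noisy):
        """On a fixed split the training fit improves as gamma decreases."""
        design = build_design(bench_noisy.sigset, 50)
        part = partition(design, 0)
        aug = _augment_intercept(part.A_rest, part.A_k.shape[0])
        rows = np.arange(0, 800)
        from sideobsp.projections import apply_complement

        A_k, y = part.A_k[rows], design.y_trimmed[rows]
        QA = apply_complement(aug[rows], A_k)
        Qy = apply_complement(aug[rows], y.reshape(-1, 1)).ravel()
        G = A_k.T @ QA
        b = A_k.T @ Qy
        Gam = regularization_matrix(50)
        errs = []
        for g in [1e6, 1e4, 1e2, 1.0, 0.0]:
            h = np.linalg.pinv(G + g * Gam.T @ Gam) @ b
            errs.append(((Qy - QA @ h) ** 2).sum())
        assert all(b <= a * (1 + 1e-9) for a, b in zip(errs, errs[1:]))

    def test_invalid_folds(self, bench_clean):
        with pytest.raises(ValueError):
            cross_validate(bench_clean.sigset, [50], [0.0], n_folds=1)
        with pytest.raises(ValueError):
            cross_validate(bench_clean.sigset, [], [0.0], n_folds=5)
        with pytest.raises(ValueError):
            cross_validate(bench_clean.sigset, [50], [], n_folds=5)

    def test_cv_estimator(self, bench_noisy):
        ss = bench_noisy.sigset
        est = SignalDecomposerCV(p_grid=[50], n_folds=10).fit(ss.S, ss.y)
        assert est.order_ == 50
        assert est.gamma_ > 0
        assert len(est.cv_trace_) == 13
        res = est.result_()
        assert res.cv_trace == est.cv_trace_


class TestFrequencyResponse:
    def _result_with_h(self, h):
        from sideobsp.decompose import DecompositionResult

        h = np.atleast_2d(np.asarray(h, dtype=float)).T
        n = h.shape[0]
        return DecompositionResult(
            h=h,
            components=np.zeros((4, 1)),
            residual=np.zeros(4),
            p=n,
            gamma=0.0,
            names=["x", "y"],
            fs=2.0,
        )

    def test_unit_impulse_is_flat(self):
        res = self._result_with_h([1.0, 0.0, 0.0, 0.0])
        fr = frequency_response(res, n_freq=64)
        np.testing.assert_allclose(fr.amplitude[:, 0], 1.0, atol=1e-12)
        assert fr.freqs[0] == 0.0 and fr.freqs[-1] == 1.0

    def test_two_tap_mean_closed_form(self):
        res = self._result_with_h([0.5, 0.5])
        fr = frequency_response(res, n_freq=33)
        # |H(f)| = |cos(pi f / fs)| for the 2-tap mean
        expected = np.abs(np.cos(np.pi * fr.freqs / 2.0))
        np.testing.assert_allclose(fr.amplitude[:, 0], expected, atol=1e-12)

    def test_estimated_lowpass_matches_analytic_response(self, bench_clean):
        res = side_obsp(bench_clean.sigset, p=50, gamma=0.0)
        fr = frequency_response(res, fs=2.0, n_freq=256)  # freqs in half-cycles/sample
        f1 = subsystem_filters()[0]
        analytic = f1.amplitude(fr.freqs)
        assert np.abs(fr.amplitude[:, 0] - analytic).max() < 0.02

    def test_n_freq_validation(self, decomp_noisy):
        with pytest.raises(ValueError):
            frequency_response(decomp_noisy, n_freq=10)
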