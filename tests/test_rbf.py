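import warnings

import numpy as np
import pytest

import bonerom as br
from bonerom.rbf import (
    KERNELS,
    STRICTLY_POSITIVE_DEFINITE,
    RBFInterpolant,
    denormalize_params,
    kernel_eval,
    normalize_params,
    shape_parameter_sweep,
)


class TestKernels:
    @pytest.mark.parametrize(
        "kernel,a,r,expected",
        [
            ("MQ", 3.0, 0.0, 1.0),
            ("G", 2.0, 0.5, np.exp(-1.0)),
            ("IMQ", 2.0, 0.5, 1.0 / np.sqrt(2.0)),
            ("MC0", 1.0, 1.0, np.exp(-1.0)),
            ("MC2", 1.0, 1.0, 2.0 * np.exp(-1.0)),
            ("MC4", 1.0, 1.0, 7.0 * np.exp(-1.0)),
        ],
    )
    def test_hand_evaluated_values(self, kernel, a, r, expected):
        assert kernel_eval(kernel, r, a) == pytest.approx(expected, rel=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel_eval("G", -0.1, 1.0)

    def test_unknown_kernel_and_bad_shape(self):
        with pytest.raises(KeyError):
            kernel_eval("cubic", 1.0, 1.0)
        with pytest.raises(ValueError):
            kernel_eval("G", 1.0, 0.0)

    @pytest.mark.parametrize("kernel", sorted(STRICTLY_POSITIVE_DEFINITE))
    def test_strict_kernels_yield_spd_interpolation_matrix(self, kernel):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(12, 3))
        from scipy.spatial.distance import cdist

        B = kernel_eval(kernel, cdist(X, X), 1.5)
        np.linalg.cholesky(B)  # raises if not SPD


class TestNormalisation:
    def test_bounds_map_to_unit_interval(self):
        bounds = np.array([[-1.0, 1.0], [0.0, 10.0]])
        P = np.array([[-1.0, 0.0], [1.0, 10.0], [0.0, 5.0]])
        Ph = normalize_params(P, bounds)
        assert np.allclose(Ph, [[0, 0], [1, 1], [0.5, 0.5]])

    def test_round_trip(self):
        rng = np.random.default_rng(2)
        bounds = np.array([[-3.0, 5.0], [0.1, 0.2], [-1.0, 1.0]])
        P = rng.uniform(bounds[:, 0], bounds[:, 1], size=(20, 3))
        assert np.abs(
            denormalize_params(normalize_params(P, bounds), bounds) - P
        ).max() < 1e-14

    def test_degenerate_dimension_rejected(self):
        with pytest.raises(ValueError, match="constant parameter"):
            normalize_params(np.zeros((3, 2)), np.array([[0.0, 1.0], [2.0, 2.0]]))


class TestInterpolant:
    def _training_data(self, seed=0, n=12, n_p=2):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(n, n_p))
        Y = np.column_stack([
            np.sin(X[:, 0]) + X[:, 1] ** 2,
            np.cos(X.sum(axis=1)),
        ])
        return X, Y

    @pytest.mark.parametrize("kernel", sorted(KERNELS))
    @pytest.mark.parametrize("augment", [False, True])
    def test_interpolation_conditions_at_centers(self, kernel, augment):
        X, Y = self._training_data()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            interp = RBFInterpolant(kernel=kernel, shape=1.0, augment=augment).fit(X, Y)
        resid = np.abs(interp.predict(X) - Y).max()
        assert resid < 1e-8 * max(1.0, np.abs(Y).max())

    @pytest.mark.parametrize("kernel", sorted(KERNELS))
    def test_augmented_reproduces_affine_functions(self, kernel):
        X = np.array([[0.0, 0.0], [1.0, 0.2], [0.1, 1.0], [0.8, 0.9], [0.5, 0.3]])
        y = 2.0 * X[:, 0] + 1.0 - 0.5 * X[:, 1]
        interp = RBFInterpolant(
            kernel=kernel, shape=1.0, augment=True,
            bounds=np.array([[0.0, 1.0], [0.0, 1.0]]),
        ).fit(X, y)
        X_new = np.array([[0.42, 0.77], [0.9, 0.05]])
        expect = 2.0 * X_new[:, 0] + 1.0 - 0.5 * X_new[:, 1]
        assert np.abs(interp.predict(X_new).ravel() - expect).max() < 1e-8

    def test_augmented_side_conditions_hold(self):
        X, Y = self._training_data(seed=3)
        interp = RBFInterpolant(kernel="MC2", shape=1.0, augment=True).fit(X, Y)
        from bonerom.rbf import _poly_tail

        P = _poly_tail(interp.centers_)
        assert np.abs(P.T @ interp.coef_.T).max() < 1e-8

    def test_duplicate_centers_rejected(self):
        X = np.array([[0.0, 0.0], [0.5, 0.5], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="duplicate"):
            RBFInterpolant(kernel="G", shape=1.0).fit(X, np.arange(4.0))

    def test_mq_without_augmentation_warns(self):
        X, Y = self._training_data()
        with pytest.warns(UserWarning, match="conditionally positive"):
            RBFInterpolant(kernel="MQ", shape=1.0, augment=False).fit(X, Y)

    def test_prediction_symmetric_under_reflection(self):
        """A symmetric training set predicts symmetrically: distances are all
        that matter."""
        X = np.array([[-1.0], [-0.5], [0.5], [1.0]])
        y = np.abs(X[:, 0])  # even function
        interp = RBFInterpolant(
            kernel="G", shape=1.0, augment=False,
            bounds=np.array([[-1.0, 1.0]]),
        ).fit(X, y)
        a = interp.predict([[0.3]])
        b = interp.predict([[-0.3]])
        assert np.abs(a - b).max() < 1e-10

    def test_constant_data_reproduced_everywhere(self):
        X, _ = self._training_data(n=8)
        y = np.full(8, 3.7)
        interp = RBFInterpolant(kernel="MC0", shape=0.5, augment=True).fit(X, y)
        rng = np.random.default_rng(1)
        Xq = rng.uniform(-1, 1, size=(20, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            assert np.abs(interp.predict(Xq) - 3.7).max() < 1e-10

    def test_unit_rescaling_leaves_predictions_unchanged(self):
        """Rescaling one raw dimension (e.g. mm -> m) plus matching bounds
        must not change predictions: only normalised distances enter."""
        X, Y = self._training_data(seed=7)
        bounds = np.array([[-1.0, 1.0], [-1.0, 1.0]])
        i1 = RBFInterpolant(kernel="G", shape=1.0, bounds=bounds).fit(X, Y)
        scale = np.array([1000.0, 1.0])
        i2 = RBFInterpolant(
            kernel="G", shape=1.0, bounds=bounds * scale[:, None]
        ).fit(X * scale, Y)
        Xq = np.array([[0.2, -0.4], [-0.9, 0.9]])
        assert np.abs(i1.predict(Xq) - i2.predict(Xq * scale)).max() < 1e-10

    def test_extrapolation_warns(self):
        X, Y = self._training_data()
        interp = RBFInterpolant(kernel="G", shape=1.0).fit(X, Y)
        with pytest.warns(UserWarning, match="extrapolation"):
            interp.predict([[5.0, 5.0]])

    def test_center_prediction_returns_training_column(self):
        X, Y = self._training_data(seed=11)
        interp = RBFInterpolant(kernel="IMQ", shape=2.0, augment=True).fit(X, Y)
        w = br.rbf.predict_weights(interp, X[4])
        assert np.abs(w - Y[4]).max() < 1e-8


class TestShapeSweep:
    def _smooth_problem(self):
        rng = np.random.default_rng(9)
        X_tr = np.linspace(0.0, 1.0, 9)[:, None]
        X_ho = rng.uniform(0, 1, size=(15, 1))
        f = lambda x: np.sin(3 * x[:, 0]) + 0.3 * x[:, 0] ** 2
        return (X_tr, f(X_tr)[:, None]), (X_ho, f(X_ho)[:, None])

    def test_table_covers_all_cells_and_selection_is_argmin(self):
        train, holdout = self._smooth_problem()
        a_grid = np.logspace(-2, 1, 5)
        table, sel = shape_parameter_sweep(train, holdout, a_grid=a_grid)
        assert len(table) == len(KERNELS) * len(a_grid) * 2
        assert sel["mae"] <= np.nanmin(table["mae"].values) + 1e-15

    def test_selection_matches_brute_force(self):
        train, holdout = self._smooth_problem()
        a_grid = np.logspace(-2, 1, 5)
        table, sel = shape_parameter_sweep(
            train, holdout, families=["G", "MC2"], a_grid=a_grid)
        # brute force over the same grid
        best = (np.inf, None)
        for fam in ["G", "MC2"]:
            for a in a_grid:
                for aug in (False, True):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        interp = RBFInterpolant(
                            kernel=fam, shape=float(a), augment=aug
                        ).fit(*train)
                        mae = float(np.mean(np.abs(
                            interp.predict(holdout[0]) - holdout[1])))
                    if mae < best[0] - 1e-18:
                        best = (mae, (fam, a, aug))
        assert sel["mae"] == pytest.approx(best[0], rel=1e-12)
        assert (sel["kernel"], sel["a"], sel["augmented"]) == (
            best[1][0], pytest.approx(best[1][1]), best[1][2])
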