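"""Spectra extraction, SPXY splitting, PLS, UVE, and evaluation metrics."""

import numpy as np
import pytest

from spadmap import (
    BinaryMask,
    SpectraTable,
    evaluate,
    extract_mean_reflectance,
    generate_spectra_dataset,
    pls_fit,
    pls_select_components,
    spxy_split,
    uve_select,
)
from spadmap.errors import (
    BadComponents,
    DegenerateMetric,
    DegenerateTarget,
    EmptyMask,
    TooFewSamples,
)


class TestExtractMeanReflectance:
    def test_all_ones_mask_gives_global_mean(self, tiny_cube):
        mask = BinaryMask(data=np.ones(tiny_cube.shape, np.uint8))
        vec = extract_mean_reflectance(tiny_cube, mask)
        assert len(vec) == 25  # reference profile width
        assert np.allclose(vec, tiny_cube.data.mean(axis=(0, 1)))

    def test_single_pixel_mask_returns_that_spectrum(self, tiny_cube):
        mask = np.zeros(tiny_cube.shape, np.uint8)
        mask[1, 2] = 1
        vec = extract_mean_reflectance(tiny_cube, BinaryMask(data=mask))
        assert np.allclose(vec, tiny_cube.data[1, 2, :])

    def test_empty_mask_raises(self, tiny_cube):
        with pytest.raises(EmptyMask):
            extract_mean_reflectance(
                tiny_cube, BinaryMask(data=np.zeros(tiny_cube.shape, np.uint8))
            )


def brute_force_maxmin_split(X, y, n_cal):
    """Exhaustive greedy SPXY oracle on tiny n (reimplemented from scratch)."""
    dx = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    dy = np.abs(y[:, None] - y[None, :])
    d = (dx / dx.max() if dx.max() > 0 else dx) + (dy / dy.max() if dy.max() > 0 else dy)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    chosen = sorted((int(i), int(j)))
    while len(chosen) < n_cal:
        best, best_val = None, -1.0
        for k in range(len(y)):
            if k in chosen:
                continue
            val = min(d[k][c] for c in chosen)
            if val > best_val:
                best_val, best = val, k
        chosen.append(best)
    return sorted(chosen)


class TestSpxy:
    def test_hundred_samples_split_67_33(self):
        table = generate_spectra_dataset(n=100, seed=0)
        cal, val = spxy_split(table, ratio=(2, 1))
        assert len(cal) == 67 and len(val) == 33
        assert set(cal).isdisjoint(val)
        assert set(cal) | set(val) == set(table.ids)

    def test_minimum_three_samples(self):
        table = generate_spectra_dataset(n=3, seed=1)
        cal, val = spxy_split(table, ratio=(2, 1))
        assert len(cal) == 2 and len(val) == 1
        with pytest.raises(TooFewSamples):
            spxy_split(generate_spectra_dataset(n=3, seed=1).subset(table.ids[:2]))

    def test_matches_bruteforce_maxmin_oracle(self):
        table = generate_spectra_dataset(n=12, seed=2)
        cal, _ = spxy_split(table, ratio=(2, 1))
        expect = brute_force_maxmin_split(table.X, table.y, 8)
        assert sorted(table.ids.index(s) for s in cal) == expect

    def test_permutation_stability_of_selected_points(self):
        """Shuffling sample order changes ids, not the selected X/Y points."""
        table = generate_spectra_dataset(n=20, seed=3)
        rng = np.random.default_rng(4)
        perm = rng.permutation(20)
        shuffled = SpectraTable(
            ids=[table.ids[i] for i in perm], X=table.X[perm], y=table.y[perm],
            wavelengths=table.wavelengths,
        )
        cal_a, _ = spxy_split(table)
        cal_b, _ = spxy_split(shuffled)
        assert sorted(cal_a) == sorted(cal_b)

    def test_duplicated_dataset_covers_same_range(self):
        table = generate_spectra_dataset(n=10, seed=5)
        doubled = SpectraTable(
            ids=table.ids + [f"{s}_dup" for s in table.ids],
            X=np.vstack([table.X, table.X]),
            y=np.concatenate([table.y, table.y]),
            wavelengths=table.wavelengths,
        )
        cal, _ = spxy_split(doubled, ratio=(2, 1))
        rows = doubled.subset(cal)
        assert rows.y.min() == table.y.min() and rows.y.max() == table.y.max()


class TestPls:
    def test_full_rank_equals_normal_equations(self):
        """PLS at rank(X_centered) components reproduces OLS predictions."""
        rng = np.random.default_rng(6)
        for n, p in [(12, 5), (30, 10)]:
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            model = pls_fit(X, y, n_components=p)
            Xc = X - X.mean(axis=0)
            beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
            ols_pred = y.mean() + Xc @ beta
            assert np.allclose(model.predict(X), ols_pred, atol=1e-8)

    def test_single_latent_factor_one_component_suffices(self):
        rng = np.random.default_rng(7)
        t = rng.normal(size=40)
        w = rng.normal(size=8)
        X = np.outer(t, w) + rng.normal(scale=1e-9, size=(40, 8))
        y = 3.0 * t
        model = pls_fit(X, y, n_components=1)
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse < 1e-6

    def test_contract_prediction_formula(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        m = pls_fit(X, y, 2)
        assert np.allclose(m.predict(X), m.y_mean + (X - m.x_mean) @ m.coefficients)

    def test_degenerate_inputs(self):
        X = np.random.default_rng(9).normal(size=(10, 4))
        with pytest.raises(DegenerateTarget):
            pls_fit(X, np.ones(10), 2)
        with pytest.raises(BadComponents):
            pls_fit(X, np.arange(10.0), 0)
        with pytest.raises(BadComponents):
            pls_fit(X, np.arange(10.0), 11)


class TestSelectComponents:
    def test_exact_one_factor_data_selects_one(self):
        rng = np.random.default_rng(10)
        t = rng.normal(size=30)
        X = np.outer(t, rng.normal(size=6)) + rng.normal(scale=1e-8, size=(30, 6))
        y = 2.0 * t
        best_k, rmsecv = pls_select_components(X, y, max_components=4)
        assert best_k == 1
        assert rmsecv[best_k - 1] <= rmsecv[-1]

    def test_argmin_definition(self):
        table = generate_spectra_dataset(n=30, seed=11)
        best_k, rmsecv = pls_select_components(table.X, table.y, max_components=6)
        assert rmsecv[best_k - 1] == rmsecv.min()


class TestUve:
    def test_zero_threshold_selects_everything(self):
        table = generate_spectra_dataset(n=30, seed=12)
        res = uve_select(table.X, table.y, n_components=3,
                         wavelengths=table.wavelengths, threshold=0.0)
        assert len(res.selected_indices) == table.X.shape[1]

    def test_informative_bands_survive_noise_augmented_cutoff(self):
        informative = (681.0, 849.0, 935.0)
        kept_noise = []
        for seed in range(5):
            table = generate_spectra_dataset(
                n=200, seed=seed, structure="independent", informative_bands=informative
            )
            res = uve_select(table.X, table.y, n_components=3,
                             wavelengths=table.wavelengths,
                             noise_augment=True, random_state=seed)
            got = set(res.selected_wavelengths)
            assert set(informative) <= got
            kept_noise.append(len(got - set(informative)) / 22)
        assert np.mean(kept_noise) <= 0.20

    def test_reliability_index_shape_and_default_threshold(self):
        table = generate_spectra_dataset(n=20, seed=13)
        res = uve_select(table.X, table.y, n_components=2,
                         wavelengths=table.wavelengths)
        assert res.reliability_index.shape == (25,)
        assert res.threshold == 1.0
        assert np.all(np.abs(res.reliability_index[res.selected_indices]) >= 1.0)


class TestEvaluate:
    def test_hand_arithmetic_case(self):
        # SSE = 16, SST = 5 -> R2 = -2.2; RMSE = sqrt(16/4) = 2
        m = evaluate([1, 2, 3, 4], [1, 2, 3, 8])
        assert m.r2 == pytest.approx(1 - 16 / 5)
        assert m.rmse == pytest.approx(2.0)

    def test_mean_predictor_scores_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_perfect_prediction_breaks_rpd(self):
        with pytest.raises(DegenerateMetric):
            evaluate([1, 2, 3], [1, 2, 3])

    def test_constant_truth_rejected(self):
        with pytest.raises(DegenerateTarget):
            evaluate([2, 2, 2], [1, 2, 3])

    @pytest.mark.parametrize("rpd_target,grade", [(2.5, "good"), (1.7, "middle"), (1.1, "poor")])
    def test_rpd_grading_bands(self, rpd_target, grade):
        rng = np.random.default_rng(14)
        y = rng.normal(size=200) * 8 + 40
        std = np.std(y, ddof=1)
        rmse_target = std / rpd_target
        m = evaluate(y, y + rng.choice([-1, 1], size=200) * rmse_target)
        assert m.grade == grade

    def test_shift_invariance_of_rmse(self):
        rng = np.random.default_rng(15)
        y, p = rng.normal(size=10), rng.normal(size=10)
        assert evaluate(y, p).rmse == pytest.approx(evaluate(y + 5, p + 5).rmse)

    def test_r2_never_exceeds_one(self):
        rng = np.random.default_rng(16)
        for _ in range(5):
            y = rng.normal(size=12)
            p = rng.normal(size=12)
            assert evaluate(y, p).r2 <= 1.0


class TestSpectraTable:
    def test_csv_round_trip(self, tmp_path):
        table = generate_spectra_dataset(n=8, seed=17)
        table.to_csv(tmp_path / "s.csv")
        back = SpectraTable.from_csv(tmp_path / "s.csv")
        assert back.ids == table.ids
        assert np.allclose(back.X, table.X)
        assert np.allclose(back.y, table.y)
        assert back.wavelengths == table.wavelengths
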