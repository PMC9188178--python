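import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedscreen.spa import exhaustive_best_subset, spa_chain, spa_select


def brute_force_chain(X, start, k):
    """Straight-line reference implementation of the projection recursion.

    Projects every candidate column onto the orthogonal complement of the
    chosen columns with an explicitly built orthonormal basis (numerically
    independent of the deflation scheme in ``spa_chain``).
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    chain = [start]
    for _ in range(k - 1):
        basis = np.linalg.qr(X[:, chain])[0]
        best_norm, best_idx = -1.0, None
        for j in range(p):
            if j in chain:
                continue
            resid = X[:, j] - basis @ (basis.T @ X[:, j])
            n = np.linalg.norm(resid)
            if n > best_norm + 1e-12:
                best_norm, best_idx = n, j
        if best_idx is None or best_norm < 1e-10:
            break
        chain.append(best_idx)
    return chain


class TestSpaChain:
    def test_orthogonal_columns_pick_largest_norm(self):
        # columns with norms 3 > 2 > 1, mutually orthogonal
        X = np.diag([3.0, 2.0, 1.0])
        chain = spa_chain(X, start=1, k=2)
        assert chain == [1, 0]

    def test_duplicated_column_never_selected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 4))
        X = np.column_stack([X, X[:, 1]])  # column 4 duplicates column 1
        chain = spa_chain(X, start=1, k=5)
        assert 4 not in chain

    def test_matches_brute_force_all_starts(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 6))
        for start in range(6):
            assert spa_chain(X, start, 3) == brute_force_chain(X, start, 3)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_random(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(7, 5))
        start = int(rng.integers(5))
        assert spa_chain(X, start, 4) == brute_force_chain(X, start, 4)

    def test_rank_exhaustion_truncates_with_warning(self):
        X = np.ones((5, 4))  # rank 1
        with pytest.warns(UserWarning, match="truncated"):
            chain = spa_chain(X, 0, 4)
        assert chain == [0]

    def test_bad_start_rejected(self):
        with pytest.raises(ValueError, match="start"):
            spa_chain(np.eye(3), 5, 2)


class TestSpaSelect:
    def test_exact_linear_support_recovered(self):
        rng = np.random.default_rng(2)
        Xtr = rng.normal(size=(40, 8))
        Xval = rng.normal(size=(20, 8))
        coef = np.zeros(8)
        coef[1], coef[4] = 2.0, -1.5
        ytr = 0.3 + Xtr @ coef
        yval = 0.3 + Xval @ coef
        # k_max = n_bands guarantees some chain prefix spans the support
        res = spa_select(Xtr, ytr, Xval, yval, k_min=1, k_max=8)
        assert res.rmse == pytest.approx(0.0, abs=1e-8)
        assert set(res.selected) >= {1, 4}
        oracle_rmse, oracle_subset = exhaustive_best_subset(Xtr, ytr, Xval, yval, 1, 2)
        assert oracle_subset == (1, 4)
        assert oracle_rmse == pytest.approx(0.0, abs=1e-8)

    def test_single_informative_band(self):
        rng = np.random.default_rng(3)
        Xtr = rng.normal(size=(50, 6))
        Xval = rng.normal(size=(25, 6))
        ytr = 1.0 + 3.0 * Xtr[:, 2]
        yval = 1.0 + 3.0 * Xval[:, 2]
        res = spa_select(Xtr, ytr, Xval, yval, k_min=1, k_max=1)
        assert res.selected == [2]

    def test_never_beats_exhaustive_and_matches_when_reachable(self):
        rng = np.random.default_rng(4)
        for trial in range(25):
            Xtr = rng.normal(size=(20, 7))
            Xval = rng.normal(size=(12, 7))
            ytr = rng.normal(size=20)
            yval = rng.normal(size=12)
            res = spa_select(Xtr, ytr, Xval, yval, k_min=1, k_max=3)
            oracle_rmse, oracle_subset = exhaustive_best_subset(
                Xtr, ytr, Xval, yval, 1, 3
            )
            assert res.rmse >= oracle_rmse - 1e-9
            reachable = {
                tuple(sorted(chain[:k]))
                for chain in res.chain_store.values()
                for k in range(1, len(chain) + 1)
            }
            if tuple(sorted(oracle_subset)) in reachable:
                assert res.rmse == pytest.approx(oracle_rmse, abs=1e-9)

    def test_rmse_path_non_increasing_on_noise_free_linear(self):
        rng = np.random.default_rng(5)
        Xtr = rng.normal(size=(60, 6))
        Xval = rng.normal(size=(30, 6))
        coef = np.array([1.0, 0.5, -0.7, 0.2, 0.0, 0.0])
        ytr, yval = Xtr @ coef, Xval @ coef
        res = spa_select(Xtr, ytr, Xval, yval, k_min=1, k_max=4)
        path = res.rmse_path[~np.isnan(res.rmse_path)]
        assert np.all(np.diff(path) <= 1e-9)

    def test_selected_within_band_range_and_unique(self):
        rng = np.random.default_rng(6)
        Xtr = rng.normal(size=(30, 9))
        Xval = rng.normal(size=(15, 9))
        ytr = rng.integers(0, 2, 30).astype(float)
        yval = rng.integers(0, 2, 15).astype(float)
        res = spa_select(Xtr, ytr, Xval, yval, k_min=1, k_max=5)
        assert len(set(res.selected)) == len(res.selected)
        assert all(0 <= i < 9 for i in res.selected)
        assert res.rmse == pytest.approx(np.nanmin(res.rmse_path), abs=1e-12)

    def test_wavelengths_attached(self):
        rng = np.random.default_rng(7)
        Xtr = rng.normal(size=(30, 5))
        Xval = rng.normal(size=(15, 5))
        ytr = Xtr[:, 3]
        yval = Xval[:, 3]
        wl = np.array([400.0, 500.0, 600.0, 700.0, 800.0])
        res = spa_select(Xtr, ytr, Xval, yval, k_min=1, k_max=1, wavelengths=wl)
        assert res.selected == [3]
        np.testing.assert_array_equal(res.selected_nm, [700.0])

    def test_simulator_peak_localization(self):
        # separation concentrated at one Gaussian peak: selected wavelengths
        # should cluster within +-2 FWHM of its centre
        from seedscreen.simulate import (
            default_grid,
            make_variety_spec,
            simulate_spectra,
            target_variety_spec,
        )

        grid = default_grid(4.0)
        target = target_variety_spec(seed_sigma=0.01, lot_sigma=0.0)
        # perturb only the water band (index 2): centre 980, width 24
        other = make_variety_spec(target, 0.15, seed=11, band_mask=[0, 0, 1])
        t1 = simulate_spectra(target, 1, 150, grid=grid, seed=1, category="target")
        t2 = simulate_spectra(other, 1, 150, grid=grid, seed=2, category="non-target")
        X = np.vstack([t1.spectra, t2.spectra])
        y = np.concatenate([np.ones(150), np.zeros(150)])
        rng = np.random.default_rng(12)
        perm = rng.permutation(300)
        tr, va = perm[:200], perm[200:]
        fwhm = 2.355 * 24.0
        in_window = lambda nm: np.abs(np.asarray(nm) - 980.0) <= 2 * fwhm

        res1 = spa_select(X[tr], y[tr], X[va], y[va], k_min=1, k_max=1, wavelengths=grid)
        assert in_window(res1.selected_nm).all()

        # with k_max > 1 the dominant bands sit at the peak; an occasional
        # chance-helpful noise band may join, so require a majority
        res3 = spa_select(X[tr], y[tr], X[va], y[va], k_min=1, k_max=3, wavelengths=grid)
        assert in_window(res3.selected_nm[0])
        assert in_window(res3.selected_nm).mean() >= 0.5
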