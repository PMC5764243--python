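"""Variogram decomposition identity and the three MSO spatial diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from benthoscale.dataio import CommunityMatrix, StationTable
from benthoscale.mso import (
    mantel_residual_tests,
    mso_decompose,
    scale_dependence_test,
    stationarity_check,
)
from benthoscale.rda import ExplanatoryDesign, fit_rda, province_indicators
from benthoscale.variogram import build_classes, pair_semivariances


def _site(rng, n=30, n_species=6, extent=3.0):
    counts = rng.integers(1, 30, size=(n, n_species)).astype(float)
    ids = [f"S{i}" for i in range(n)]
    comm = CommunityMatrix(sample_ids=ids,
                           species_ids=[f"sp{j}" for j in range(n_species)],
                           counts=counts)
    coords = rng.uniform(0, extent, size=(n, 2))
    stations = StationTable(sample_ids=ids, x_km=coords[:, 0],
                            y_km=coords[:, 1],
                            province=pd.Series(["A"] * (n // 2)
                                               + ["B"] * (n - n // 2),
                                               index=ids),
                            environment=pd.DataFrame(index=ids))
    return comm, stations


def _fit(comm, columns):
    return fit_rda(comm, ExplanatoryDesign(variables=columns))


class TestDecompose:
    def test_identity_with_independent_cross_term(self, rng):
        """gamma = gamma_fit + gamma_res + gamma_cross, with the cross term
        recomputed independently as twice the covariance of differences."""
        comm, stations = _site(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            classing = build_classes(stations, interval_km=0.3)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
        model = _fit(comm, X)
        mso = mso_decompose(model, classing)
        for k, pairs in enumerate(classing.pair_lists):
            if len(pairs) == 0:
                continue
            df = model.fitted[pairs[:, 0]] - model.fitted[pairs[:, 1]]
            dr = model.residual[pairs[:, 0]] - model.residual[pairs[:, 1]]
            cross_direct = np.mean(np.einsum("ij,ij->i", df, dr))
            total = mso.gamma_fit[k] + mso.gamma_res[k] + cross_direct
            assert total == pytest.approx(mso.gamma[k], abs=1e-12)
            assert mso.gamma_cross[k] == pytest.approx(cross_direct,
                                                       abs=1e-12)

    def test_saturated_model_all_fit(self, rng):
        counts = np.array([[9, 1]] * 5 + [[1, 9]] * 5, dtype=float)
        ids = [f"S{i}" for i in range(10)]
        comm = CommunityMatrix(sample_ids=ids, species_ids=["x", "y"],
                               counts=counts)
        coords = rng.uniform(0, 2, size=(10, 2))
        stations = StationTable(sample_ids=ids, x_km=coords[:, 0],
                                y_km=coords[:, 1],
                                province=pd.Series(["A"] * 5 + ["B"] * 5,
                                                   index=ids),
                                environment=pd.DataFrame(index=ids))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            classing = build_classes(stations, interval_km=0.25)
            model = _fit(comm, province_indicators(stations.province))
        mso = mso_decompose(model, classing)
        usable = classing.n_pairs > 0
        np.testing.assert_allclose(mso.gamma_res[usable], 0.0, atol=1e-12)
        np.testing.assert_allclose(mso.gamma_fit[usable], mso.gamma[usable],
                                   atol=1e-12)

    def test_intercept_only_all_residual(self, rng):
        comm, stations = _site(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            classing = build_classes(stations, interval_km=0.3)
        model = _fit(comm, pd.DataFrame(index=range(30)))
        mso = mso_decompose(model, classing)
        usable = classing.n_pairs > 0
        np.testing.assert_allclose(mso.gamma_fit[usable], 0.0, atol=1e-14)
        np.testing.assert_allclose(mso.gamma_res[usable], mso.gamma[usable],
                                   atol=1e-14)

    def test_total_cross_term_vanishes(self, rng):
        # classes covering all pairs: pair-weighted cross total is ~0 (OLS)
        comm, stations = _site(rng)
        classing = build_classes(stations, interval_km=0.4,
                                 cutoff_km=stations.h_max * 1.001)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        mso = mso_decompose(_fit(comm, X), classing)
        usable = classing.n_pairs > 0
        total = np.sum(classing.n_pairs[usable] * mso.gamma_cross[usable])
        assert abs(total) / classing.n_pairs.sum() < 1e-10

    def test_invariance_to_species_order_and_constant_species(self, rng):
        comm, stations = _site(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            classing = build_classes(stations, interval_km=0.3)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
        base = mso_decompose(_fit(comm, X), classing)

        # permute species columns
        perm = rng.permutation(comm.n_species)
        comm2 = CommunityMatrix(
            sample_ids=comm.sample_ids,
            species_ids=[comm.species_ids[j] for j in perm],
            counts=comm.counts[:, perm])
        alt = mso_decompose(_fit(comm2, X), classing)
        np.testing.assert_allclose(alt.gamma, base.gamma, atol=1e-12)
        np.testing.assert_allclose(alt.gamma_fit, base.gamma_fit, atol=1e-12)


class TestScaleDependence:
    def test_no_flags_when_cross_is_zero(self, rng):
        comm, stations = _site(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            classing = build_classes(stations, interval_km=0.3)
        mso = mso_decompose(_fit(comm, pd.DataFrame(index=range(30))),
                            classing)
        # intercept-only: cross is exactly zero everywhere
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            flags = scale_dependence_test(mso, alpha=0.05)
        assert not flags.any()

    def test_inflated_cross_flagged(self, rng):
        comm, stations = _site(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            classing = build_classes(stations, interval_km=0.3)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
        mso = mso_decompose(_fit(comm, X), classing)
        k = int(np.nanargmax(mso.classing.n_pairs))
        mso.gamma_fit[k] += 50 * mso.se[k]  # push fit+res far outside
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            flags = scale_dependence_test(mso, alpha=0.05)
        assert flags[k]

    def test_envelope_brackets_gamma(self, rng):
        comm, stations = _site(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            classing = build_classes(stations, interval_km=0.3)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
        mso = mso_decompose(_fit(comm, X), classing)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            scale_dependence_test(mso, alpha=0.05)
        t = mso.testable() & np.isfinite(mso.se)
        assert np.all(mso.ci_lower[t] <= mso.gamma[t])
        assert np.all(mso.gamma[t] <= mso.ci_upper[t])


class TestMantel:
    def test_power_against_short_range_autocorrelation(self, rng):
        # residuals that are similar only at short range: first class fires
        n = 50
        coords = rng.uniform(0, 3, size=(n, 2))
        ids = [f"S{i}" for i in range(n)]
        stations = StationTable(sample_ids=ids, x_km=coords[:, 0],
                                y_km=coords[:, 1],
                                province=pd.Series(["A"] * n, index=ids),
                                environment=pd.DataFrame(index=ids))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            classing = build_classes(stations, interval_km=0.5)
        # strongly autocorrelated field as the "residual" matrix
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(coords))
        C = np.exp(-D / 0.4)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
        resid = L @ rng.standard_normal((n, 4))
        counts = rng.integers(1, 30, size=(n, 4)).astype(float)
        comm = CommunityMatrix(sample_ids=ids,
                               species_ids=[f"sp{j}" for j in range(4)],
                               counts=counts)
        model = _fit(comm, pd.DataFrame(index=range(n)))
        model.residual = resid  # inject the structured residuals
        r, p, sig = mantel_residual_tests(model, classing, alpha=0.05,
                                          n_perm=199, rng=1)
        assert sig[0]
        assert r[0] < 0  # short-range pairs are more similar than average

    def test_permutation_reproducible_and_exchangeable(self, rng):
        comm, stations = _site(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            classing = build_classes(stations, interval_km=0.3)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
        model = _fit(comm, X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            r1, p1, _ = mantel_residual_tests(model, classing, n_perm=99,
                                              rng=7)
            r2, p2, _ = mantel_residual_tests(model, classing, n_perm=99,
                                              rng=7)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(r1, r2)

    def test_small_n_perm_rejected(self, rng):
        comm, stations = _site(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            classing = build_classes(stations, interval_km=0.3)
        model = _fit(comm, pd.DataFrame(index=range(30)))
        with pytest.raises(ValueError, match="n_perm"):
            mantel_residual_tests(model, classing, n_perm=10)


class TestStationarity:
    def _mso_with_res(self, rng, res_values):
        comm, stations = _site(rng, n=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            classing = build_classes(stations, interval_km=0.25)
        mso = mso_decompose(_fit(comm, pd.DataFrame(index=range(40))),
                            classing)
        mso.gamma_res = res_values(classing.class_centers)
        return mso

    def test_flat_residual_ok(self, rng):
        mso = self._mso_with_res(rng, lambda h: np.full_like(h, 0.3))
        assert stationarity_check(mso) is True

    def test_rising_residual_not_ok(self, rng):
        mso = self._mso_with_res(rng, lambda h: 0.1 + 0.5 * h)
        assert stationarity_check(mso) is False

    def test_too_few_classes_rejected(self, rng):
        mso = self._mso_with_res(rng, lambda h: np.full_like(h, 0.3))
        mso.gamma_res[3:] = np.nan
        with pytest.raises(ValueError, match="classes"):
            stationarity_check(mso)
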