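import warnings

import numpy as np
import pytest

from metamediation import (
    Polarity,
    fit_mediation,
    mediation_ci,
    pool_matrix,
    proportion_mediated,
    reference_pooled_matrix,
)
from metamediation.coding import CodingTable, StudyRecord
from metamediation.masem import NotPositiveDefiniteError, PooledMatrix


def random_pd_matrix(rng):
    L = rng.standard_normal((3, 3))
    S = L @ L.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    return PooledMatrix(r_xm=S[0, 1], r_xy=S[0, 2], r_my=S[1, 2], n_harmonic=500, k=5)


class TestPoolMatrix:
    def test_negative_stratum_near_published(self, ref_table):
        m = pool_matrix(ref_table, "negative")
        assert m.k == 7
        assert m.r_xm == pytest.approx(0.273, abs=0.006)
        assert m.r_xy == pytest.approx(-0.256, abs=0.006)
        assert m.r_my == pytest.approx(-0.319, abs=0.006)

    def test_positive_stratum_near_published(self, ref_table):
        m = pool_matrix(ref_table, "positive")
        assert m.k == 9
        assert m.r_xm == pytest.approx(0.263, abs=0.02)
        assert m.r_xy == pytest.approx(0.27, abs=0.02)
        assert m.r_my == pytest.approx(0.453, abs=0.02)

    def test_single_study_stratum_is_that_study(self):
        table = CodingTable(
            records=[
                StudyRecord(
                    study_id="solo", n=200, indicator_name="anxiety",
                    polarity="negative", r_pa_re=0.2, r_pa_mh=-0.3, r_re_mh=-0.4,
                )
            ]
        )
        m = pool_matrix(table, "negative")
        assert m.r_xm == pytest.approx(0.2, abs=1e-12)
        assert m.r_xy == pytest.approx(-0.3, abs=1e-12)
        assert m.r_my == pytest.approx(-0.4, abs=1e-12)
        assert m.n_harmonic == 200

    def test_harmonic_n(self, ref_table):
        m = pool_matrix(ref_table, "negative")
        ns = [rec.n for rec in ref_table if rec.polarity is Polarity.NEGATIVE]
        assert m.n_harmonic == pytest.approx(len(ns) / sum(1.0 / n for n in ns))

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError, match="no studies"):
            pool_matrix(CodingTable(records=[]), "positive")

    def test_non_positive_definite_rejected(self):
        with pytest.raises(NotPositiveDefiniteError):
            PooledMatrix(r_xm=0.9, r_xy=0.9, r_my=-0.9, n_harmonic=100, k=3)


class TestFitMediation:
    def test_published_positive_matrix(self):
        fit = fit_mediation(reference_pooled_matrix("positive"))
        assert abs(round(fit.a * 1000) - 263) <= 1
        assert abs(round(fit.b * 1000) - 411) <= 1
        assert abs(round(fit.ab * 1000) - 108) <= 1
        assert abs(round(fit.c * 1000) - 161) <= 1
        assert abs(round(fit.d * 1000) - 269) <= 1

    def test_published_negative_matrix(self):
        fit = fit_mediation(reference_pooled_matrix("negative"))
        assert abs(round(fit.b * 1000) + 270) <= 1
        assert abs(round(fit.ab * 1000) + 74) <= 1
        assert abs(round(fit.c * 1000) + 182) <= 1
        assert abs(round(fit.d * 1000) + 256) <= 1

    def test_independence_gives_zero_paths(self):
        m = PooledMatrix(r_xm=0.0, r_xy=0.0, r_my=0.0, n_harmonic=100, k=3)
        fit = fit_mediation(m)
        assert fit.a == fit.b == fit.c == fit.ab == 0.0

    def test_saturated_identities(self):
        rng = np.random.default_rng(7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(25):
                m = random_pd_matrix(rng)
                fit = fit_mediation(m)
                assert fit.d == pytest.approx(fit.ab + fit.c, abs=1e-12)
                assert fit.d == pytest.approx(m.r_xy, abs=1e-12)

    def test_ml_agrees_with_closed_form(self):
        rng = np.random.default_rng(11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(100):
                m = random_pd_matrix(rng)
                cf = fit_mediation(m)
                ml = fit_mediation(m, method="ml")
                assert ml.a == pytest.approx(cf.a, abs=1e-8)
                assert ml.b == pytest.approx(cf.b, abs=1e-8)
                assert ml.c == pytest.approx(cf.c, abs=1e-8)

    def test_saturated_fit_block(self):
        fit = fit_mediation(reference_pooled_matrix("positive"), method="ml")
        assert fit.fit.chi2 < 1e-6
        assert fit.fit.df == 0
        assert fit.fit.cfi == 1.0
        assert fit.fit.tli == 1.0
        assert fit.fit.rmsea == 0.0


class TestMediationCI:
    def test_monte_carlo_reproducible(self):
        m = reference_pooled_matrix("positive")
        ci1 = mediation_ci(m, reps=5000, seed=3)
        ci2 = mediation_ci(m, reps=5000, seed=3)
        assert ci1 == ci2

    def test_zero_matrix_straddles_zero(self):
        m = PooledMatrix(
            r_xm=0.0, r_xy=0.0, r_my=0.0, n_harmonic=1000, k=5,
            se_z={"xm": 0.01, "xy": 0.01, "my": 0.01},
        )
        ci = mediation_ci(m, reps=5000, seed=1)
        assert ci["ab"][0] < 0 < ci["ab"][1]

    def test_delta_close_to_monte_carlo(self):
        m = reference_pooled_matrix("positive")
        mc = mediation_ci(m, method="monte_carlo", reps=200_000, seed=5)
        delta = mediation_ci(m, method="delta")
        for name in ("a", "b", "c", "ab"):
            width = mc[name][1] - mc[name][0]
            assert delta[name][0] == pytest.approx(mc[name][0], abs=0.15 * width)
            assert delta[name][1] == pytest.approx(mc[name][1], abs=0.15 * width)

    def test_doubling_reps_is_stable(self):
        m = reference_pooled_matrix("positive")
        ci1 = mediation_ci(m, reps=50_000, seed=9)
        ci2 = mediation_ci(m, reps=100_000, seed=9)
        for name in ("a", "b", "c", "ab"):
            assert ci2[name][0] == pytest.approx(ci1[name][0], abs=0.005)
            assert ci2[name][1] == pytest.approx(ci1[name][1], abs=0.005)

    def test_contract_errors(self):
        m = reference_pooled_matrix("positive")
        with pytest.raises(ValueError, match="seed"):
            mediation_ci(m, reps=5000)
        with pytest.raises(ValueError, match="reps"):
            mediation_ci(m, reps=10, seed=1)
        with pytest.raises(ValueError, match="method"):
            mediation_ci(m, method="bootstrap", seed=1)
        bare = PooledMatrix(r_xm=0.2, r_xy=0.2, r_my=0.3, n_harmonic=100, k=3)
        with pytest.raises(ValueError, match="standard errors"):
            mediation_ci(bare, seed=1)


class TestProportionMediated:
    def test_published_values_from_rounded_paths(self):
        assert proportion_mediated(0.108, 0.269) == pytest.approx(40.15, abs=0.01)
        assert proportion_mediated(-0.074, -0.256) == pytest.approx(28.91, abs=0.01)

    def test_sign_safe(self):
        assert proportion_mediated(-0.074, -0.256) > 0

    def test_zero_indirect(self):
        assert proportion_mediated(0.0, 0.3) == 0.0

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError):
            proportion_mediated(0.1, 0.0)

    def test_inconsistent_mediation_warns(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            value = proportion_mediated(0.5, 0.2)
        assert value == pytest.approx(250.0)
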