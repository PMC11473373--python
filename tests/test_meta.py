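import math
import shutil
import subprocess

import numpy as np
import pytest

from metamediation import effects_from_table, heterogeneity, pool_fixed, pool_random
from metamediation.meta import tau2_reml

from conftest import make_effects


def brute_force_random(effects):
    """Direct-summation oracle for Q, DL tau^2 and the random-effects mean."""
    z = [e.z for e in effects]
    v = [e.v for e in effects]
    w = [1.0 / vi for vi in v]
    zbar = sum(wi * zi for wi, zi in zip(w, z)) / sum(w)
    Q = sum(wi * (zi - zbar) ** 2 for wi, zi in zip(w, z))
    c = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (Q - (len(z) - 1)) / c)
    ws = [1.0 / (vi + tau2) for vi in v]
    zstar = sum(wi * zi for wi, zi in zip(ws, z)) / sum(ws)
    return Q, tau2, zstar


class TestPoolFixed:
    def test_single_effect_passthrough(self):
        (eff,) = make_effects([0.4], [0.2])
        zbar, var = pool_fixed([eff])
        assert zbar == pytest.approx(0.4, abs=1e-15)
        assert var == pytest.approx(0.04, abs=1e-15)

    def test_equal_weights_average(self):
        effs = make_effects([0.2, 0.4], [0.1, 0.1])
        zbar, _ = pool_fixed(effs)
        assert zbar == pytest.approx(0.3, abs=1e-15)

    def test_hand_inverse_variance(self):
        # w = 1, 1, 2 -> zbar = (0 + 0 + 2*0.4)/4 = 0.2
        effs = make_effects([0.0, 0.0, 0.4], [1.0, 1.0, math.sqrt(0.5)])
        zbar, _ = pool_fixed(effs)
        assert zbar == pytest.approx(0.2, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed([])


class TestHeterogeneity:
    def test_identical_effects(self):
        effs = make_effects([0.3, 0.3, 0.3], [0.1, 0.1, 0.1])
        het = heterogeneity(effs)
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.I2 == 0.0
        assert het.tau2 == 0.0

    def test_hand_q(self):
        # equal unit weights, z = 0 and 2: zbar = 1, Q = 1 + 1 = 2
        effs = make_effects([0.0, 2.0], [1.0, 1.0])
        het = heterogeneity(effs)
        assert het.Q == pytest.approx(2.0, abs=1e-12)
        assert het.df == 1

    def test_requires_two(self):
        with pytest.raises(ValueError):
            heterogeneity(make_effects([0.1], [0.1]))

    def test_reference_negative_stratum(self, neg_stratum):
        het = heterogeneity(effects_from_table(neg_stratum, "re_mh"))
        assert het.Q == pytest.approx(22.667, abs=0.01)
        assert het.I2 == pytest.approx(73.53, abs=0.05)


class TestPoolRandom:
    @pytest.mark.parametrize(
        "zs, ses",
        [
            ([0.1, 0.5, 0.3], [0.2, 0.1, 0.3]),
            ([0.0, 0.0, 0.4, -0.2], [1.0, 1.0, 0.5, 0.8]),
            ([-0.3, 0.9], [0.15, 0.4]),
        ],
    )
    def test_matches_brute_force_oracle(self, zs, ses):
        effs = make_effects(zs, ses)
        Q, tau2, zstar = brute_force_random(effs)
        pooled = pool_random(effs)
        assert pooled.Q == pytest.approx(Q, abs=1e-12)
        assert pooled.tau2 == pytest.approx(tau2, abs=1e-12)
        assert pooled.z_pooled == pytest.approx(zstar, abs=1e-12)

    def test_zero_tau2_coincides_with_fixed(self):
        effs = make_effects([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])
        pooled = pool_random(effs)
        zbar, var = pool_fixed(effs)
        assert pooled.tau2 == 0.0
        assert pooled.z_pooled == pytest.approx(zbar, abs=1e-14)
        assert pooled.se_z == pytest.approx(math.sqrt(var), abs=1e-14)

    def test_pooled_within_input_range(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            k = rng.integers(2, 8)
            zs = rng.normal(0.2, 0.5, k)
            ses = rng.uniform(0.05, 0.5, k)
            pooled = pool_random(make_effects(zs, ses))
            assert zs.min() - 1e-12 <= pooled.z_pooled <= zs.max() + 1e-12
            assert pooled.ci_low < pooled.r_pooled < pooled.ci_high

    def test_duplicating_a_study_narrows_ci(self):
        effs = make_effects([0.1, 0.3, 0.5], [0.1, 0.1, 0.1])
        base = pool_random(effs)
        more = pool_random(effs + make_effects([0.3], [0.1]))
        assert (more.ci_high - more.ci_low) < (base.ci_high - base.ci_low)

    def test_single_study(self):
        (eff,) = make_effects([0.4], [0.1])
        pooled = pool_random([eff])
        assert pooled.k == 1
        assert pooled.z_pooled == pytest.approx(0.4)
        assert pooled.se_z == pytest.approx(0.1)
        assert pooled.df == 0

    def test_reference_negative_stratum_values(self, neg_stratum):
        re_ni = pool_random(effects_from_table(neg_stratum, "re_mh"))
        assert re_ni.r_pooled == pytest.approx(-0.321, abs=0.005)
        assert re_ni.ci_low == pytest.approx(-0.360, abs=0.005)
        assert re_ni.ci_high == pytest.approx(-0.280, abs=0.005)
        pa_ni = pool_random(effects_from_table(neg_stratum, "pa_mh"))
        assert pa_ni.r_pooled == pytest.approx(-0.259, abs=0.005)

    def test_reml_close_to_dl_on_balanced_data(self):
        effs = make_effects([0.1, 0.4, 0.25, 0.6], [0.1, 0.1, 0.1, 0.1])
        dl = pool_random(effs, tau2_estimator="dl")
        reml = pool_random(effs, tau2_estimator="reml")
        # balanced designs: REML and DL agree closely
        assert reml.tau2 == pytest.approx(dl.tau2, rel=0.2, abs=0.005)
        assert tau2_reml(make_effects([0.3], [0.1])) == 0.0


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_dl_pooling_matches_metafor(neg_stratum):
    """Independent oracle: metafor's rma(method='DL') on the same z/v inputs."""
    effs = effects_from_table(neg_stratum, "re_mh")
    zi = ",".join(repr(e.z) for e in effs)
    vi = ",".join(repr(e.v) for e in effs)
    script = (
        f"suppressMessages(library(metafor));"
        f"m <- rma(c({zi}), c({vi}), method='DL');"
        f"cat(sprintf('%.10f %.10f %.10f', coef(m), m$QE, m$tau2))"
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    beta, Q, tau2 = (float(x) for x in out.stdout.split())
    pooled = pool_random(effs)
    assert pooled.z_pooled == pytest.approx(beta, abs=1e-8)
    assert pooled.Q == pytest.approx(Q, abs=1e-8)
    assert pooled.tau2 == pytest.approx(tau2, abs=1e-8)
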