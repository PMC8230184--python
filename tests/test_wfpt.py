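"""First-passage-time density, absorption probabilities, CDF and simulator.

The series density is cross-checked against an independent route: the
Euler-Maruyama simulator with bridge correction, plus closed forms where
they exist.
"""

import numpy as np
import pytest
from scipy.integrate import quad

import refback as rb
from refback.params import DDMParams, ParameterError
from refback.wfpt import _cdf_grid


PARAM_GRID = [
    DDMParams(v=1.0, a=1.0, z=0.5, t0=0.3),
    DDMParams(v=2.5, a=1.5, z=0.4, t0=0.25, sv=1.0),
    DDMParams(v=0.5, a=0.8, z=0.6, t0=0.2, sz=0.3),
    DDMParams(v=-1.5, a=1.2, z=0.5, t0=0.35, sv=0.8, sz=0.2),
]


class TestDensity:
    def test_zero_before_nondecision_time(self):
        p = DDMParams(v=1.0, a=1.0, t0=0.3)
        assert rb.fpt_density(p.t0 - 0.01, "upper", p) == 0.0
        assert rb.fpt_density(p.t0 - 0.01, "lower", p) == 0.0
        assert rb.fpt_density(p.t0, "upper", p) == 0.0

    def test_symmetry_at_zero_drift(self):
        p = DDMParams(v=0.0, a=1.0, z=0.5, t0=0.2)
        ts = np.linspace(0.21, 2.0, 25)
        np.testing.assert_allclose(
            rb.fpt_density(ts, "upper", p), rb.fpt_density(ts, "lower", p), rtol=1e-9
        )

    def test_nonnegative(self):
        for p in PARAM_GRID:
            ts = np.linspace(p.t0 - 0.1, 5.0, 200)
            assert np.all(rb.fpt_density(ts, "upper", p) >= 0.0)
            assert np.all(rb.fpt_density(ts, "lower", p) >= 0.0)

    @pytest.mark.parametrize("p", PARAM_GRID, ids=lambda p: f"v{p.v}_sv{p.sv}_sz{p.sz}")
    def test_normalization(self, p):
        """Upper plus lower defective mass integrates to one within 1e-4."""
        total = rb.defective_cdf(200.0, "upper", p) + rb.defective_cdf(200.0, "lower", p)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_matches_euler_simulation_histogram(self):
        """Series density agrees with a brute-force Euler histogram."""
        p = DDMParams(v=1.0, a=1.0, z=0.5, t0=0.3)
        n = 200_000
        up, rt = rb.simulate_choice_rt(p, n, seed=42, dt=2e-4)
        edges = np.arange(0.3, 1.5, 0.05)
        hist, _ = np.histogram(rt[up], bins=edges)
        observed = hist / n
        # expected bin mass from the integrated density (defective CDF)
        cdf_vals = rb.defective_cdf(edges, "upper", p)
        expected = np.diff(cdf_vals)
        se = np.sqrt(np.maximum(expected * (1 - expected) / n, 1e-12))
        assert np.all(np.abs(observed - expected) < 4 * se + 5e-4)

    def test_non_finite_t_rejected(self):
        p = DDMParams(v=1.0, a=1.0)
        with pytest.raises(ValueError):
            rb.fpt_density(np.nan, "upper", p)

    def test_invalid_boundary_rejected(self):
        with pytest.raises(ValueError):
            rb.fpt_density(0.5, "top", DDMParams(v=1.0, a=1.0))


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(v=1.0, a=-1.0),
            dict(v=1.0, a=1.0, z=0.0),
            dict(v=1.0, a=1.0, z=1.2),
            dict(v=1.0, a=1.0, t0=-0.1),
            dict(v=1.0, a=1.0, sv=-0.5),
            dict(v=1.0, a=1.0, z=0.1, sz=0.4),
            dict(v=1.0, a=1.0, dc=0.5),
            dict(v=1.0, a=1.0, st0=0.1),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            DDMParams(**kwargs)


class TestBoundaryProbability:
    def test_symmetric_diffusion_is_half(self):
        p = DDMParams(v=0.0, a=1.0, z=0.5)
        assert rb.boundary_probability("upper", p) == pytest.approx(0.5)

    @pytest.mark.parametrize("p", PARAM_GRID, ids=lambda p: f"v{p.v}_sv{p.sv}_sz{p.sz}")
    def test_conservation(self, p):
        up = rb.boundary_probability("upper", p)
        lo = rb.boundary_probability("lower", p)
        assert 0.0 <= up <= 1.0
        assert up + lo == pytest.approx(1.0, abs=1e-12)

    def test_matches_simulation(self):
        p = DDMParams(v=2.0, a=1.0, z=0.5)
        up, _ = rb.simulate_choice_rt(p, 200_000, seed=9, dt=2e-4)
        prob = rb.boundary_probability("upper", p)
        se = np.sqrt(prob * (1 - prob) / up.size)
        assert abs(up.mean() - prob) < 3 * se + 1e-3

    def test_closed_form_biased_diffusion(self):
        # P(upper) = (1 - e^{-2 v a z}) / (1 - e^{-2 v a}) for sv = sz = 0
        p = DDMParams(v=1.5, a=1.2, z=0.35)
        expected = np.expm1(-2 * p.v * p.a * p.z) / np.expm1(-2 * p.v * p.a)
        assert rb.boundary_probability("upper", p) == pytest.approx(expected, rel=1e-9)


class TestDefectiveCDF:
    def test_zero_at_t0_and_limit(self):
        p = DDMParams(v=1.0, a=1.0, z=0.5, t0=0.3, sv=0.5)
        assert rb.defective_cdf(p.t0, "upper", p) == 0.0
        assert rb.defective_cdf(500.0, "upper", p) == pytest.approx(
            rb.boundary_probability("upper", p), abs=2e-4
        )

    def test_nondecreasing(self):
        p = DDMParams(v=1.0, a=1.2, z=0.45, t0=0.25, sz=0.2)
        ts = np.linspace(0.0, 4.0, 100)
        vals = rb.defective_cdf(ts, "upper", p)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_equals_quadrature_of_density(self):
        p = DDMParams(v=1.2, a=1.0, z=0.55, t0=0.3, sv=0.7)
        t = 0.9
        expected = quad(lambda u: rb.fpt_density(u, "lower", p), p.t0, t, limit=200)[0]
        assert rb.defective_cdf(t, "lower", p) == pytest.approx(expected, abs=1e-5)


class TestSimulator:
    def test_rts_exceed_t0(self):
        p = DDMParams(v=1.0, a=1.0, t0=0.4, sv=1.0, sz=0.3)
        _, rt = rb.simulate_choice_rt(p, 2000, seed=3)
        assert rt.min() > p.t0

    def test_reproducible(self):
        p = DDMParams(v=1.0, a=1.0, t0=0.3)
        a1 = rb.simulate_choice_rt(p, 500, seed=77)
        a2 = rb.simulate_choice_rt(p, 500, seed=77)
        np.testing.assert_array_equal(a1[0], a2[0])
        np.testing.assert_array_equal(a1[1], a2[1])

    def test_rejects_bad_n(self):
        with pytest.raises(ValueError):
            rb.simulate_choice_rt(DDMParams(v=1.0, a=1.0), 0, seed=1)

    @pytest.mark.parametrize("p", PARAM_GRID[:2], ids=["plain", "sv"])
    def test_ks_distance_against_density(self, p):
        """Conditional RT distribution matches the normalized defective CDF."""
        up, rt = rb.simulate_choice_rt(p, 100_000, seed=13, dt=2e-4)
        grid, cdf = _cdf_grid(p, "upper")
        rts = np.sort(rt[up])
        emp = np.arange(1, rts.size + 1) / rts.size
        theo = np.interp(rts, grid, cdf) / cdf[-1]
        assert np.abs(emp - theo).max() < 0.01


class TestInvariants:
    def test_t0_shift_additivity(self):
        """Shifting t0 shifts every quantile by exactly that amount and
        leaves choice probabilities unchanged."""
        base = DDMParams(v=1.5, a=1.1, z=0.45, t0=0.25, sv=0.6, sz=0.2)
        delta = 0.15
        shifted = DDMParams(v=1.5, a=1.1, z=0.45, t0=0.25 + delta, sv=0.6, sz=0.2)
        qs = [0.1, 0.5, 0.9]
        q0 = rb.conditional_quantiles(qs, "upper", base)
        q1 = rb.conditional_quantiles(qs, "upper", shifted)
        np.testing.assert_allclose(q1 - q0, delta, atol=1e-3)
        assert rb.boundary_probability("upper", base) == pytest.approx(
            rb.boundary_probability("upper", shifted)
        )

    def test_drift_monotonicity(self):
        """Higher drift magnitude: more accurate and faster correct medians."""
        accs, meds = [], []
        for v in (0.5, 1.5, 3.0):
            p = DDMParams(v=v, a=1.2, z=0.5, t0=0.3)
            accs.append(rb.boundary_probability("upper", p))
            meds.append(rb.conditional_quantiles([0.5], "upper", p)[0])
        assert accs == sorted(accs)
        assert meds == sorted(meds, reverse=True)

    def test_threshold_monotonicity(self):
        """Higher threshold: more accurate but slower."""
        accs, meds = [], []
        for a in (0.8, 1.2, 1.8):
            p = DDMParams(v=1.5, a=a, z=0.5, t0=0.3)
            accs.append(rb.boundary_probability("upper", p))
            meds.append(rb.conditional_quantiles([0.5], "upper", p)[0])
        assert accs == sorted(accs)
        assert meds == sorted(meds)


class TestLogLikelihood:
    def test_single_trial_equals_log_density(self):
        import pandas as pd

        p = DDMParams(v=1.0, a=1.0, t0=0.3)
        df = pd.DataFrame({"rt": [0.8], "response": ["same"], "cell": [1]})
        expected = np.log(rb.fpt_density(0.8, "upper", p))
        assert rb.log_likelihood(df, {1: p}) == pytest.approx(expected)

    def test_additivity_over_disjoint_sets(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        p = {1: DDMParams(v=1.0, a=1.0, t0=0.3), 2: DDMParams(v=2.0, a=1.2, t0=0.25)}
        df = pd.DataFrame(
            {
                "rt": rng.uniform(0.4, 1.5, 30),
                "response": rng.choice(["same", "different"], 30),
                "cell": rng.choice([1, 2], 30),
            }
        )
        whole = rb.log_likelihood(df, p)
        parts = rb.log_likelihood(df.iloc[:11], p) + rb.log_likelihood(df.iloc[11:], p)
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_floor_keeps_result_finite(self):
        import pandas as pd

        p = DDMParams(v=1.0, a=1.0, t0=0.3)
        df = pd.DataFrame({"rt": [0.301], "response": ["same"], "cell": [1]})
        ll = rb.log_likelihood(df, {1: p})
        assert np.isfinite(ll)
        assert ll >= np.log(1e-10)

    def test_missing_cell_params_raise(self):
        import pandas as pd

        df = pd.DataFrame({"rt": [0.8], "response": ["same"], "cell": [3]})
        with pytest.raises(KeyError):
            rb.log_likelihood(df, {1: DDMParams(v=1.0, a=1.0)})

    def test_generating_params_beat_distorted_params(self):
        """Simulated data prefer their generating parameters over a
        doubled-drift distortion in nearly every replicate."""
        import pandas as pd

        p_true = DDMParams(v=1.5, a=1.2, t0=0.3)
        p_bad = DDMParams(v=3.0, a=1.2, t0=0.3)
        wins = 0
        n_rep = 40
        for rep in range(n_rep):
            up, rt = rb.simulate_choice_rt(p_true, 200, seed=1000 + rep, dt=5e-4)
            df = pd.DataFrame(
                {"rt": rt, "response": np.where(up, "same", "different"), "cell": 1}
            )
            if rb.log_likelihood(df, {1: p_true}) > rb.log_likelihood(df, {1: p_bad}):
                wins += 1
        assert wins >= int(0.95 * n_rep)
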