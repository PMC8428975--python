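import itertools

import numpy as np
import pandas as pd
import pytest

from gliasim.lme import (
    bootstrap_sd_cis,
    fit_h2,
    fit_h3,
    fit_h4,
    fit_lme,
    hypothesis_fits,
    removal_contrast,
    response_surface,
)


def balanced_oneway_reml(y, n_groups, n_per):
    """Closed-form REML for the balanced one-way random-intercept model."""
    y = np.asarray(y).reshape(n_groups, n_per)
    gm = y.mean(axis=1)
    grand = y.mean()
    msb = n_per * ((gm - grand) ** 2).sum() / (n_groups - 1)
    msw = ((y - gm[:, None]) ** 2).sum() / (n_groups * (n_per - 1))
    sig_b2 = max(0.0, (msb - msw) / n_per)
    return grand, np.sqrt(sig_b2), np.sqrt(msw)


def simulate_oneway(rng, n_groups=8, n_per=10, mu=2.0, sd_b=0.5, sd_w=0.3):
    u = rng.normal(0, sd_b, n_groups)
    y = mu + np.repeat(u, n_per) + rng.normal(0, sd_w, n_groups * n_per)
    return pd.DataFrame({"y": y, "g": np.repeat(np.arange(n_groups), n_per)})


class TestRemlOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_closed_form_balanced_oneway(self, seed):
        rng = np.random.default_rng(seed)
        df = simulate_oneway(rng)
        mu, sb, sw = balanced_oneway_reml(df["y"], 8, 10)
        fit = fit_lme(df, "y", "1", "g", re_formula="1",
                      sd_names={"intercept": "sd_b"})
        assert fit.fixed["Intercept"] == pytest.approx(mu, rel=1e-6)
        assert fit.sd["sd_b"] == pytest.approx(sb, rel=1e-6)
        assert fit.sd["residual"] == pytest.approx(sw, rel=1e-6)

    def test_degenerate_constant_response(self):
        df = pd.DataFrame({"y": np.full(30, 5.0),
                           "g": np.repeat(np.arange(6), 5)})
        fit = fit_lme(df, "y", "1", "g", re_formula="1",
                      sd_names={"intercept": "sd_b"})
        assert fit.fixed["Intercept"] == pytest.approx(5.0)
        assert fit.sd["sd_b"] == 0.0 and fit.sd["residual"] == 0.0
        assert fit.boundary


class TestPolynomialRecovery:
    def test_h3_noise_free_exact(self):
        beta = {"Intercept": 10.0, "w_f": 2.0, "w_g": -3.0,
                "wf2": 0.5, "wg2": 1.5, "wfg": -0.7}
        rows = []
        for net in range(9):
            for wf, wg in itertools.product((1.0, 0.5, 0.25), repeat=2):
                z = (beta["Intercept"] + beta["w_f"] * wf + beta["w_g"] * wg
                     + beta["wf2"] * wf**2 + beta["wg2"] * wg**2
                     + beta["wfg"] * wf * wg)
                rows.append({"Z_spike": z, "network": f"n{net}",
                             "w_f": wf, "w_g": wg})
        fit = fit_h3(pd.DataFrame(rows), "Z_spike")
        for k, v in beta.items():
            assert fit.fixed[k] == pytest.approx(v, abs=1e-6)

    def test_h4_noise_free_exact(self):
        beta = {"Intercept": 4.0, "y_in": 1.0, "y_ex": -2.0,
                "yin2": 0.3, "yex2": 0.9, "yinex": -0.4}
        rows = []
        for net in range(9):
            for yi, ye in itertools.product((0.1, 0.5, 0.6, 0.7),
                                            (0.7, 0.8, 0.9)):
                z = (beta["Intercept"] + beta["y_in"] * yi + beta["y_ex"] * ye
                     + beta["yin2"] * yi**2 + beta["yex2"] * ye**2
                     + beta["yinex"] * yi * ye)
                rows.append({"Z_burst": z, "network": f"n{net}",
                             "y_in": yi, "y_ex": ye})
        fit = fit_h4(pd.DataFrame(rows), "Z_burst")
        for k, v in beta.items():
            assert fit.fixed[k] == pytest.approx(v, abs=1e-6)


class TestRemovalContrast:
    def _table(self, rng, shift, sd_res=0.05):
        rows = []
        for k in range(9):
            base = np.exp(rng.normal(4.0, 0.2))
            for rep in range(5):
                noise = np.exp(rng.normal(0, sd_res))
                rows.append({"Z_spike": base * noise, "condition": "default",
                             "instance": f"d{k}"})
        for k in range(27):
            base = np.exp(rng.normal(4.0, 0.2)) * np.exp(shift)
            for rep in range(5):
                noise = np.exp(rng.normal(0, sd_res))
                rows.append({"Z_spike": base * noise,
                             "condition": "astro_removed",
                             "instance": f"r{k}"})
        return pd.DataFrame(rows)

    def test_identical_data_zero_reduction(self):
        rng = np.random.default_rng(0)
        df = self._table(rng, shift=0.0, sd_res=0.01)
        rc = removal_contrast(df, "Z_spike")
        assert abs(rc.delta_rem_pct) < 15.0  # no systematic effect
        assert rc.p_value > 1e-6

    def test_exact_log2_shift_gives_50_percent(self):
        # reduced rows are exactly half the default rows, instance by instance
        rng = np.random.default_rng(1)
        rows = []
        for k in range(12):
            base = np.exp(rng.normal(4.0, 0.2, size=5))
            for v in base:
                rows.append({"Z_spike": v, "condition": "default",
                             "instance": f"d{k}"})
            for v in base * 0.5:
                rows.append({"Z_spike": v, "condition": "astro_removed",
                             "instance": f"r{k}"})
        rc = removal_contrast(pd.DataFrame(rows), "Z_spike")
        assert rc.delta_rem_pct == pytest.approx(50.0, abs=1e-5)

    def test_large_shift_significant_and_back_transform(self):
        rng = np.random.default_rng(2)
        df = self._table(rng, shift=np.log(1 - 0.66))
        rc = removal_contrast(df, "Z_spike")
        assert rc.p_value < 1e-10
        assert 50.0 < rc.delta_rem_pct < 80.0
        lo, hi = rc.delta_rem_ci
        assert lo < rc.delta_rem_pct < hi <= 100.0
        assert rc.sigma_rem_norm_pct > 0

    def test_missing_default_rows_error(self):
        df = pd.DataFrame({"Z_spike": [1.0], "condition": ["astro_removed"],
                           "instance": ["a"]})
        with pytest.raises(ValueError, match="default"):
            removal_contrast(df, "Z_spike")

    def test_zero_response_under_log_names_rows(self):
        df = pd.DataFrame({
            "Z_spike": [1.0, 0.0, 2.0, 1.5],
            "condition": ["default", "default", "astro_removed", "astro_removed"],
            "instance": ["a", "a", "b", "b"],
        })
        with pytest.raises(ValueError, match="log"):
            removal_contrast(df, "Z_spike")


def simulate_h2_table(rng, mu=4.0, b_a=-9.0, b_a2=57.0,
                      sd_mu=0.3, sd_a=2.0, sd_res=0.1, n_reps=10):
    grid = (0.01, 0.025, 0.05, 0.075, 0.1)
    rows = []
    for net in range(9):
        u_mu = rng.normal(0, sd_mu)
        u_a = rng.normal(0, sd_a)
        for ya in grid:
            for rep in range(n_reps):
                logz = (mu + u_mu + (b_a + u_a) * ya + b_a2 * ya**2
                        + rng.normal(0, sd_res))
                rows.append({"Z_spike": np.exp(logz), "network": f"n{net}",
                             "y_astro": ya})
    return pd.DataFrame(rows)


class TestHypothesisFits:
    def test_h2_recovers_generating_parameters(self):
        rng = np.random.default_rng(3)
        fit = fit_h2(simulate_h2_table(rng), "Z_spike")
        assert fit.transform == "log"
        assert fit.fixed["Intercept"] == pytest.approx(4.0, abs=0.5)
        assert fit.fixed["ya"] == pytest.approx(-9.0, abs=3.0)
        assert fit.sd["residual"] == pytest.approx(0.1, abs=0.03)

    def test_h2_coverage_of_fixed_effects(self):
        """Wald 95 % CIs cover the generating fixed effects at a rate in
        [90 %, 99 %] over repeated simulated experiments."""
        truth = {"Intercept": 4.0, "ya": -9.0, "ya2": 57.0}
        rng = np.random.default_rng(4)
        n_rep = 100
        covered = {k: 0 for k in truth}
        for _ in range(n_rep):
            fit = fit_h2(simulate_h2_table(rng), "Z_spike")
            for k, v in truth.items():
                lo, hi = fit.fixed_ci[k]
                covered[k] += lo <= v <= hi
        for k, c in covered.items():
            assert 90 <= c <= 99, f"coverage for {k}: {c}/100"

    def test_h2_bias_small(self):
        rng = np.random.default_rng(5)
        ests = []
        for _ in range(30):
            fit = fit_h2(simulate_h2_table(rng), "Z_spike")
            ests.append([fit.fixed["Intercept"], fit.fixed["ya"],
                         fit.fixed["ya2"]])
        mean = np.mean(ests, axis=0)
        truth = np.array([4.0, -9.0, 57.0])
        assert np.all(np.abs(mean - truth) < 0.05 * np.abs(truth))

    def test_h4_zero_network_variance_at_boundary(self):
        rng = np.random.default_rng(6)
        rows = []
        for net in range(9):
            for yi, ye in itertools.product((0.1, 0.5, 0.6, 0.7),
                                            (0.7, 0.8, 0.9)):
                z = 100 + 10 * yi + 20 * ye + rng.normal(0, 1.0)
                rows.append({"Z_spike": z, "network": f"n{net}",
                             "y_in": yi, "y_ex": ye})
        fit = fit_h4(pd.DataFrame(rows), "Z_spike")
        assert fit.sd["sd_net"] < 0.5  # generator had no network effect

    def test_hypothesis_fits_table_layout(self):
        rng = np.random.default_rng(7)
        table = simulate_h2_table(rng, n_reps=3)
        for resp in ("Z_burst", "Z_astro"):
            table[resp] = table["Z_spike"]
        fits = hypothesis_fits(table, "H2")
        assert set(fits) == {"Z_spike", "Z_burst", "Z_astro"}
        for fit in fits.values():
            assert {"Intercept", "ya", "ya2"} <= set(fit.fixed)
            assert {"sd_mu", "sd_a", "residual"} <= set(fit.sd)


class TestResponseSurface:
    def test_flat_surface_for_intercept_only(self):
        rows = []
        rng = np.random.default_rng(8)
        for net in range(9):
            for wf, wg in itertools.product((1.0, 0.5, 0.25), repeat=2):
                rows.append({"Z_spike": 7.0, "network": f"n{net}",
                             "w_f": wf, "w_g": wg})
        fit = fit_h3(pd.DataFrame(rows), "Z_spike")
        grid = pd.DataFrame({"w_f": [0.3, 0.8], "w_g": [0.5, 1.0]})
        surf = response_surface(fit, grid)
        assert np.allclose(surf["predicted"], 7.0, atol=1e-8)

    def test_polynomial_evaluation_at_unit_point(self):
        beta = {"Intercept": 1.0, "w_f": 2.0, "w_g": 3.0,
                "wf2": 4.0, "wg2": 5.0, "wfg": 6.0}
        rows = []
        for net in range(9):
            for wf, wg in itertools.product((1.0, 0.5, 0.25), repeat=2):
                z = (beta["Intercept"] + beta["w_f"] * wf + beta["w_g"] * wg
                     + beta["wf2"] * wf**2 + beta["wg2"] * wg**2
                     + beta["wfg"] * wf * wg)
                rows.append({"Z_spike": z, "network": f"n{net}",
                             "w_f": wf, "w_g": wg})
        fit = fit_h3(pd.DataFrame(rows), "Z_spike")
        surf = response_surface(fit, pd.DataFrame({"w_f": [1.0], "w_g": [1.0]}))
        assert surf["predicted"].iloc[0] == pytest.approx(sum(beta.values()))

    def test_symmetry_iff_coefficients_equal(self):
        fit_sym = fit_h3(_symmetric_h3_table(), "Z_spike")
        a = response_surface(fit_sym, pd.DataFrame({"w_f": [0.3], "w_g": [0.9]}))
        b = response_surface(fit_sym, pd.DataFrame({"w_f": [0.9], "w_g": [0.3]}))
        assert a["predicted"].iloc[0] == pytest.approx(b["predicted"].iloc[0])


def _symmetric_h3_table():
    rows = []
    for net in range(9):
        for wf, wg in itertools.product((1.0, 0.5, 0.25), repeat=2):
            z = 5.0 + 2.0 * (wf + wg) + 1.0 * (wf**2 + wg**2) + 0.5 * wf * wg
            rows.append({"Z_spike": z, "network": f"n{net}",
                         "w_f": wf, "w_g": wg})
    return pd.DataFrame(rows)


def test_bootstrap_sd_cis_bracket_estimates():
    rng = np.random.default_rng(9)
    df = simulate_oneway(rng, n_groups=9, n_per=10, sd_b=0.5, sd_w=0.3)
    df = df.rename(columns={"g": "network"})
    fit = fit_lme(df, "y", "1", "network", re_formula="1",
                  sd_names={"intercept": "sd_net"})
    cis = bootstrap_sd_cis(df, fit, n_boot=60, seed=11)
    lo, hi = cis["sd_net"]
    assert lo <= fit.sd["sd_net"] <= hi
    lo, hi = cis["residual"]
    assert lo <= fit.sd["residual"] <= hi
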