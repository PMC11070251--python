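"""Zero-inflated mixed models: likelihood oracle, fitting, comparison,
effect predictions and pseudo-R^2."""

import json
import math
import shutil
import subprocess
import textwrap
from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom, poisson

from moonchorus import (
    ComparisonError,
    CountRecord,
    FitResult,
    ModelError,
    ModelSpec,
    ParameterError,
    SiteConfig,
    akaike_table,
    compare,
    default_truth,
    fit,
    generate_schedule,
    percent_change,
    predict_effects,
    pseudo_r2,
    simulate_counts,
    zi_loglik,
)
from moonchorus.synthdata import SimTruth

T0 = pd.Timestamp("2019-02-01T18:00:00-05:00")


def _recs(species, counts, moons, sites=None):
    sites = sites or ["S1"] * len(counts)
    return [
        CountRecord(st, T0, sp, int(c), moon=float(m))
        for st, sp, c, m in zip(sites, species, counts, moons)
    ]


def naive_zi_loglik(y, mu, pi, theta):
    """Independent term-by-term summation using scipy pmfs."""
    total = 0.0
    for yi, mui in zip(y, mu):
        if theta is None:
            f = poisson.pmf(yi, mui)
            f0 = poisson.pmf(0, mui)
        else:
            p = theta / (theta + mui)
            f = nbinom.pmf(yi, theta, p)
            f0 = nbinom.pmf(0, theta, p)
        if yi == 0:
            total += math.log(pi + (1 - pi) * f0)
        else:
            total += math.log((1 - pi) * f)
    return total


class TestZiLoglik:
    @pytest.mark.parametrize("family,theta", [("zip", None), ("zinb", 0.7),
                                              ("zinb", 3.0)])
    @pytest.mark.parametrize("pi", [0.0, 0.3])
    def test_matches_naive_summation_oracle(self, rng, family, theta, pi):
        for _ in range(20):
            n = 10
            species = rng.choice(["a", "b"], n)
            moons = rng.random(n)
            counts = rng.integers(0, 9, n)
            recs = _recs(species, counts, moons)
            beta = {
                "intercept[a]": 0.4,
                "intercept[b]": 1.1,
                "moon[a]": -0.5,
                "moon[b]": 0.2,
            }
            spec = ModelSpec(
                ("intercept", "species", "moon", "species_moon"), (), family
            )
            got = zi_loglik(
                {"beta": beta, "zi_prob": pi, "theta": theta}, recs, spec
            )
            mu = np.exp(
                np.where(species == "a", 0.4, 1.1)
                + np.where(species == "a", -0.5, 0.2) * moons
            )
            want = naive_zi_loglik(counts, mu, pi, theta)
            assert got == pytest.approx(want, abs=1e-10)

    def test_conditional_on_supplied_random_effects(self, rng):
        n = 10
        species = rng.choice(["a", "b"], n)
        sites = list(rng.choice(["S1", "S2"], n))
        moons = rng.random(n)
        counts = rng.integers(0, 6, n)
        recs = _recs(species, counts, moons, sites)
        beta = {"intercept[a]": 0.3, "intercept[b]": 0.8,
                "moon[a]": 0.1, "moon[b]": -0.4}
        u_site = {"S1": 0.35, "S2": -0.2}
        spec = ModelSpec(("intercept", "species", "moon", "species_moon"),
                         ("site",), "zinb")
        got = zi_loglik(
            {"beta": beta, "zi_prob": 0.2, "theta": 1.5,
             "random_effects": {"site": [u_site["S1"], u_site["S2"]]}},
            recs, spec,
        )
        mu = np.exp(
            np.where(species == "a", 0.3, 0.8)
            + np.where(species == "a", 0.1, -0.4) * moons
            + np.array([u_site[s] for s in sites])
        )
        assert got == pytest.approx(naive_zi_loglik(counts, mu, 0.2, 1.5),
                                    abs=1e-10)

    def test_zero_inflation_zero_reduces_to_plain_family(self, rng):
        counts = rng.integers(0, 7, 20)
        recs = _recs(["a"] * 20, counts, np.zeros(20))
        spec = ModelSpec(("intercept",), (), "zip")
        got = zi_loglik({"beta": [0.9], "zi_prob": 0.0}, recs, spec)
        assert got == pytest.approx(
            poisson.logpmf(counts, math.exp(0.9)).sum(), abs=1e-10
        )

    def test_degenerate_point_mass_on_all_zero_data(self):
        recs = _recs(["a"] * 5, [0] * 5, np.zeros(5))
        spec = ModelSpec(("intercept",), (), "zip")
        assert zi_loglik({"beta": [1.0], "zi_prob": 1.0}, recs, spec) == 0.0

    def test_invalid_theta_rejected(self):
        recs = _recs(["a"] * 3, [1, 2, 0], np.zeros(3))
        spec = ModelSpec(("intercept",), (), "zinb")
        with pytest.raises(ParameterError):
            zi_loglik({"beta": [0.5], "zi_prob": 0.1, "theta": -1.0}, recs, spec)

    def test_wrong_beta_length_rejected(self):
        recs = _recs(["a", "b"], [1, 2], [0.0, 0.5])
        with pytest.raises(ParameterError):
            zi_loglik({"beta": [0.5], "zi_prob": 0.1, "theta": 1.0}, recs,
                      ModelSpec(("intercept", "species"), (), "zinb"))


class TestFit:
    def test_poisson_intercept_only_closed_form(self, rng):
        counts = rng.poisson(5.0, 400) + 1  # no zeros: inflation -> 0
        recs = _recs(["a"] * 400, counts, np.zeros(400))
        res = fit(recs, ModelSpec(("intercept",), (), "zip"))
        assert res.converged
        assert res.zi_prob < 1e-3
        assert res.coefficients["intercept"] == pytest.approx(
            math.log(counts.mean()), abs=1e-3
        )

    def test_aic_identity(self, rng):
        counts = rng.poisson(2.0, 200)
        recs = _recs(["a"] * 200, counts, np.zeros(200))
        res = fit(recs, ModelSpec(("intercept",), (), "zip"))
        assert res.aic == pytest.approx(2 * res.n_params - 2 * res.loglik,
                                        abs=1e-9)

    def test_matches_statsmodels_zinb_without_random_effects(self, rng):
        """Dual-route check: our profiled optimizer against statsmodels'
        zero-inflated negative binomial on the same design."""
        from statsmodels.discrete.count_model import (
            ZeroInflatedNegativeBinomialP,
        )

        n = 600
        moons = rng.random(n)
        species = rng.choice(["a", "b"], n)
        mu = np.exp(1.0 + 0.5 * (species == "b") - 0.6 * moons)
        y = rng.poisson(rng.gamma(1.2, mu / 1.2))
        y[rng.random(n) < 0.3] = 0
        recs = _recs(species, y, moons)
        ours = fit(recs, ModelSpec(("intercept", "species", "moon"), (), "zinb"))
        X = np.column_stack([np.ones(n), (species == "b").astype(float), moons])
        sm_res = ZeroInflatedNegativeBinomialP(
            y, X, exog_infl=np.ones((n, 1)), p=2
        ).fit(disp=0, maxiter=500)
        assert ours.converged
        assert ours.loglik == pytest.approx(sm_res.llf, abs=0.01)
        assert ours.coefficients["moon"] == pytest.approx(sm_res.params[3],
                                                          abs=0.01)

    def test_matches_glmmtmb_with_random_intercepts(self, rng, tmp_path):
        """Independent oracle for the Laplace likelihood: glmmTMB on a
        small grouped ZINB dataset."""
        n_site, n_per = 8, 120
        rows = []
        u_site = rng.normal(0, 0.5, n_site)
        for s in range(n_site):
            moons = rng.random(n_per)
            mu = np.exp(0.8 - 0.5 * moons + u_site[s])
            y = rng.poisson(rng.gamma(1.5, mu / 1.5))
            y[rng.random(n_per) < 0.25] = 0
            rows += [(f"G{s}", float(m), int(v)) for m, v in zip(moons, y)]
        df = pd.DataFrame(rows, columns=["site", "moon", "y"])
        recs = [
            CountRecord(r.site, T0, "sp", r.y, moon=r.moon)
            for r in df.itertuples()
        ]
        ours = fit(recs, ModelSpec(("intercept", "moon"), ("site",), "zinb"))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{csv}")
            m <- glmmTMB(y ~ moon + (1|site), ziformula=~1, family=nbinom2,
                         data=d)
            cat(jsonlite::toJSON(list(ll=as.numeric(logLik(m)),
                moon=as.numeric(fixef(m)$cond[2]),
                theta=sigma(m),
                var=as.numeric(VarCorr(m)$cond$site[1,1]))))
            """
        )
        out = subprocess.run(
            [shutil.which("Rscript") or "Rscript", "-e", script],
            capture_output=True, text=True, timeout=300,
        )
        assert out.returncode == 0, out.stderr
        ref = {k: v[0] for k, v in json.loads(out.stdout).items()}
        assert ours.loglik == pytest.approx(ref["ll"], abs=0.5)
        assert ours.coefficients["moon"] == pytest.approx(ref["moon"], abs=0.05)
        assert ours.theta == pytest.approx(ref["theta"], rel=0.1)
        assert ours.variance_components["site"] == pytest.approx(
            ref["var"], abs=0.05
        )

    def test_candidate_models_df_structure(self, four_sites, four_site_schedule):
        truth = default_truth(seed=3, theta=None)
        recs, _ = simulate_counts(truth, four_site_schedule[:520], four_sites)
        fits = [
            fit(recs, spec)
            for spec in (
                ModelSpec.full("zip"),
                ModelSpec.no_interaction("zip"),
                ModelSpec.species_only("zip"),
            )
        ]
        n_species = len(truth.species)
        assert fits[0].n_params - fits[1].n_params == n_species - 1
        assert fits[1].n_params - fits[2].n_params == 1

    def test_single_species_with_species_terms_rejected(self):
        recs = _recs(["a"] * 10, [1] * 10, np.linspace(0, 1, 10))
        with pytest.raises(ModelError):
            fit(recs, ModelSpec(("intercept", "species"), (), "zip"))

    def test_missing_moon_covariate_rejected(self):
        recs = [CountRecord("S1", T0, s, 1) for s in "ab"]
        with pytest.raises(ModelError):
            fit(recs, ModelSpec(("intercept", "species", "moon"), (), "zip"))


class TestRecovery:
    def _small_truth(self, seed=0):
        return SimTruth(
            species=("up", "flat", "down"),
            log_rates={"up": 1.2, "flat": 1.2, "down": 1.2},
            moon_slopes={"up": 0.8, "flat": 0.0, "down": -0.8},
            zi_prob=0.2,
            theta=None,
            variance_components={"time_block": 0.05, "site": 0.05,
                                 "species_site": 0.05,
                                 "species_time_block": 0.05},
            seed=seed,
        )

    def test_moon_slope_signs_recovered(self, four_sites, four_site_schedule):
        truth = self._small_truth(seed=11)
        recs, _ = simulate_counts(truth, four_site_schedule, four_sites)
        res = fit(recs, ModelSpec.full("zip"))
        assert res.converged
        assert res.coefficients["moon[up]"] > 0.3
        assert res.coefficients["moon[down]"] < -0.3
        assert abs(res.coefficients["moon[flat]"]) < 0.3

    def test_dropping_interaction_from_interaction_data_raises_aic(
        self, four_sites, four_site_schedule
    ):
        truth = self._small_truth(seed=12)
        recs, _ = simulate_counts(truth, four_site_schedule, four_sites)
        full = fit(recs, ModelSpec.full("zip"))
        reduced = fit(recs, ModelSpec.no_interaction("zip"), start_from=full)
        assert reduced.aic > full.aic


class TestComparison:
    def test_daic_and_weights(self):
        comp = akaike_table([100.0, 104.0], [5, 4], ["m1", "m2"])
        assert [e.d_aic for e in comp.entries] == [0.0, 4.0]
        w = [e.weight for e in comp.entries]
        assert sum(w) == pytest.approx(1.0)
        assert w[0] / w[1] == pytest.approx(math.exp(2.0))
        assert comp.best.label == "m1"

    def test_identical_aics_give_equal_weights(self):
        comp = akaike_table([50.0, 50.0, 50.0], [3, 3, 3])
        assert [e.weight for e in comp.entries] == pytest.approx([1 / 3] * 3)

    def test_differing_record_counts_rejected(self):
        f1 = FitResult(ModelSpec.full(), {}, {}, 0.1, 1.0, -10.0, 5, 30.0,
                       True, 100, ("a", "b"))
        f2 = FitResult(ModelSpec.no_interaction(), {}, {}, 0.1, 1.0, -11.0, 4,
                       30.0, True, 99, ("a", "b"))
        with pytest.raises(ComparisonError):
            compare([f1, f2])


class TestEffects:
    def _fit_result(self, pi=0.2):
        coefs = {
            "intercept[a]": 1.0, "intercept[b]": 0.5,
            "moon[a]": -0.4, "moon[b]": 0.3,
        }
        return FitResult(ModelSpec.full(), coefs, {}, pi, 1.0, -10.0, 6,
                         32.0, True, 100, ("a", "b"))

    def test_population_predictions_and_delta(self):
        effects = predict_effects(self._fit_result(), 0.0, 1.0)
        by_sp = {e.species: e for e in effects}
        assert by_sp["a"].pred_new_moon == pytest.approx(0.8 * math.exp(1.0))
        assert by_sp["a"].pred_full_moon == pytest.approx(0.8 * math.exp(0.6))
        for e in effects:
            assert e.delta == pytest.approx(e.pred_new_moon - e.pred_full_moon)
            assert e.percent_change == pytest.approx(
                100 * e.delta / e.pred_new_moon
            )

    def test_sign_convention(self):
        # activity increasing with moonlight gives a negative percent change
        e = {x.species: x for x in predict_effects(self._fit_result(), 0, 1)}
        assert e["a"].percent_change > 0  # calling declines under moonlight
        assert e["b"].percent_change < 0

    def test_equal_predictions_give_zero_change(self):
        assert percent_change(4.42, 4.42) == 0.0

    def test_zero_new_moon_prediction_is_missing(self):
        assert percent_change(0.0, 1.0) is None


class TestPseudoR2:
    def test_zero_fixed_variation_gives_zero(self):
        res = FitResult(
            ModelSpec(("intercept", "species"), (), "zip"),
            {"intercept[a]": 1.0, "intercept[b]": 1.0}, {}, 0.0, None,
            -10.0, 3, 26.0, True, 20, ("a", "b"),
        )
        recs = _recs(["a", "b"] * 10, [1] * 20, np.linspace(0, 1, 20))
        assert pseudo_r2(res, recs) == 0.0

    def test_strong_effect_with_tiny_noise_approaches_one(self, rng):
        n = 800
        moons = np.tile(np.linspace(0, 1, n // 2), 2)
        species = np.repeat(["a", "b"], n // 2)
        mu = np.exp(2.0 + np.where(species == "a", 3.0, -3.0) * moons)
        recs = _recs(species, rng.poisson(mu), moons)
        res = fit(recs, ModelSpec.full("zip"))
        assert pseudo_r2(res, recs) > 0.8

    def test_per_species_scope_restricts_to_moon_variation(self):
        res = self_res = FitResult(
            ModelSpec.full(), {"intercept[a]": 1.0, "intercept[b]": 5.0,
                               "moon[a]": -0.4, "moon[b]": 0.0},
            {}, 0.0, None, -10.0, 6, 32.0, True, 20, ("a", "b"),
        )
        recs = _recs(["a", "b"] * 10, [1] * 20,
                     np.tile(np.linspace(0, 1, 10), 2))
        r2_b = pseudo_r2(res, recs, scope="per_species", species="b")
        r2_a = pseudo_r2(res, recs, scope="per_species", species="a")
        assert r2_b == 0.0      # flat slope: no fixed-effect variation
        assert r2_a > 0.0


class TestModelSpecValidation:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(ModelError):
            ModelSpec(("intercept", "species_moon"), (), "zinb")

    def test_intercept_required(self):
        with pytest.raises(ModelError):
            ModelSpec(("species",), (), "zinb")

    def test_unknown_family_rejected(self):
        with pytest.raises(ModelError):
            ModelSpec(("intercept",), (), "gaussian")
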