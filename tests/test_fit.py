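"""Model fitting: date GLMs, Firth logistic, season model, gene fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from multistress import (
    ConfigurationError,
    DegenerateFitError,
    InputError,
    SimulationConfig,
    binarize_occurrence,
    fit_date_glm,
    fit_firth_logistic,
    fit_gene_models,
    fit_season_model,
    simulate_survey,
)


def make_survey(values_by_cell, day=0, response="x", n_per_cell=None):
    """Build a long survey table from per-cell value lists.

    ``values_by_cell`` maps (site, warming) -> list of plate values.
    """
    rows = []
    plate = 0
    for (site, warm), vals in values_by_cell.items():
        for v in vals:
            rows.append({
                "plate_id": f"P{plate}", "site": site, "warming": warm,
                "day": day, "response": response, "value": float(v),
            })
            plate += 1
    return pd.DataFrame(rows)


CELLS = [
    ("non_polluted", "ambient"), ("non_polluted", "warmed"),
    ("polluted", "ambient"), ("polluted", "warmed"),
]


class TestBinarize:
    def test_positive_values_become_one(self):
        df = make_survey({c: [0, 2, 0.5] for c in CELLS})
        out = binarize_occurrence(df, "x")
        assert set(out["value"].unique()) == {0.0, 1.0}
        # fractional abundances count as presence
        assert out.loc[df["value"] == 0.5, "value"].eq(1.0).all()

    def test_other_responses_untouched(self):
        df = pd.concat([
            make_survey({c: [3, 0] for c in CELLS}, response="x"),
            make_survey({c: [7, 9] for c in CELLS}, response="y"),
        ], ignore_index=True)
        out = binarize_occurrence(df, "x")
        pd.testing.assert_frame_equal(
            out[out["response"] == "y"].reset_index(drop=True),
            df[df["response"] == "y"].reset_index(drop=True),
        )

    def test_all_zero_warns(self):
        df = make_survey({c: [0, 0] for c in CELLS})
        with pytest.warns(UserWarning, match="absent everywhere"):
            binarize_occurrence(df, "x")

    def test_negative_value_errors(self):
        df = make_survey({c: [1, -2] for c in CELLS})
        with pytest.raises(InputError):
            binarize_occurrence(df, "x")


class TestDateGLM:
    def test_saturated_log_fit_matches_closed_form(self):
        """With one parameter per cell the NB log-link MLE equals the log
        cell means, so the contrasts have an exact closed-form oracle."""
        means = {
            ("non_polluted", "ambient"): 20.0, ("non_polluted", "warmed"): 10.0,
            ("polluted", "ambient"): 160.0, ("polluted", "warmed"): 120.0,
        }
        # balanced integer-valued cells with exact means and some spread
        df = make_survey({
            c: [m - 2, m - 1, m, m, m + 1, m + 2] for c, m in means.items()
        })
        fit = fit_date_glm(df, "x", 0, family="count_nb")
        la = {c: np.log(m) for c, m in means.items()}
        ref = la[("non_polluted", "ambient")]
        assert fit.alpha == pytest.approx(ref, abs=1e-6)
        assert fit.beta_w == pytest.approx(
            la[("non_polluted", "warmed")] - ref, abs=1e-6)
        assert fit.beta_p == pytest.approx(
            la[("polluted", "ambient")] - ref, abs=1e-6)
        assert fit.beta_int == pytest.approx(
            la[("polluted", "warmed")] - la[("polluted", "ambient")]
            - la[("non_polluted", "warmed")] + ref, abs=1e-6)
        assert fit.link == "log" and fit.n_obs == 24

    def test_wald_identity_on_emitted_record(self):
        df = make_survey({
            ("non_polluted", "ambient"): [5, 7, 6, 8],
            ("non_polluted", "warmed"): [2, 4, 3, 3],
            ("polluted", "ambient"): [30, 34, 28, 40],
            ("polluted", "warmed"): [44, 52, 39, 61],
        })
        fit = fit_date_glm(df, "x", 0)
        for b, s, p in ((fit.beta_w, fit.se_w, fit.p_w),
                        (fit.beta_int, fit.se_int, fit.p_int)):
            assert p == pytest.approx(2 * norm.sf(abs(b) / s), abs=1e-12)

    def test_binary_logit_matches_closed_form(self):
        """Saturated binomial logit: coefficients are log-odds contrasts."""
        props = {
            ("non_polluted", "ambient"): 2, ("non_polluted", "warmed"): 4,
            ("polluted", "ambient"): 6, ("polluted", "warmed"): 5,
        }
        n = 8
        df = make_survey({
            c: [1] * k + [0] * (n - k) for c, k in props.items()
        })
        fit = fit_date_glm(df, "x", 0, family="binary")
        logit = lambda k: np.log(k / (n - k))
        ref = logit(props[("non_polluted", "ambient")])
        assert fit.beta_w == pytest.approx(
            logit(props[("non_polluted", "warmed")]) - ref, abs=1e-6)
        assert fit.beta_int == pytest.approx(
            logit(props[("polluted", "warmed")])
            - logit(props[("polluted", "ambient")])
            - logit(props[("non_polluted", "warmed")]) + ref, abs=1e-6)

    def test_continuous_identity_matches_cell_means(self):
        means = {
            ("non_polluted", "ambient"): 0.30, ("non_polluted", "warmed"): 0.28,
            ("polluted", "ambient"): 0.55, ("polluted", "warmed"): 0.70,
        }
        df = make_survey({
            c: [m - 0.02, m, m + 0.02] for c, m in means.items()
        })
        fit = fit_date_glm(df, "x", 0, family="continuous")
        ref = means[("non_polluted", "ambient")]
        assert fit.link == "identity"
        assert fit.beta_int == pytest.approx(
            means[("polluted", "warmed")] - means[("polluted", "ambient")]
            - means[("non_polluted", "warmed")] + ref, abs=1e-8)

    def test_proportion_beta_regression(self):
        rng = np.random.default_rng(4)
        df = make_survey({
            ("non_polluted", "ambient"): rng.beta(2, 8, 6),
            ("non_polluted", "warmed"): rng.beta(2, 8, 6),
            ("polluted", "ambient"): rng.beta(8, 2, 6),
            ("polluted", "warmed"): rng.beta(8, 2, 6),
        })
        fit = fit_date_glm(df, "x", 0, family="proportion")
        assert fit.link == "logit"
        assert fit.beta_p > 1.0  # pollution strongly raises the mean
        assert fit.p_p < 0.01

    def test_constant_response_degenerate(self):
        df = make_survey({c: [5, 5, 5] for c in CELLS})
        with pytest.raises(DegenerateFitError, match="zero variance"):
            fit_date_glm(df, "x", 0)

    def test_missing_cell_degenerate(self):
        df = make_survey({c: [1, 2, 3] for c in CELLS[:3]})
        with pytest.raises(DegenerateFitError, match="treatment cell"):
            fit_date_glm(df, "x", 0)

    def test_no_observations(self):
        df = make_survey({c: [1, 2] for c in CELLS})
        with pytest.raises(InputError):
            fit_date_glm(df, "x", 99)
        with pytest.raises(ConfigurationError):
            fit_date_glm(df, "x", 0, family="bogus")

    def test_separation_raises_degenerate(self):
        # one cell all-ones, another all-zeros -> perfect separation
        df = make_survey({
            ("non_polluted", "ambient"): [0, 0, 0, 0],
            ("non_polluted", "warmed"): [0, 1, 0, 1],
            ("polluted", "ambient"): [1, 1, 1, 1],
            ("polluted", "warmed"): [1, 1, 1, 1],
        })
        with pytest.raises(DegenerateFitError):
            fit_date_glm(df, "x", 0, family="binary")


class TestFirth:
    def test_finite_under_separation(self):
        df = make_survey({
            ("non_polluted", "ambient"): [0, 0, 0, 0, 0, 0],
            ("non_polluted", "warmed"): [0, 1, 0, 1, 0, 1],
            ("polluted", "ambient"): [1, 1, 1, 1, 1, 1],
            ("polluted", "warmed"): [1, 1, 1, 0, 1, 1],
        })
        fit = fit_firth_logistic(df, "x", 0)
        for b in (fit.beta_w, fit.beta_p, fit.beta_int):
            assert np.isfinite(b) and abs(b) < 20
        for s in (fit.se_w, fit.se_p, fit.se_int):
            assert np.isfinite(s) and s > 0

    def test_null_data_within_two_se(self):
        rng = np.random.default_rng(8)
        df = make_survey({c: rng.integers(0, 2, 12) for c in CELLS})
        fit = fit_firth_logistic(df, "x", 0)
        assert abs(fit.beta_int) < 2.5 * fit.se_int

    def test_non_binary_rejected(self):
        df = make_survey({c: [0, 1, 2] for c in CELLS})
        with pytest.raises(InputError, match="binary"):
            fit_firth_logistic(df, "x", 0)


def simulate_season(seed, beta_int=0.5, n_plates=6, trend_amp=0.8):
    cfg = SimulationConfig(
        n_plates_per_cell=n_plates, n_dates=7, alpha=3.0, beta_w=-0.6,
        beta_p=1.5, beta_int=beta_int, smooth_amplitude=trend_amp,
        plate_sd=0.25, dispersion=0.1, seed=seed,
    )
    return simulate_survey(cfg)


class TestSeason:
    def test_input_validation(self):
        df = simulate_season(1)
        short = df[df["day"] <= 14]
        with pytest.raises(InputError, match=">= 3 distinct dates"):
            fit_season_model(short, "response")
        with pytest.raises(ConfigurationError, match="smooth_df"):
            fit_season_model(df, "response", smooth_df=7)
        with pytest.raises(InputError):
            fit_season_model(df, "nope")

    def test_recovers_simulated_interaction(self):
        df = simulate_season(21, beta_int=0.6)
        fit = fit_season_model(df, "response")
        c = fit.coefficients
        assert c.date_label == "season"
        assert abs(c.beta_int - 0.6) < 2.5 * c.se_int
        assert c.p_int < 0.05
        assert set(fit.smooths) == {
            f"{s}|{w}" for s in ("non_polluted", "polluted")
            for w in ("ambient", "warmed")
        }

    def test_random_effect_toggle_agrees_without_plate_variance(self):
        cfg = SimulationConfig(
            n_plates_per_cell=8, n_dates=7, alpha=3.0, beta_w=-0.5,
            beta_p=1.0, beta_int=0.4, plate_sd=0.0, dispersion=0.05, seed=33,
        )
        df = simulate_survey(cfg)
        with_re = fit_season_model(df, "response", random_effect=True)
        without = fit_season_model(df, "response", random_effect=False)
        assert with_re.coefficients.beta_int == pytest.approx(
            without.coefficients.beta_int, abs=0.02)

    def test_smooth_tracks_seasonal_trend(self):
        """Fitted per-cell smooths rise and fall with the simulated
        half-period seasonal pulse (range well above flat)."""
        df = simulate_season(5, trend_amp=1.2)
        fit = fit_season_model(df, "response")
        ranges = [s["range"] for s in fit.smooths.values()]
        assert np.median(ranges) > 0.4


class TestGeneModels:
    def make_counts(self, rows, samples_per_cell=2):
        n = 4 * samples_per_cell
        cols = [f"s{i}" for i in range(n)]
        counts = pd.DataFrame(rows, columns=cols)
        counts.index = [f"g{i}" for i in range(len(counts))]
        counts.index.name = "gene_id"
        site = ["non_polluted"] * (n // 2) + ["polluted"] * (n // 2)
        warming = (["ambient"] * samples_per_cell
                   + ["warmed"] * samples_per_cell) * 2
        samples = pd.DataFrame(
            {"sample_id": cols, "site": site, "warming": warming})
        return counts, samples

    def test_low_count_filter(self):
        counts, samples = self.make_counts([
            [50, 60, 55, 48, 70, 66, 52, 61],   # kept (all positive)
            [3, 2, 1, 0, 1, 1, 1, 0],            # total 9 -> removed
            [1, 0, 0, 0, 1, 0, 1, 0],            # total 3 -> removed
            [20, 18, 25, 21, 19, 23, 24, 22],    # kept
            [12, 9, 14, 11, 10, 13, 9, 12],      # kept
        ])
        fits = fit_gene_models(counts, samples)
        assert sorted(fits["gene_id"]) == ["g0", "g3", "g4"]

    def test_identical_counts_give_null_fit(self):
        counts, samples = self.make_counts([
            [40] * 8,
            [25, 30, 27, 24, 31, 28, 26, 29],
        ])
        fits = fit_gene_models(counts, samples).set_index("gene_id")
        # size factors from the second gene perturb the offsets slightly,
        # so "null" means tiny, not machine zero
        assert fits.loc["g0", "lfc_int"] == pytest.approx(0.0, abs=0.01)
        assert fits.loc["g0", "p_int"] > 0.9

    def test_metadata_mismatch_and_bad_cells(self):
        counts, samples = self.make_counts([[10] * 8, [20] * 8])
        with pytest.raises(InputError):
            fit_gene_models(counts, samples.iloc[:-1])
        bad = samples.copy()
        bad["warming"] = "ambient"
        with pytest.raises(InputError, match="treatment cell"):
            fit_gene_models(counts, bad)

    def test_all_filtered_raises(self):
        counts, samples = self.make_counts([[1, 0, 0, 0, 0, 0, 0, 0]])
        with pytest.raises(DegenerateFitError):
            fit_gene_models(counts, samples)

    def test_recovers_strong_interaction_lfc(self):
        """A constructed gene whose polluted+warmed cell is ~4x above the
        additive expectation yields lfc_int near +2."""
        base = [100, 104, 98, 102]
        rows = [
            base * 2,
            [100, 102, 99, 101, 100, 103, 400, 410],  # int-only gene
        ] + [[np.random.default_rng(i).poisson(80, 8).tolist()][0]
             for i in range(40)]
        counts, samples = self.make_counts([list(r) for r in rows])
        fits = fit_gene_models(counts, samples).set_index("gene_id")
        assert fits.loc["g1", "lfc_int"] == pytest.approx(2.0, abs=0.35)
        # t-calibrated SEs at 4 residual df thicken the far tail, so the
        # p-value is small but not astronomically so
        assert fits.loc["g1", "p_int"] < 0.01
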