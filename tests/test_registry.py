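"""Synthetic registry generator: mechanism, invariants and file round trip."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elncut import GeneratorConfig, generate_cohort, read_cohort, write_cohort
from elncut.registry import CohortValidationError, validate_cohort

from conftest import toy_cohort, uniform_positivity_config


class TestConfigValidation:
    @pytest.mark.parametrize("fields, named", [
        ({"n_patients": 0}, "n_patients"),
        ({"cohort_style": "martian"}, "cohort_style"),
        ({"m_total": 3}, "m_total"),
        ({"geometric_q": 0.0}, "geometric_q"),
        ({"censor_rate": -1.0}, "censor_rate"),
        ({"break_eln": 99}, "break_eln"),
        ({"covariate_freqs": {"sex": {"male": 0.7, "female": 0.7}}}, "covariate_freqs"),
    ])
    def test_invalid_config_names_offending_field(self, fields, named):
        with pytest.raises(ValueError, match=named):
            GeneratorConfig(**fields)

    def test_style_presets_fill_eln_distribution(self):
        cfg = GeneratorConfig(cohort_style="china")
        assert cfg.eln_mean == 16.5 and cfg.eln_dispersion == 3.7


class TestGeneratorMechanism:
    def test_zero_positivity_yields_all_node_negative(self):
        cfg = GeneratorConfig(n_patients=500, positivity_intercept=-50.0, seed=3)
        cohort = generate_cohort(cfg)
        assert (cohort["positive_count"] == 0).all()
        assert (cohort["n_stage"] == "N0").all()

    def test_exhaustive_sampling_detects_every_positive_node(self):
        # degenerate ELN distribution at m_total: every node examined
        cfg = GeneratorConfig(n_patients=2_000, eln_mean=40, eln_dispersion=math.inf,
                              m_total=40, seed=4)
        cohort = generate_cohort(cfg)
        assert (cohort["eln_count"] == 40).all()
        assert (cohort["positive_count"] == cohort["latent_true_positive"]).all()

    def test_same_seed_is_byte_identical_different_seed_is_not(self, tmp_path):
        cfg = GeneratorConfig(n_patients=300, seed=12)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(a, pa, include_latent=True)
        write_cohort(b, pb, include_latent=True)
        assert pa.read_bytes() == pb.read_bytes()
        other = generate_cohort(dataclasses.replace(cfg, seed=13))
        assert not a["eln_count"].equals(other["eln_count"])

    def test_cohort_invariants_hold(self, benefit_cohort):
        c = benefit_cohort
        assert (c["positive_count"] <= c["eln_count"]).all()
        assert (c["positive_count"] <= c["latent_true_positive"]).all()
        assert (c["eln_count"].between(1, 40)).all()
        assert (c["time"] > 0).all()
        assert ((c["n_stage"] == "N0") == (c["positive_count"] == 0)).all()

    def test_eln_distribution_matches_configured_quantiles(self):
        # low-yield style targets median 7 (IQR 4-12); high-yield median 15 (IQR 10-22)
        seer = generate_cohort(GeneratorConfig(n_patients=50_000, seed=21))
        china = generate_cohort(GeneratorConfig(n_patients=50_000,
                                                cohort_style="china", seed=22))
        assert np.median(seer["eln_count"]) == pytest.approx(7, abs=1)
        assert np.median(china["eln_count"]) == pytest.approx(15, abs=1)

    def test_positive_counts_are_hypergeometric_given_latent_state(self):
        """Chi-square goodness of fit of observed positives against the
        hypergeometric pmf, within strata of identical (p_true, M, n)."""
        cohort = generate_cohort(uniform_positivity_config(n_patients=50_000, seed=44))
        tested = 0
        for (p_true, n), grp in cohort.groupby(["latent_true_positive", "eln_count"]):
            if p_true == 0 or len(grp) < 200:
                continue
            k = np.arange(0, min(p_true, n) + 1)
            expected = stats.hypergeom.pmf(k, 40, p_true, n) * len(grp)
            observed = np.array([(grp["positive_count"] == kk).sum() for kk in k])
            keep = expected >= 5
            if keep.sum() < 2:
                continue
            obs = np.append(observed[keep], observed[~keep].sum())
            exp = np.append(expected[keep], expected[~keep].sum())
            obs, exp = obs[exp > 0], exp[exp > 0]
            _, p = stats.chisquare(obs, exp * obs.sum() / exp.sum())
            assert p > 0.01, f"hypergeometric fit rejected in stratum p={p_true}, n={n}"
            tested += 1
        assert tested >= 5

    def test_detection_fraction_monotone_in_examined_count(self):
        cohort = generate_cohort(uniform_positivity_config(n_patients=50_000, seed=45))
        truly_pos = cohort[cohort["latent_true_positive"] > 0]
        bins = pd.cut(truly_pos["eln_count"], [0, 5, 10, 20, 40])
        detected = truly_pos.groupby(bins, observed=True)["positive_count"].apply(
            lambda s: (s > 0).mean())
        assert (detected.diff().dropna() >= 0).all(), detected.to_dict()

    def test_occult_mechanism_raises_mortality_of_understaged_patients(self):
        """Declared node-negative patients with few examined nodes die more
        often than those with many, and the size of the contrast agrees with
        a direct Monte-Carlo re-simulation of the same mechanism."""
        cfg = uniform_positivity_config(
            n_patients=100_000, occult_log_hazard=0.3, m_total=40, seed=46)
        cohort = generate_cohort(cfg)
        n0 = cohort[cohort["n_stage"] == "N0"]
        low = n0.loc[n0["eln_count"] < 8, "event"].mean()
        high = n0.loc[n0["eln_count"] >= 16, "event"].mean()
        assert low > high

        # independent minimal re-simulation: same latent mechanism, no covariates
        rng = np.random.default_rng(99)
        n = 100_000
        p_pos = 1 / (1 + np.exp(-cfg.positivity_intercept))
        latent = np.where(rng.uniform(size=n) < p_pos,
                          rng.geometric(cfg.geometric_q, size=n), 0)
        eln = cohort["eln_count"].to_numpy()  # same marginal ELN distribution
        pos = rng.hypergeometric(latent, 40 - latent, eln)
        lam = cfg.baseline_hazard * np.exp(cfg.occult_log_hazard * (latent - pos))
        t = rng.exponential(1 / lam)
        cens = np.minimum(rng.exponential(1 / cfg.censor_rate, size=n), cfg.max_followup)
        event = t <= cens
        neg = pos == 0
        mc_low = event[neg & (eln < 8)].mean()
        mc_high = event[neg & (eln >= 16)].mean()
        assert mc_low > mc_high
        # contrasts agree within Monte-Carlo error (covariates add spread)
        assert (low - high) == pytest.approx(mc_low - mc_high, abs=0.03)


class TestCohortIO:
    def test_round_trip_identity(self, tmp_path):
        cohort = generate_cohort(GeneratorConfig(n_patients=100, seed=8))
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(
            back, cohort.drop(columns=["latent_true_positive", "latent_m_total"]),
            check_dtype=False)

    def test_latent_columns_only_behind_flag(self, tmp_path):
        cohort = generate_cohort(GeneratorConfig(n_patients=50, seed=9))
        path = tmp_path / "c.csv"
        write_cohort(cohort, path)
        assert "latent_true_positive" not in pd.read_csv(path).columns
        write_cohort(cohort, path, include_latent=True)
        assert "latent_true_positive" in pd.read_csv(path).columns

    def test_positive_exceeding_examined_rejected_with_row_number(self, tmp_path):
        df = toy_cohort(eln=[5, 5, 5, 5], positive=[0, 0, 9, 0])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match=r"positive_count > eln_count.*\[3\]"):
            read_cohort(path)

    def test_unknown_histology_lists_allowed_categories(self, tmp_path):
        df = toy_cohort(eln=[5, 5], positive=[0, 0])
        df.loc[1, "histology"] = "carcinoid"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="adenocarcinoma"):
            read_cohort(path)

    def test_missing_column_rejected(self):
        with pytest.raises(CohortValidationError, match="missing required columns"):
            validate_cohort(pd.DataFrame({"eln_count": [1]}))
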