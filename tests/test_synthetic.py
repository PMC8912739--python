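"""Generator contracts: Hardy-Weinberg dosages, matching, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from polygre.io import write_cohort, write_dosages
from polygre.synthetic import (
    SimulationConfig,
    SimulationError,
    simulate_cohort,
    simulate_dosages,
)


class TestSimulateDosages:
    def test_symmetric_frequency_mean(self):
        d = simulate_dosages(10_000, np.full(5, 0.5), seed=1)
        assert np.allclose(d.mean(axis=0), 1.0, atol=0.05)

    def test_degenerate_high_frequency_fixes_allele(self):
        d = simulate_dosages(200, np.full(3, 1 - 1e-12), seed=0)
        assert (d.to_numpy() == 2.0).all()

    def test_bounds_and_shape(self):
        d = simulate_dosages(50, [0.2, 0.8], seed=2, jitter_sd=0.3)
        assert d.shape == (50, 2)
        assert d.to_numpy().min() >= 0 and d.to_numpy().max() <= 2

    def test_variance_matches_binomial_oracle(self, rng):
        # closed-form Binomial(2, f) variance 2f(1-f); per-locus sample
        # variances must sit within 4.5 sigma of it, where the sigma of a
        # sample variance comes from the exact binomial moments
        n, freqs = 5000, rng.uniform(0.05, 0.95, size=40)
        d = simulate_dosages(n, freqs, seed=7).to_numpy()
        var_true = 2 * freqs * (1 - freqs)
        # fourth central moment of Binomial(2, f), from its pmf
        k = np.arange(3)[:, None]
        pmf = stats.binom.pmf(k, 2, freqs[None, :])
        mu = 2 * freqs
        mu4 = (pmf * (k - mu) ** 4).sum(axis=0)
        se = np.sqrt((mu4 - var_true**2) / n)
        assert (np.abs(d.var(axis=0, ddof=1) - var_true) < 4.5 * se).all()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_rejects_non_probability_frequencies(self, bad):
        with pytest.raises(ValueError):
            simulate_dosages(10, [0.5, bad])


class TestConfigValidation:
    def test_prevalences_must_be_simplex(self):
        with pytest.raises(ValueError, match="simplex"):
            SimulationConfig(exposure_control_prevalences=(0.5, 0.3, 0.1, 0.2))

    def test_counts_positive(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_cases=0)

    def test_beta_exposure_length(self):
        with pytest.raises(ValueError):
            SimulationConfig(beta_exposure=(0.1, 0.2))

    def test_frequencies_length_and_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_loci=3, risk_allele_freqs=(0.5, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(n_loci=2, risk_allele_freqs=(0.5, 1.2))

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            SimulationConfig(covariate_effects={"shoe_size": (0.1,)})


class TestSimulateCohort:
    def test_counts_bounds_and_truth_echo(self, small_dataset):
        ds = small_dataset
        ds.validate()
        assert len(ds.cohort) == 1200
        assert len(ds.truth.risk_allele_freqs) == 140
        d = ds.dosages.to_numpy()
        assert d.min() >= 0 and d.max() <= 2
        assert not ds.cohort["exposure"].isna().any()

    def test_exposure_prevalences_near_target(self, small_dataset):
        controls = small_dataset.cohort.query("case == 0")
        obs = controls["exposure"].value_counts(normalize=True)
        target = small_dataset.truth.exposure_control_prevalences
        for lvl, t in zip(small_dataset.cohort["exposure"].cat.categories,
                          target):
            assert abs(obs[lvl] - t) < 0.04

    def test_matching_balances_age_and_sex(self, small_dataset):
        c = small_dataset.cohort
        p_male = c.groupby("case", observed=True)["sex"].apply(
            lambda s: (s == "male").mean())
        assert abs(p_male[0] - p_male[1]) < 0.01
        decade = (c["age"] // 10).clip(4, 8)
        dist = decade.groupby(c["case"]).value_counts(normalize=True).unstack()
        assert (dist.loc[0] - dist.loc[1]).abs().max() < 0.01

    def test_same_seed_byte_identical_output(self, tmp_path):
        cfg = SimulationConfig(n_cases=120, n_controls=120, seed=9)
        files = []
        for tag in ("a", "b"):
            ds = simulate_cohort(cfg)
            write_cohort(ds.cohort, tmp_path / f"c_{tag}.tsv")
            write_dosages(ds.dosages, tmp_path / f"d_{tag}.tsv")
            files.append(((tmp_path / f"c_{tag}.tsv").read_bytes(),
                          (tmp_path / f"d_{tag}.tsv").read_bytes()))
        assert files[0] == files[1]
        ds2 = simulate_cohort(dataclasses.replace(cfg, seed=10))
        assert not ds2.cohort["age"].equals(simulate_cohort(cfg).cohort["age"])

    def test_infeasible_pool_raises(self):
        cfg = SimulationConfig(n_cases=500, n_controls=500, pool_size=800)
        with pytest.raises(SimulationError, match="increase pool_size"):
            simulate_cohort(cfg)

    def test_missing_exposure_rate(self):
        cfg = SimulationConfig(n_cases=400, n_controls=400,
                               missing_exposure_rate=0.1, seed=5)
        ds = simulate_cohort(cfg)
        frac = ds.cohort["exposure"].isna().mean()
        assert 0.05 < frac < 0.15

    def test_confounding_knob_induces_association(self):
        cfg = SimulationConfig(n_cases=400, n_controls=400, seed=6,
                               exposure_confounding=1.5)
        ds = simulate_cohort(cfg)
        c = ds.cohort
        heavy = c["exposure"].cat.codes >= 2
        assert (c.loc[heavy, "smoking"] == "current").mean() > \
               (c.loc[~heavy, "smoking"] == "current").mean()

    def test_null_world_exposure_exchangeable(self):
        # with all effects off, case/control exposure distributions differ
        # only by sampling noise: chi-square rejections at alpha=0.1 stay
        # within the nominal binomial envelope over 30 seeds
        null = dict(n_cases=150, n_controls=150, beta_exposure=(0.0, 0.0, 0.0),
                    beta_prs_per_percentile=0.0, beta_age_per_year=0.0,
                    beta_male=0.0, covariate_effects={}, matching=False)
        rejections = 0
        for seed in range(30):
            ds = simulate_cohort(SimulationConfig(**null, seed=seed))
            ct = ds.cohort.groupby("case", observed=True)[
                "exposure"].value_counts().unstack(fill_value=0)
            _, p, _, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
            rejections += p < 0.1
        assert rejections <= stats.binom.ppf(0.9995, 30, 0.1)
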