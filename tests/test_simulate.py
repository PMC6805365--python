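"""Synthetic cohort generator: determinism, calibration, component laws."""

import dataclasses
import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from lbptriage.cohort import assign_groups
from lbptriage.mannequin import is_widespread
from lbptriage.marginals import solve_censored_normal
from lbptriage.simulate import (
    GeneratorConfig,
    generate_cohort,
    recover_parameters,
    widespread_probability,
    _sbt_alpha,
    _ztnb_capped_pmf,
)
from lbptriage.stats import scored_frame


@pytest.fixture(scope="module")
def default_config():
    return GeneratorConfig.default()


def _resize(cfg, n_lbp, n_ref, n_unassigned=0, **overrides):
    return dataclasses.replace(
        cfg,
        lbp=dataclasses.replace(cfg.lbp, n=n_lbp),
        reference=dataclasses.replace(cfg.reference, n=n_ref),
        n_unassigned=n_unassigned,
        **overrides,
    )


class TestDeterminism:
    def test_same_seed_identical_cohorts(self, default_config):
        a = generate_cohort(default_config, seed=5)
        b = generate_cohort(default_config, seed=5)
        assert a.records == b.records

    def test_different_seeds_differ(self, default_config):
        a = generate_cohort(default_config, seed=5)
        b = generate_cohort(default_config, seed=6)
        assert a.records != b.records

    def test_default_sizes_and_group_split(self, default_config):
        cohort = generate_cohort(default_config, seed=1)
        part = assign_groups(cohort)
        assert len(cohort) == 126
        assert (len(part.lbp), len(part.reference), len(part.unassigned)) == (52, 67, 7)

    def test_zero_sizes_give_empty_cohort(self, default_config):
        cfg = _resize(default_config, 0, 0)
        assert len(generate_cohort(cfg, seed=1)) == 0


class TestMarginalSolver:
    @pytest.mark.parametrize(
        "mean, sd, lo, hi, gran",
        [
            (5.1, 2.1, 0, 10, 1),  # well inside the scale
            (1.2, 2.4, 0, 10, 1),  # overdispersed: censoring mass at zero
            (0.87, 0.14, 0, 1, 0.001),  # near the top of the scale
            (2.0, 2.1, 0, 24, 1),
        ],
    )
    def test_moment_match_within_monte_carlo_error(self, mean, sd, lo, hi, gran):
        marg = solve_censored_normal(mean, sd, lo, hi, gran)
        rng = np.random.default_rng(0)
        sample = marg.sample(rng.standard_normal(200_000))
        assert sample.min() >= lo and sample.max() <= hi
        assert sample.mean() == pytest.approx(mean, abs=4 * sd / math.sqrt(200_000))
        assert sample.std(ddof=1) == pytest.approx(sd, rel=0.02)

    def test_zero_sd_gives_constant(self):
        marg = solve_censored_normal(4.0, 0.0, 0, 10, 1)
        assert np.all(marg.sample(np.random.default_rng(0).standard_normal(100)) == 4.0)

    def test_unreachable_targets_rejected(self):
        with pytest.raises(ValueError):
            solve_censored_normal(0.5, 5.0, 0, 1, 0.001)  # SD beyond the scale
        with pytest.raises(ValueError):
            solve_censored_normal(12.0, 1.0, 0, 10, 1)  # mean off the scale


class TestComponentLaws:
    def test_ztnb_capped_pmf_hits_target_mean(self):
        pmf = np.array(_ztnb_capped_pmf(6.25, 5.0))
        assert pmf.sum() == pytest.approx(1.0)
        assert float(np.dot(np.arange(1, 19), pmf)) == pytest.approx(6.25)

    def test_sbt_alpha_reproduces_marginal(self):
        slope = 1.2
        alpha = _sbt_alpha(0.3, slope)
        rng = np.random.default_rng(1)
        z = rng.standard_normal(400_000)
        p_hat = (rng.random(400_000) < 1 / (1 + np.exp(-(alpha + slope * z)))).mean()
        assert p_hat == pytest.approx(0.3, abs=0.005)

    def test_widespread_probability_matches_monte_carlo(self, region_map):
        rng = np.random.default_rng(2)
        ids = list(region_map.ids)
        for k in (3, 5, 8, 12):
            exact = widespread_probability(k, region_map)
            hits = sum(
                is_widespread(frozenset(rng.choice(ids, size=k, replace=False)), region_map)
                for _ in range(4000)
            )
            assert hits / 4000 == pytest.approx(exact, abs=4 * math.sqrt(0.25 / 4000))

    def test_widespread_probability_boundaries(self, region_map):
        assert widespread_probability(0, region_map) == 0.0
        assert widespread_probability(2, region_map) == 0.0  # needs >= 3 regions
        assert widespread_probability(18, region_map) == 1.0
        # any 15+ regions must cover all five attributes (largest avoidable
        # category, the axial skeleton, has only 4 regions)
        assert widespread_probability(15, region_map) == 1.0


class TestGeneratedStructure:
    def test_degenerate_zero_sds_give_exact_means(self, default_config):
        lbp = dataclasses.replace(
            default_config.lbp,
            pro_means={"nrs_pain": 5.0, "rmdq": 7.0},
            pro_sds={"nrs_pain": 0.0, "rmdq": 0.0},
        )
        cfg = dataclasses.replace(_resize(default_config, 40, 0), lbp=lbp)
        cohort = generate_cohort(cfg, seed=9)
        assert all(r.nrs_pain == 5.0 and r.rmdq == 7.0 for r in cohort)

    def test_lbp_group_answers_yes(self, default_config):
        cohort = generate_cohort(_resize(default_config, 30, 30), seed=4)
        part = assign_groups(cohort)
        assert len(part.lbp) == 30 and len(part.unassigned) == 0

    def test_missingness_rates_apply(self, default_config):
        cfg = _resize(default_config, 1500, 0, sbt_missing=0.3, mannequin_missing=0.1)
        cohort = generate_cohort(cfg, seed=8)
        sbt_missing = sum(not r.sbt_complete for r in cohort) / len(cohort)
        mann_missing = sum(not r.mannequin_complete for r in cohort) / len(cohort)
        assert sbt_missing == pytest.approx(0.3, abs=0.05)
        assert mann_missing == pytest.approx(0.1, abs=0.04)

    def test_zero_coupling_makes_screens_independent(self, default_config):
        cfg = _resize(default_config, 3000, 0, coupling=0.0)
        df = scored_frame(generate_cohort(cfg, seed=12))
        sub = df[df["sbt_risk"].notna() & df["ms_cwp"].notna()]
        table = [
            [
                int(((sub["sbt_risk"] == lev) & (sub["ms_cwp"] == flag)).sum())
                for flag in (False, True)
            ]
            for lev in ("low", "medium", "high")
        ]
        _, p, _, _ = chi2_contingency(np.array(table), correction=False)
        assert p > 0.01  # no systematic association without the latent factor

    def test_positive_coupling_puts_ms_cwp_in_sbt_low(self, default_config):
        cfg = _resize(default_config, 2000, 0)
        df = scored_frame(generate_cohort(cfg, seed=13))
        low = df[df["sbt_risk"] == "low"]
        frac = low["ms_cwp"].dropna().astype(bool).mean()
        assert frac > 0.05  # the mannequin flags people the SBT calls low risk

    def test_pro_group_differences_point_the_configured_way(self, default_config):
        cfg = _resize(default_config, 2500, 2500)
        df = scored_frame(generate_cohort(cfg, seed=14))
        lbp = df[df["group"] == "lbp"]
        ref = df[df["group"] == "reference"]
        worse_high = ["nrs_pain", "rmdq", "had_anxiety", "had_depression", "fabq_pa", "fabq_work"]
        for name in worse_high:
            assert lbp[name].mean() > ref[name].mean()
        assert lbp["eq5d_index"].mean() < ref["eq5d_index"].mean()

    def test_recover_parameters_reports_all_quantities(self, default_config):
        cohort = generate_cohort(default_config, seed=15)
        rep = recover_parameters(cohort, default_config)
        assert set(rep["group"]) == {"lbp", "reference"}
        assert {"p_cwp", "region_mean", "sbt_mean", "nrs_pain"} <= set(rep["quantity"])
        assert rep["configured"].notna().all()


class TestConfigValidation:
    def test_cwp_cannot_exceed_chronic(self, default_config):
        with pytest.raises(ValueError, match="chronic"):
            dataclasses.replace(
                default_config.lbp, p_chronic=0.4, p_cwp=0.5
            )

    def test_yaml_round_trip_matches_default(self, tmp_path, default_config):
        import yaml
        from importlib import resources

        text = resources.files("lbptriage").joinpath("data/generator.yaml").read_text()
        path = tmp_path / "gen.yaml"
        path.write_text(text)
        assert GeneratorConfig.from_yaml(path) == default_config
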