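import math

import numpy as np
import pandas as pd
import pytest

import cpuecal as cc
from cpuecal.simulate import _rng_streams
from conftest import static_population


class TestSimConfig:
    def test_defaults_geometry(self):
        cfg = cc.SimConfig()
        assert cfg.area_ha == pytest.approx(5.0176)
        assert cfg.effective_transect_width == 4.0
        assert cfg.full_coverage == pytest.approx(29 * 220 * 4 / 224**2)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("monthly_survival", 1.5),
            ("monthly_survival", -0.1),
            ("monthly_survival", float("nan")),
            ("trap_capture_prob", 2.0),
            ("hyperstability_beta", 0.0),
            ("hyperstability_beta", -1.0),
            ("catchability_q", -0.5),
            ("monthly_birth_rate", float("inf")),
        ],
    )
    def test_rejects_bad_rates_naming_field(self, field, value):
        with pytest.raises(ValueError, match=field):
            cc.SimConfig(**{field: value})

    def test_rejects_over_full_coverage(self):
        with pytest.raises(ValueError, match="100%"):
            cc.SimConfig(n_transects=80)


class TestSimulatePopulation:
    def test_no_dynamics_constant_abundance(self):
        cfg = cc.SimConfig(
            initial_abundance=33, monthly_survival=1.0, monthly_birth_rate=0.0,
            n_months=24, seed=3,
        )
        _, abundance = cc.simulate_population(cfg)
        assert (abundance == 33).all()

    def test_paper_like_preset_declines_into_range(self):
        finals = []
        for seed in range(9):
            _, ab = cc.simulate_population(cc.paper_like_config(seed=seed))
            assert ab.iloc[0] == 117
            assert ab.iloc[-1] < ab.iloc[0] / 2  # declining overall
            finals.append(ab.iloc[-1])
        # preset is tuned so the median trajectory spans ~117 -> ~15
        assert 10 <= np.median(finals) <= 40

    def test_seed_determinism(self, paper_config):
        a = cc.simulate_dataset(paper_config)
        b = cc.simulate_dataset(paper_config)
        pd.testing.assert_frame_equal(a.captures, b.captures)
        pd.testing.assert_frame_equal(a.effort, b.effort)
        pd.testing.assert_series_equal(a.abundance, b.abundance)

    def test_closure_every_change_is_birth_or_death(self, paper_config):
        individuals, abundance = cc.simulate_population(paper_config)
        births = pd.Series(0, index=range(paper_config.n_months), dtype=int)
        deaths = pd.Series(0, index=range(paper_config.n_months), dtype=int)
        for ind in individuals:
            if 0 <= ind.birth_month < paper_config.n_months:
                births[ind.birth_month] += 1
            if ind.death_month is not None and 0 <= ind.death_month < paper_config.n_months:
                deaths[ind.death_month] += 1
        n = abundance.to_numpy()
        for m in range(paper_config.n_months - 1):
            assert n[m + 1] - n[m] == births[m + 1] - deaths[m]

    def test_rejects_bad_removal_schedule(self):
        with pytest.raises(ValueError, match="removal_schedule"):
            cc.SimConfig(removal_schedule=((3, 1.7),))

    def test_removal_schedule_extra_mortality(self):
        base = cc.SimConfig(initial_abundance=200, monthly_survival=1.0,
                            monthly_birth_rate=0.0, n_months=6, seed=9)
        removed = cc.SimConfig(initial_abundance=200, monthly_survival=1.0,
                               monthly_birth_rate=0.0, n_months=6, seed=9,
                               removal_schedule=((2, 0.5),))
        _, ab0 = cc.simulate_population(base)
        _, ab1 = cc.simulate_population(removed)
        assert (ab0 == 200).all()
        assert ab1.iloc[2] == 200  # deaths within the month still count that month
        assert ab1.iloc[3] < 200


class TestVisualSurveys:
    def test_zero_catchability_effort_still_recorded(self):
        cfg = cc.SimConfig(catchability_q=0.0, n_months=3, seed=1)
        pop = static_population(40, config=cfg)
        sched = cc.survey_schedule(cfg, nights_per_week=2)
        caps, eff = cc.simulate_visual_surveys(pop, sched, cfg)
        assert caps.empty
        assert len(eff) == len(sched)
        assert eff["km"].eq(29 * 0.22).all()

    def test_effort_bookkeeping_exact(self, dataset, paper_config):
        vis = dataset.effort[dataset.effort["method"] == "visual"]
        expected = len(vis) * paper_config.n_transects * 0.220
        assert vis["km"].sum() == pytest.approx(expected, rel=1e-12)

    def test_rejects_out_of_range_transects(self):
        cfg = cc.SimConfig(n_months=2, seed=1)
        pop = static_population(10, config=cfg)
        with pytest.raises(ValueError, match="transect ids"):
            cc.simulate_visual_surveys(pop, [(cfg.start.start_time, [0, 5])], cfg)
        with pytest.raises(ValueError, match="transect ids"):
            cc.simulate_visual_surveys(pop, [(cfg.start.start_time, [30])], cfg)

    def test_mean_detections_match_closed_form_beta1(self):
        # >= 2000 replicate nights against q*N*coverage
        cfg = cc.SimConfig(n_months=72, catchability_q=0.1, seed=21,
                           monthly_survival=1.0, monthly_birth_rate=0.0)
        n = 50
        pop = static_population(n, config=cfg)
        from cpuecal.periods import day_to_date
        all_t = tuple(range(1, 30))
        sched = [(day_to_date(d, cfg.start), all_t) for d in range(2100)]
        caps, eff = cc.simulate_visual_surveys(pop, sched, cfg)
        lam = cfg.catchability_q * n * cfg.full_coverage
        mean = len(caps) / len(sched)
        se = math.sqrt(lam / len(sched))
        assert abs(mean - lam) < 3 * se

    def test_hyperstability_beta_half_cpue_ratio(self):
        # beta=0.5: halving N shrinks CPUE by ~sqrt(2), not 2
        from cpuecal.periods import day_to_date
        means = {}
        for n in (80, 40):
            cfg = cc.SimConfig(n_months=72, catchability_q=0.2, seed=31,
                               hyperstability_beta=0.5,
                               monthly_survival=1.0, monthly_birth_rate=0.0)
            pop = static_population(n, config=cfg)
            sched = [(day_to_date(d, cfg.start), tuple(range(1, 30))) for d in range(2000)]
            caps, _ = cc.simulate_visual_surveys(pop, sched, cfg)
            means[n] = len(caps) / len(sched)
        ratio = means[80] / means[40]
        lam80 = 0.2 * 80**0.5 * cc.SimConfig().full_coverage
        lam40 = 0.2 * 40**0.5 * cc.SimConfig().full_coverage
        se_ratio = ratio * math.sqrt(1 / (lam80 * 2000) + 1 / (lam40 * 2000))
        assert abs(ratio - math.sqrt(2)) < 3 * se_ratio

    def test_unbiased_cpue_at_beta1(self):
        # realized CPUE estimates q * N * coverage / km (3-SE Monte Carlo)
        from cpuecal.periods import day_to_date
        cfg = cc.SimConfig(n_months=72, catchability_q=0.1, seed=41,
                           monthly_survival=1.0, monthly_birth_rate=0.0)
        n = 60
        pop = static_population(n, config=cfg)
        sched = [(day_to_date(d, cfg.start), tuple(range(1, 30))) for d in range(2000)]
        caps, eff = cc.simulate_visual_surveys(pop, sched, cfg)
        cpue = len(caps) / eff["km"].sum()
        expected = 0.1 * n * cfg.full_coverage / (29 * 0.22)
        se = math.sqrt(0.1 * n * cfg.full_coverage * len(sched)) / eff["km"].sum()
        assert abs(cpue - expected) < 3 * se

    def test_proportional_thinning_uniform_density(self):
        # uniform density: keeping 14/29 transects leaves expected CPUE unchanged
        from cpuecal.periods import day_to_date
        cfg = cc.SimConfig(n_months=72, catchability_q=0.15, seed=51,
                           monthly_survival=1.0, monthly_birth_rate=0.0)
        pop = static_population(50, config=cfg)
        kept = cc.apply_spatial_scheme(14, config=cfg).transect_ids
        full_sched = [(day_to_date(d, cfg.start), tuple(range(1, 30))) for d in range(1500)]
        sub_sched = [(day_to_date(d, cfg.start), kept) for d in range(1500)]
        caps_f, eff_f = cc.simulate_visual_surveys(pop, full_sched, cfg)
        caps_s, eff_s = cc.simulate_visual_surveys(pop, sub_sched, cfg)
        cpue_f = len(caps_f) / eff_f["km"].sum()
        cpue_s = len(caps_s) / eff_s["km"].sum()
        lam_s = 0.15 * 50 * cc.coverage_fraction(14, cfg)
        se_s = math.sqrt(lam_s * 1500) / eff_s["km"].sum()
        lam_f = 0.15 * 50 * cfg.full_coverage
        se_f = math.sqrt(lam_f * 1500) / eff_f["km"].sum()
        assert abs(cpue_s - cpue_f) < 3 * math.hypot(se_s, se_f)


class TestTrapping:
    def test_all_small_snakes_never_trapped(self):
        cfg = cc.SimConfig(n_months=3, seed=2, trap_capture_prob=0.05)
        pop = static_population(50, svl=500.0, growth=0.01, config=cfg)
        bouts = cc.trap_bout_schedule(cfg, n_bouts=2, nights_per_bout=5)
        caps, eff = cc.simulate_trapping(pop, bouts, cfg)
        assert caps.empty
        assert len(eff) == 10

    def test_empty_bout_schedule_empty_outputs(self):
        cfg = cc.SimConfig(n_months=3, seed=2)
        caps, eff = cc.simulate_trapping(static_population(5, config=cfg), [], cfg)
        assert caps.empty and eff.empty

    def test_trap_captures_only_above_threshold(self, dataset):
        trap = dataset.captures[dataset.captures["method"] == "trap"]
        assert (trap["svl_mm"] > 900).all()

    def test_unique_captures_match_closed_form(self):
        # p=0.001/trap-night, 169 traps x 14 nights: E[unique] = N(1-(1-p)^2366)
        n, p, reps = 40, 0.001, 150
        expected = n * (1 - (1 - p) ** 2366)
        uniques = []
        for seed in range(reps):
            cfg = cc.SimConfig(n_months=2, seed=seed, trap_capture_prob=p,
                               monthly_survival=1.0, monthly_birth_rate=0.0)
            pop = static_population(n, svl=1000.0, config=cfg)
            bouts = cc.trap_bout_schedule(cfg, n_bouts=1, nights_per_bout=14)
            caps, eff = cc.simulate_trapping(pop, bouts, cfg)
            assert eff["trap_nights_deployed"].sum() == 2366
            uniques.append(caps["individual_id"].nunique())
        mean = np.mean(uniques)
        se = np.std(uniques, ddof=1) / math.sqrt(reps)
        assert abs(mean - expected) < 3 * se

    def test_prey_modulation_decouples_trap_cpue(self):
        # modulation variance >> density signal: slope CI covers 0 in >= 80%
        # (overdispersion-aware NB fit; prey noise dilutes the slope to ~0)
        covered, fitted = 0, 0
        reps = 10
        for seed in range(reps):
            cfg = cc.paper_like_config(seed=100 + seed, prey_modulation_sd=2.5)
            ds = cc.simulate_dataset(cfg, nights_per_week=2)
            truth = cc.census_panel(ds.captures, ds.growth_rates,
                                    removals=ds.removals,
                                    censor_month=cfg.months[-1], months=cfg.months)
            panel = cc.build_panel(truth, ds.captures, ds.effort)
            try:
                fit = cc.fit_count_glm(panel, response="gt900", predictor="trap",
                                       family="negative_binomial", terms="linear")
            except (cc.ConvergenceError, ValueError):
                continue
            fitted += 1
            if fit.ci_lower[1] <= 0 <= fit.ci_upper[1]:
                covered += 1
        assert fitted >= 8
        assert covered >= 0.8 * fitted

    def test_corrected_trap_nights_at_most_deployed(self, dataset):
        trap = dataset.effort[dataset.effort["method"] == "trap"]
        assert (trap["trap_nights_corrected"] <= trap["trap_nights_deployed"]).all()


class TestTransectWeights:
    def test_uniform_when_sd_zero(self):
        cfg = cc.SimConfig(n_months=6)
        w = cc.transect_weights(cfg, np.random.default_rng(0))
        assert w.shape == (6, 29)
        assert (w == 1.0).all()

    def test_stationary_marginal_sd(self):
        cfg = cc.SimConfig(n_months=400, transect_heterogeneity_sd=1.5,
                           transect_heterogeneity_rho=0.9)
        w = cc.transect_weights(cfg, np.random.default_rng(1))
        assert np.log(w).std() == pytest.approx(1.5, rel=0.1)
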