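"""Synthetic cohort generator: determinism, distributions, signal shape."""

import numpy as np
import pytest
from scipy import stats

import ovutemp as ot
from ovutemp.nightly import nightly_value
from ovutemp.synthetic import (
    CohortConfig,
    LUTEAL_BETWEEN_SD,
    _split_sd,
    render_minute_night,
    sample_cycle_structure,
)

NOISELESS = dict(
    skin_sd_follicular=0.0, skin_sd_luteal=0.0,
    oral_sd_follicular=0.0, oral_sd_luteal=0.0,
    skin_missing_rate=0.0, oral_missing_rate=0.0,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(n_participants=0), "n_participants"),
            (dict(cycle_len_mean=55.0), "cycle_len_min"),
            (dict(skin_sd_luteal=-0.1), "skin_sd_luteal"),
            (dict(oral_missing_rate=1.0), "oral_missing_rate"),
            (dict(quantization=0.0), "quantization"),
            (dict(lh_day_min=20), "lh_day_min"),
        ],
    )
    def test_invalid_parameter_named(self, kwargs, message):
        with pytest.raises(ValueError, match=message):
            CohortConfig(**kwargs)


class TestCycleStructure:
    def test_events_satisfy_ordering_invariants(self):
        for seed in range(4):
            cfg = CohortConfig(n_participants=8, seed=seed)
            for rec in ot.generate_cohort(cfg):
                for c, c_next in zip(rec.events.cycles, rec.events.cycles[1:]):
                    assert c.start < c.lh_day < c_next.start
                    assert c.ovulation_day == c.lh_day + 1
                    assert c_next.start - c.start == c.length
                    assert cfg.cycle_len_min <= c.length <= cfg.cycle_len_max
                    lh_cd = c.lh_day - c.start + 1
                    assert cfg.lh_day_min <= lh_cd <= min(cfg.lh_day_max, c.length - 2)
                for m in rec.events.menses_starts:
                    assert 1 <= m <= cfg.study_days

    def test_forced_lh_bounds_fix_ovulation_cycle_day(self):
        cfg = CohortConfig(
            n_participants=3, cycle_len_mean=28, cycle_len_sd=0.0,
            lh_day_min=14, lh_day_max=14, lh_day_mean=14, seed=2,
        )
        for rec in ot.generate_cohort(cfg):
            for c in rec.events.cycles:
                assert c.ovulation_day - c.start + 1 == 15

    def test_degenerate_bounds_fix_cycle_length(self):
        cfg = CohortConfig(
            n_participants=3, cycle_len_min=28, cycle_len_max=28,
            cycle_len_mean=28, seed=3,
        )
        for rec in ot.generate_cohort(cfg):
            assert all(c.length == 28 for c in rec.events.cycles)

    def test_cycle_length_mean_matches_hierarchical_truncnorm_oracle(self):
        # first cycle of each participant is an unbiased draw from the
        # hierarchical marginal (pooling all cycles would be length-biased:
        # short-cycle participants fit more cycles into the study window)
        cfg = CohortConfig(n_participants=2000, seed=9)
        rng = np.random.default_rng(9)
        lengths = [
            sample_cycle_structure(cfg, rng).cycles[0].length
            for _ in range(cfg.n_participants)
        ]
        # oracle: E[TruncN(mu, sd_w)] integrated over mu ~ TruncN(mean, sd_b),
        # computed by quadrature, independent of the sampling path
        sd_b, sd_w = _split_sd(cfg.cycle_len_sd, cfg.cycle_len_sd_within)
        lo, hi = cfg.cycle_len_min, cfg.cycle_len_max
        a, b = (lo - cfg.cycle_len_mean) / sd_b, (hi - cfg.cycle_len_mean) / sd_b
        mu = np.linspace(lo, hi, 2001)
        w = stats.truncnorm.pdf(mu, a, b, loc=cfg.cycle_len_mean, scale=sd_b)
        inner = stats.truncnorm.mean(
            (lo - mu) / sd_w, (hi - mu) / sd_w, loc=mu, scale=sd_w
        )
        oracle = np.trapezoid(inner * w, mu) / np.trapezoid(w, mu)
        assert np.mean(lengths) == pytest.approx(oracle, abs=0.3)

    def test_cohort_realized_mean_near_published_value(self):
        cfg = CohortConfig(n_participants=22, study_days=115, seed=12)
        lengths = [
            c.length for rec in ot.generate_cohort(cfg) for c in rec.events.cycles
        ]
        assert len(lengths) >= 88  # ~4+ cycles per participant
        assert np.mean(lengths) == pytest.approx(27.6, abs=2.0)

    def test_lh_day_marginal_near_published_statistics(self):
        cfg = CohortConfig(n_participants=400, seed=10)
        rng = np.random.default_rng(10)
        lh_days = []
        for _ in range(cfg.n_participants):
            ev = sample_cycle_structure(cfg, rng)
            lh_days.extend(c.lh_day - c.start + 1 for c in ev.cycles)
        assert np.mean(lh_days) == pytest.approx(cfg.lh_day_mean, abs=1.5)
        assert np.std(lh_days) == pytest.approx(cfg.lh_day_sd, abs=1.5)
        assert LUTEAL_BETWEEN_SD <= cfg.lh_day_sd


class TestDailySeries:
    def test_determinism_same_seed_identical_records(self):
        a = ot.generate_cohort(CohortConfig(n_participants=4, seed=5))
        b = ot.generate_cohort(CohortConfig(n_participants=4, seed=5))
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.skin.values, rb.skin.values, equal_nan=True)
            assert np.array_equal(ra.oral.values, rb.oral.values, equal_nan=True)
            assert ra.events.menses_starts == rb.events.menses_starts
            assert ra.events.cycles == rb.events.cycles

    def test_noiseless_regular_config_is_periodic_square_wave(self):
        cfg = CohortConfig(
            n_participants=1, study_days=112, seed=4,
            cycle_len_mean=28, cycle_len_sd=0.0, lh_day_sd=0.0,
            transition_days=0, **NOISELESS,
        )
        [rec] = ot.generate_cohort(cfg)
        vals = rec.skin.values
        assert np.isfinite(vals).all()
        assert len(np.unique(vals)) == 2  # two quantized plateau levels
        np.testing.assert_array_equal(vals[:-28], vals[28:])  # period 28

    def test_noiseless_phase_means_differ_by_shift(self):
        cfg = CohortConfig(
            n_participants=1, study_days=112, seed=4,
            cycle_len_mean=28, cycle_len_sd=0.0, lh_day_sd=0.0,
            transition_days=0, quantization=1e-9, **NOISELESS,
        )
        [rec] = ot.generate_cohort(cfg)
        vals = rec.skin.values
        # ramp-high days carry baseline + shift exactly
        assert vals.max() - vals.min() == pytest.approx(cfg.skin_shift, abs=1e-6)

    def test_quantization_grid(self):
        cfg = CohortConfig(n_participants=3, seed=6)
        for rec in ot.generate_cohort(cfg):
            vals = rec.skin.values[np.isfinite(rec.skin.values)]
            np.testing.assert_allclose(
                vals, np.round(vals / cfg.quantization) * cfg.quantization, atol=1e-9
            )

    def test_missingness_rate_matches_binomial_oracle(self):
        cfg = CohortConfig(n_participants=100, seed=7)
        records = ot.generate_cohort(cfg)
        frac = np.mean([np.isnan(r.skin.values).mean() for r in records])
        # binomial SE over 100 x 115 days ~ 0.0017; 3 pp tolerance
        assert frac == pytest.approx(cfg.skin_missing_rate, abs=0.03)
        frac_oral = np.mean([np.isnan(r.oral.values).mean() for r in records])
        assert frac_oral == pytest.approx(cfg.oral_missing_rate, abs=0.03)


class TestMinuteNights:
    def test_plateau_recovered_within_quantization_step(self, rng):
        cfg = CohortConfig()
        s = render_minute_night(36.40, ot.synthetic.STUDY_EPOCH, cfg, rng)
        assert len(s) == 601
        res = nightly_value(s)
        assert res.value == pytest.approx(36.40, abs=cfg.quantization)

    def test_spike_rejected_by_stability_rule(self, rng):
        cfg = CohortConfig()
        s = render_minute_night(36.0, ot.synthetic.STUDY_EPOCH, cfg, rng, spikes=1)
        res = nightly_value(s)
        assert res.value == pytest.approx(36.0, abs=cfg.quantization)

    def test_all_night_dropout_flagged_missing(self, rng):
        cfg = CohortConfig()
        s = render_minute_night(
            36.0, ot.synthetic.STUDY_EPOCH, cfg, rng, all_night_dropout=True
        )
        assert len(s) == 0
        assert nightly_value(s).value is None

    def test_minute_level_cohort_consistent_with_daily(self):
        cfg = CohortConfig(n_participants=2, study_days=20, seed=8)
        for rec in ot.generate_cohort(cfg, include_minutes=True):
            for d, night in enumerate(rec.minutes, start=1):
                target = rec.skin.values[d - 1]
                res = nightly_value(night)
                if np.isnan(target):
                    assert res.value is None
                else:
                    assert res.value == pytest.approx(target, abs=cfg.quantization)
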