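import numpy as np
import pytest

from flylat.dyad_metrics import dyad_series, position_side_bias
from flylat.errors import ConfigError
from flylat.individual_metrics import (
    circling_from_positions,
    circling_index,
    compute_turn_series,
    wing_index,
    wing_signed_sums,
)
from flylat.synthetic_flies import (
    TABLE1_DESIGN,
    SimConfig,
    design_total,
    sample_individual_biases,
    sample_wing_side_probs,
    simulate_dyad,
    simulate_experiment,
    simulate_positions,
    simulate_single_fly,
)
from flylat.track_data import ArenaConfig


def cfg_short(seed=1, duration=60.0, **kw):
    return SimConfig(seed=seed, arena=ArenaConfig(duration=duration), **kw)


class TestBiases:
    def test_zero_spread_collapses_to_mean(self):
        b = sample_individual_biases(2.5, 0.0, 10, 1)
        np.testing.assert_array_equal(b, np.full(10, 2.5))

    def test_sample_mean_near_population_mean(self):
        b = sample_individual_biases(0.0, 2.0, 4000, 2)
        assert abs(b.mean()) < 3 * 2.0 / np.sqrt(4000)

    def test_deterministic_under_seed(self):
        np.testing.assert_array_equal(
            sample_individual_biases(1.0, 2.0, 50, 7),
            sample_individual_biases(1.0, 2.0, 50, 7),
        )

    def test_wing_probs_in_unit_interval(self):
        p = sample_wing_side_probs(0.0, 1.5, 200, 3)
        assert np.all((p > 0) & (p < 1))


class TestSingleFly:
    def test_strong_bias_low_noise_high_circling(self):
        cfg = SimConfig(seed=1, arena=ArenaConfig(duration=3600.0),
                        turn_noise=1.0, pause_prob=0.0)
        tr = simulate_single_fly(cfg, 5.0, 0.5, 1)
        c = circling_index(compute_turn_series(tr))
        assert c.signed > 0.9

    def test_negative_bias_gives_negative_index(self):
        cfg = cfg_short(duration=300.0, turn_noise=2.0)
        tr = simulate_single_fly(cfg, -4.0, 0.5, 5)
        assert circling_index(compute_turn_series(tr)).signed < -0.5

    def test_positions_stay_in_arena(self):
        cfg = cfg_short(duration=300.0, speed_mean=10.0, speed_sd=5.0)
        tr = simulate_single_fly(cfg, 0.0, 0.5, 2)
        assert tr.in_arena(cfg.arena)
        assert np.isfinite(tr.x).all() and np.isfinite(tr.y).all()

    def test_unbiased_population_mean_near_zero(self):
        cfg = cfg_short(duration=120.0, mu_pop=0.0, sigma_ind=0.0)
        x, y = simulate_positions(cfg, 200, 11)
        C = circling_from_positions(x, y)
        assert abs(np.nanmean(C)) < 0.02

    def test_wing_bouts_have_configured_angle(self):
        cfg = cfg_short(duration=300.0, wing_event_rate=0.1, wing_angle=75.0)
        tr = simulate_single_fly(cfg, 0.0, 0.9, 3)
        opened = np.union1d(np.unique(tr.wing_left), np.unique(tr.wing_right))
        assert set(opened) <= {0.0, 75.0}
        assert (tr.wing_right > 0).sum() > (tr.wing_left > 0).sum()

    def test_deterministic_under_seed(self):
        cfg = cfg_short()
        a = simulate_single_fly(cfg, 1.0, 0.5, 9)
        b = simulate_single_fly(cfg, 1.0, 0.5, 9)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.wing_right, b.wing_right)


class TestDyads:
    def test_uncoupled_dyad_equals_solo_runs(self):
        cfg = cfg_short(duration=30.0, dyad_attraction=0.0, follow_gain=0.0)
        ta, tb = simulate_dyad(cfg, "FF", 42, biases=(2.0, -3.0), p_rights=(0.5, 0.5))
        ca, cb, _ = np.random.SeedSequence(42).spawn(3)
        sa = simulate_single_fly(cfg, 2.0, 0.5, ca)
        sb = simulate_single_fly(cfg, -3.0, 0.5, cb)
        for attr in ("x", "y", "heading", "wing_left", "wing_right"):
            np.testing.assert_array_equal(getattr(ta, attr), getattr(sa, attr))
            np.testing.assert_array_equal(getattr(tb, attr), getattr(sb, attr))

    def test_follower_keeps_partner_ahead(self):
        cfg = cfg_short(duration=300.0, follow_gain=0.6,
                        position_side_bias_lambda=0.0)
        f, m = simulate_dyad(cfg, "FM", 7)
        ds = dyad_series(m, f)  # male focal
        assert np.nanmedian(np.abs(ds.position)) < 30.0
        # and the female mostly sees the male behind her
        dsf = dyad_series(f, m)
        assert np.nanmedian(np.abs(dsf.position)) > 120.0

    def test_injected_lambda_shifts_side_bias_positive(self):
        cfg = cfg_short(duration=300.0, follow_gain=0.4,
                        position_side_bias_lambda=20.0)
        biases = []
        for d in range(12):
            f, m = simulate_dyad(cfg, "FM", 100 + d)
            biases.append(position_side_bias(dyad_series(m, f).position))
        assert np.mean(biases) > 0.2

    def test_both_members_in_arena(self):
        cfg = cfg_short(duration=120.0, dyad_attraction=0.2)
        ta, tb = simulate_dyad(cfg, "MM", 3)
        assert ta.in_arena(cfg.arena) and tb.in_arena(cfg.arena)

    def test_bad_context_rejected(self):
        with pytest.raises(ConfigError):
            simulate_dyad(cfg_short(), "FX", 1)


class TestExperiment:
    def test_design_table_total(self):
        assert design_total(TABLE1_DESIGN) == 3519

    def test_emits_one_meta_row_per_individual(self):
        cfg = cfg_short(duration=3.0)
        design = {"RAL-69": {"F": 3, "FF": 4, "FM": 2}}
        exp = simulate_experiment(design, cfg)
        assert len(exp.meta) == 9
        assert len(exp.tracks) == 9
        assert len(exp.ground_truth) == 9

    def test_partner_links_and_sexes(self):
        cfg = cfg_short(duration=3.0)
        exp = simulate_experiment({"RAL-136": {"FM": 4}}, cfg)
        metas = list(exp.meta.values())
        sexes = sorted(m.sex for m in metas)
        assert sexes == ["F", "F", "M", "M"]
        for m in metas:
            assert exp.meta[m.partner_id].partner_id == m.fly_id

    def test_odd_dyad_count_rejected(self):
        with pytest.raises(ConfigError, match="even"):
            simulate_experiment({"RAL-69": {"FF": 3}}, cfg_short(duration=3.0))

    def test_zero_count_design_empty(self):
        exp = simulate_experiment({"RAL-69": {"F": 0}}, cfg_short(duration=3.0))
        assert exp.meta == {} and exp.tracks == {}

    def test_deterministic_under_seed(self):
        cfg = cfg_short(duration=10.0)
        design = {"RAL-69": {"F": 2, "FM": 2}}
        e1 = simulate_experiment(design, cfg)
        e2 = simulate_experiment(design, cfg)
        for fid in e1.tracks:
            np.testing.assert_array_equal(e1.tracks[fid].x, e2.tracks[fid].x)
        assert e1.ground_truth.equals(e2.ground_truth)

    def test_no_nans_and_all_in_arena(self):
        cfg = cfg_short(duration=30.0)
        exp = simulate_experiment({"RAL-338": {"M": 2, "MM": 4}}, cfg)
        for tr in exp.tracks.values():
            assert tr.in_arena(cfg.arena)
            for arr in (tr.x, tr.y, tr.heading, tr.wing_left, tr.wing_right):
                assert np.isfinite(arr).all()

    def test_strain_override_changes_dynamics(self):
        cfg = cfg_short(duration=30.0, sigma_ind=0.0, mu_pop=0.0)
        exp = simulate_experiment(
            {"RAL-69": {"F": 5}, "RAL-796": {"F": 5}},
            cfg,
            strain_overrides={"RAL-796": {"mu_pop": 8.0, "turn_noise": 2.0}},
        )
        gt = exp.ground_truth.set_index("fly_id")
        b69 = gt.loc[[f for f in gt.index if f.startswith("RAL-69")], "b_i_deg_per_step"]
        b796 = gt.loc[[f for f in gt.index if f.startswith("RAL-796")], "b_i_deg_per_step"]
        assert np.allclose(b69, 0.0)
        assert np.all(b796 > 4.0)


class TestParameterRecovery:
    def test_mean_abs_c_increases_with_individual_spread(self):
        # trials long enough that the sqrt(1/n_turns) noise floor of |C|
        # sits below the signal injected by the smallest non-zero spread
        means = []
        for i, sigma in enumerate((0.0, 0.5, 2.0, 5.0)):
            cfg = SimConfig(seed=1, arena=ArenaConfig(duration=600.0),
                            mu_pop=0.0, sigma_ind=sigma)
            x, y = simulate_positions(cfg, 100, 1000 + i)
            C = circling_from_positions(x, y)
            means.append(np.nanmean(np.abs(C)))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_wing_index_recovers_side_preference(self):
        cfg = cfg_short(duration=120.0, wing_event_rate=0.05)
        w_means = []
        for mu in (-2.0, 0.0, 2.0):
            ws = []
            ps = sample_wing_side_probs(mu, 0.1, 40, 50)
            for i, p in enumerate(ps):
                tr = simulate_single_fly(cfg.replace(pause_prob=1.0), 0.0, p, 600 + i)
                ws.append(wing_index(wing_signed_sums(tr), tr.fly_id).signed)
            w_means.append(np.nanmean(ws))
        assert w_means[0] < -0.5 < 0.5 < w_means[2]
        assert abs(w_means[1]) < 0.15
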