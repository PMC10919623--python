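"""Generator contracts: determinism, distribution recovery, signal cues."""

import numpy as np
import pytest
from scipy import stats

import wearsite as ws
from wearsite import synthdata
from wearsite.synthdata import (CAT_LIGHT, CAT_MODERATE, CAT_SEDENTARY_LIVING,
                                CAT_VIGOROUS, SignalConfig, default_catalog,
                                mean_orientation, movement_rms,
                                orientation_angle_deg, simulate_calorimetry)


class TestParticipants:
    def test_empty_counts_give_empty_cohort(self):
        assert ws.sample_participants(0, 0, 1) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ws.sample_participants(-1, 0, 1)

    def test_seed_determinism(self):
        a = ws.sample_participants(20, 20, 7)
        b = ws.sample_participants(20, 20, 7)
        assert a == b

    def test_group_age_invariants(self):
        for p in ws.sample_participants(50, 50, 3):
            if p.group == "adult":
                assert p.age >= 18
            else:
                assert p.age < 18
            assert p.height > 0 and p.weight > 0 and p.resting_vo2 > 0

    def test_adult_mean_age_recovers_published_value(self):
        ages = [p.age for p in ws.sample_participants(500, 0, 7)]
        assert abs(np.mean(ages) - 26.9) < 1.0

    def test_demographic_distribution_recovery_2se(self):
        """At n=500/group, means of age, BMI and resting VO2 match the
        configured defaults within 2 standard errors."""
        cohort = ws.sample_participants(500, 500, 11)
        for group in ("adult", "child"):
            sub = [p for p in cohort if p.group == group]
            d = synthdata.DEMOGRAPHIC_DEFAULTS[group]
            for attr, key in (("age", "age"), ("bmi", "bmi"),
                              ("resting_vo2", "resting_vo2")):
                vals = np.array([getattr(p, attr) for p in sub])
                se = vals.std(ddof=1) / np.sqrt(len(vals))
                assert abs(vals.mean() - d[key][0]) < 2 * se + 1e-9, \
                    f"{group} {attr}"


class TestProtocol:
    def test_default_catalog_has_17_entries(self):
        assert len(default_catalog("adult")) == 17
        assert len(default_catalog("child")) == 17

    def test_seven_bouts_with_331_composition(self, adult_profile):
        prot = ws.draw_protocol(adult_profile, seed=5)
        cats = [b.activity.category for b in prot.bouts]
        assert len(cats) == 7
        assert cats.count(CAT_SEDENTARY_LIVING) == 3
        assert sum(c in (CAT_LIGHT, CAT_MODERATE) for c in cats) == 3
        assert cats.count(CAT_VIGOROUS) == 1

    def test_draws_without_replacement_and_duration_range(self, adult_profile):
        prot = ws.draw_protocol(adult_profile, seed=6)
        names = [b.activity.name for b in prot.bouts]
        assert len(set(names)) == 7
        for b in prot.bouts:
            assert 300.0 <= b.planned_duration <= 480.0

    def test_minimal_catalog_forces_composition(self, adult_profile):
        cat = default_catalog("adult")
        minimal = ([a for a in cat if a.category == CAT_SEDENTARY_LIVING][:3]
                   + [a for a in cat if a.category == CAT_LIGHT][:3]
                   + [a for a in cat if a.category == CAT_VIGOROUS][:1])
        prot = ws.draw_protocol(adult_profile, catalog=minimal, seed=1)
        assert sorted(b.activity.name for b in prot.bouts) == \
            sorted(a.name for a in minimal)

    def test_insufficient_catalog_rejected(self, adult_profile):
        cat = [a for a in default_catalog("adult")
               if a.category != CAT_VIGOROUS]
        with pytest.raises(ValueError, match="catalog"):
            ws.draw_protocol(adult_profile, catalog=cat, seed=1)

    def test_seed_determinism(self, adult_profile):
        a = ws.draw_protocol(adult_profile, seed=9)
        b = ws.draw_protocol(adult_profile, seed=9)
        assert a == b


class TestBoutSignal:
    def test_rest_is_gravity_plus_noise(self, adult_profile):
        rec = ws.simulate_bout_signal(adult_profile, synthdata.REST_ACTIVITY,
                                      "hip", 60.0, seed=1, met=1.0)
        vm = np.linalg.norm(np.asarray(rec.xyz, dtype=float), axis=1)
        assert abs(vm.mean() - 1.0) < 0.05
        assert movement_rms(rec) < SignalConfig().sedentary_rms_ceiling

    def test_sites_have_distinct_orientations(self, adult_profile):
        act = synthdata.REST_ACTIVITY
        recs = {s: ws.simulate_bout_signal(adult_profile, act, s, 30.0,
                                           seed=2, met=1.0)
                for s in ("hip", "wrist", "chest")}
        cfg = SignalConfig()
        for a in recs:
            for b in recs:
                if a < b:
                    ang = orientation_angle_deg(mean_orientation(recs[a]),
                                                mean_orientation(recs[b]))
                    assert ang > cfg.min_orientation_deg

    def test_movement_rms_increases_with_met(self, adult_profile):
        walk = [a for a in default_catalog("adult") if a.locomotor][0]
        for site in ("hip", "wrist", "chest"):
            rms = [movement_rms(ws.simulate_bout_signal(
                adult_profile, walk, site, 60.0, seed=3, met=m))
                for m in (1.5, 3.0, 5.0, 8.0)]
            assert all(a < b for a, b in zip(rms, rms[1:])), site

    def test_unknown_site_rejected(self, adult_profile):
        with pytest.raises(ValueError, match="wear-site"):
            ws.simulate_bout_signal(adult_profile, synthdata.REST_ACTIVITY,
                                    "ankle", 10.0, seed=1)

    def test_heavier_participant_moves_less_at_fixed_met(self, adult_profile):
        heavy = ws.ParticipantProfile(id="H", group="adult", sex="male",
                                      age=27.0, height=170.0, weight=95.0,
                                      resting_vo2=4.0)
        walk = [a for a in default_catalog("adult") if a.locomotor][0]
        r_light = movement_rms(ws.simulate_bout_signal(
            adult_profile, walk, "hip", 30.0, seed=4, met=4.0))
        r_heavy = movement_rms(ws.simulate_bout_signal(
            heavy, walk, "hip", 30.0, seed=4, met=4.0))
        assert r_heavy < r_light


class TestSession:
    def test_rest_segment_mean_matches_resting_vo2(self, adult_profile):
        prot = ws.draw_protocol(adult_profile, seed=12)
        series, _ = simulate_calorimetry(adult_profile, prot, seed=13)
        rest = series.vo2[(series.t >= 0) & (series.t < series.rest_end)]
        assert abs(rest.mean() - adult_profile.resting_vo2) < 0.1

    def test_recordings_aligned_across_sites(self, small_cohort):
        _, sessions, _ = small_cohort
        for s in sessions.values():
            assert len(s.recordings) == 3
            annos = [r.bout_annotations for r in s.recordings.values()]
            assert annos[0] == annos[1] == annos[2]
            lengths = {r.n_samples for r in s.recordings.values()}
            assert len(lengths) == 1

    def test_plateau_recovers_latent_met_draw(self, adult_profile):
        """Steady-bout plateau / resting VO2 matches the latent draw to 2%."""
        prot = ws.draw_protocol(adult_profile, seed=21)
        series, latents = simulate_calorimetry(adult_profile, prot, seed=22)
        checked = 0
        for lat in latents:
            if not lat.reached_steady or lat.met_draw < 2.0:
                continue
            mask = (series.t >= lat.start_s + 150) & (series.t < lat.end_s)
            recovered = series.vo2[mask].mean() / adult_profile.resting_vo2
            assert abs(recovered - lat.met_draw) / lat.met_draw < 0.02
            checked += 1
        assert checked >= 1

    def test_empty_sites_rejected(self, adult_profile):
        prot = ws.draw_protocol(adult_profile, seed=1)
        with pytest.raises(ValueError, match="wear-site"):
            ws.simulate_session(adult_profile, prot, (), seed=1)

    def test_session_determinism(self, adult_profile):
        prot = ws.draw_protocol(adult_profile, seed=30)
        a = ws.simulate_session(adult_profile, prot, ("hip",), seed=31)
        b = ws.simulate_session(adult_profile, prot, ("hip",), seed=31)
        assert np.array_equal(a.recordings["hip"].xyz, b.recordings["hip"].xyz)
        assert np.array_equal(a.calorimetry.vo2, b.calorimetry.vo2)
        assert a.latents == b.latents


class TestCategoryMetRecovery:
    def test_met_draws_match_configured_distributions(self):
        """Per-category latent MET means at n=120 participants match the
        configured truncated-normal means within 2 SE."""
        draws = {c: [] for c in synthdata.CATEGORIES}
        profiles = ws.sample_participants(120, 0, 5)
        for i, p in enumerate(profiles):
            prot = ws.draw_protocol(p, seed=300 + i)
            _, latents = simulate_calorimetry(p, prot, seed=600 + i)
            for lat, bout in zip(latents, prot.bouts):
                draws[bout.activity.category].append(lat.met_draw)
        for cat, vals in draws.items():
            mean, sd = synthdata.MET_DEFAULTS["adult"][cat]
            a = (0.0 - mean) / sd
            expected = stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd)
            vals = np.array(vals)
            se = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean() - expected) < 2 * se + 0.05, cat
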