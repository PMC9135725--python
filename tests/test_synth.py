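"""Synthetic-study generator: determinism, effects, schedules, audio."""

import numpy as np
import pytest

from sigwhistle import synth
from sigwhistle.contours import shape_distance
from sigwhistle.extraction import spectrogram
from sigwhistle.synth import (ConfigurationError, ContourPrototype, EffectConfig,
                              EmitterSpec, GenerationError, Segment,
                              SessionConfig)


class TestRepertoire:
    def test_seeded_regeneration_is_identical(self, site_profiles):
        a = synth.make_repertoire(site_profiles, 3, seed=1)
        b = synth.make_repertoire(site_profiles, 3, seed=1)
        assert a.to_json() == b.to_json()

    def test_different_seeds_differ(self, site_profiles):
        a = synth.make_repertoire(site_profiles, 2, seed=1)
        b = synth.make_repertoire(site_profiles, 2, seed=2)
        assert a.to_json() != b.to_json()

    def test_null_effects_give_comparable_site_means(self, site_profiles):
        """With zero effects, per-site parameter means differ only by sampling noise."""
        study = synth.make_repertoire(site_profiles, 6, seed=3)
        mins = {}
        for site in site_profiles.index:
            feats = [study.prototypes[i].analytic_features()["min_freq"]
                     for i in study.identities_at(site)]
            mins[site] = np.mean(feats)
        spread = max(mins.values()) - min(mins.values())
        # base SD 700 Hz, n=6 per site: site means should stay within a few SEs
        assert spread < 4 * 700 / np.sqrt(6)

    def test_configured_min_frequency_shift_is_recovered(self, site_profiles):
        """Monte-Carlo mean shift over 200 replicates (seeds 0..199) matches
        the configured +2000 Hz within 3 MC standard errors."""
        effects = EffectConfig(shifts={"site": {"GC": {"min_freq": 2000.0}}})
        diffs = []
        for seed in range(200):
            study = synth.make_repertoire(site_profiles, 1, effects, seed=seed)
            gc = [study.prototypes[i].analytic_features()["min_freq"]
                  for i in study.identities_at("GC")]
            rest = [study.prototypes[i].analytic_features()["min_freq"]
                    for i in study.prototypes if not i.startswith("GC")]
            diffs.append(np.mean(gc) - np.mean(rest))
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - 2000.0) < 3 * se + 1e-9

    def test_unknown_effect_level_raises(self, site_profiles):
        effects = EffectConfig(shifts={"region": {"NORTH": {"min_freq": 100.0}}})
        with pytest.raises(ConfigurationError, match="NORTH"):
            synth.make_repertoire(site_profiles, 1, effects, seed=0)

    def test_prototypes_are_mutually_distinct(self, small_study):
        shapes = [p.sample_loops()[0] for p in small_study.prototypes.values()]
        for i in range(len(shapes)):
            for j in range(i + 1, len(shapes)):
                assert shape_distance(shapes[i], shapes[j]) >= synth.SHAPE_REJECT_MARGIN


class TestPrototypeGeometry:
    def test_analytic_features_of_handmade_contours(self):
        up = ContourPrototype("u", (Segment(1.0, 5000, 15000, 0.0),))
        assert up.analytic_features() == {
            "min_freq": 5000, "max_freq": 15000, "start_freq": 5000,
            "end_freq": 15000, "freq_range": 10000, "n_inflections": 0.0,
            "duration": 1.0}
        chevron = ContourPrototype("c", (Segment(1.0, 5000, 15000),
                                         Segment(1.0, 15000, 5000)))
        f = chevron.analytic_features()
        assert f["n_inflections"] == 1.0 and f["end_freq"] == 5000
        assert f["duration"] == 2.0

    def test_loops_multiply_inflections_and_duration(self):
        chevron2 = ContourPrototype("c", (Segment(0.4, 5000, 15000),
                                          Segment(0.4, 15000, 5000)),
                                    n_loops=3, inter_loop_gap=0.1)
        f = chevron2.analytic_features()
        assert f["n_inflections"] == 3.0
        assert f["duration"] == pytest.approx(3 * 0.8 + 2 * 0.1)

    def test_generated_extrema_sit_at_start_and_end(self, small_study):
        for p in small_study.prototypes.values():
            f = p.analytic_features()
            assert f["start_freq"] == pytest.approx(f["min_freq"])
            assert f["end_freq"] == pytest.approx(f["max_freq"])


class TestSessions:
    def test_compliant_bout_satisfies_sigid_gaps(self, small_study):
        ids = small_study.identities_at("AL")
        cfg = SessionConfig(duration=600, emitters=(EmitterSpec(ids[0], "sw", 4),))
        ems = synth.sample_session(small_study, cfg, seed=5)
        gaps = [ems[i + 1].t_start - ems[i].t_end for i in range(3)]
        assert all(1.0 <= g <= 10.0 for g in gaps)
        assert synth.expected_labels(ems)[ids[0]] == "SW"

    def test_sparse_bout_has_no_gaps_in_window(self, small_study):
        ids = small_study.identities_at("AL")
        cfg = SessionConfig(duration=900, emitters=(EmitterSpec(ids[0], "sparse", 4),))
        ems = synth.sample_session(small_study, cfg, seed=5)
        gaps = [ems[i + 1].t_start - ems[i].t_end for i in range(3)]
        assert all(g > 10.0 for g in gaps)
        assert synth.expected_labels(ems)[ids[0]] == "OW"

    def test_rewt_patterns_yield_rewt_truth(self, small_study):
        ids = small_study.identities_at("GC")
        for n in (2, 4):  # too-few-units flavour and dense sub-second flavour
            cfg = SessionConfig(duration=600,
                                emitters=(EmitterSpec(ids[0], "rewt", n),))
            ems = synth.sample_session(small_study, cfg, seed=8)
            assert synth.expected_labels(ems)[ids[0]] == "REWT"

    def test_infeasible_schedule_raises(self, small_study):
        ids = small_study.identities_at("AL")
        cfg = SessionConfig(duration=3.0, emitters=(EmitterSpec(ids[0], "sw", 4),))
        with pytest.raises(GenerationError):
            synth.sample_session(small_study, cfg, seed=5)

    def test_variant_whistles_get_unique_labels(self, small_study):
        cfg = SessionConfig(duration=600, emitters=(), n_variant_whistles=3)
        ems = synth.sample_session(small_study, cfg, seed=9, session_id="X")
        labels = [e.identity for e in ems]
        assert len(set(labels)) == 3
        assert all(synth.expected_labels(ems)[l] == "OW" for l in labels)

    def test_truth_labels_rederivable_from_schedule(self, small_study):
        """Label soundness: the checker works from times alone."""
        ids = small_study.identities_at("LA")
        cfg = SessionConfig(duration=900, emitters=(
            EmitterSpec(ids[0], "sw", 5), EmitterSpec(ids[1], "rewt", 3),
            EmitterSpec(ids[2], "sparse", 4)), n_variant_whistles=1)
        ems = synth.sample_session(small_study, cfg, seed=11)
        labels = synth.expected_labels(ems)
        assert labels[ids[0]] == "SW"
        assert labels[ids[1]] == "REWT"
        assert labels[ids[2]] == "OW"


class TestAudio:
    def test_constant_tone_peaks_at_its_frequency(self):
        proto = ContourPrototype("t", (Segment(0.5, 10000, 10000.001),))
        ems = [synth.Emission("S1", "t", 0.2, proto, "sw")]
        wave = synth.render_audio(ems, 96000, snr_db=40, seed=0)
        seg = wave[int(0.25 * 96000):int(0.4 * 96000)]
        grid = spectrogram(seg, 96000, 1024)
        peak = grid.freqs[np.argmax(grid.magnitude.mean(axis=0))]
        assert abs(peak - 10000.0) <= grid.bin_width

    def test_nyquist_violation_names_the_prototype(self):
        proto = ContourPrototype("hot", (Segment(0.5, 20000, 25000),))
        ems = [synth.Emission("S1", "hot", 0.0, proto, "sw")]
        with pytest.raises(ValueError, match="hot"):
            synth.render_audio(ems, 44000, snr_db=30, seed=0)

    def test_amplitude_bounded(self):
        proto = ContourPrototype("t", (Segment(0.5, 8000, 12000),))
        ems = [synth.Emission("S1", "t", 0.1, proto, "sw")]
        wave = synth.render_audio(ems, 96000, snr_db=-10, seed=0)
        assert np.max(np.abs(wave)) <= 1.0

    def test_noise_only_sentinel_has_no_tonal_ridge(self):
        from sigwhistle.extraction import extract_session

        proto = ContourPrototype("t", (Segment(0.5, 8000, 12000),))
        ems = [synth.Emission("S1", "t", 0.1, proto, "sw")]
        wave = synth.render_audio(ems, 96000, snr_db=float("-inf"), seed=3)
        assert extract_session(wave, 96000) == []
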