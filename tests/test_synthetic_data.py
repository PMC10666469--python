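import json

import numpy as np
import pytest

from tonetrace import (
    CohortConfig,
    Group,
    OutcomeCategory,
    SpeakerModel,
    SpeakerRange,
    Tone,
    ToneSpec,
    default_cohort,
    make_target_stimuli,
    simulate_imitations,
    simulate_naming_ledger,
    t_denormalize,
    t_normalize,
    tonal_distance,
    tone_centroids,
    truncate_edges,
)
from tonetrace.core import LEVEL_TONES, TONE_ORDER
from tonetrace.errors import ValidationError
from tonetrace.lexical_scoring import score_ledger
from tonetrace.synthetic_data import (
    DEFAULT_SEGMENTS,
    DEFAULT_TONE_SPECS,
    apply_random_exclusions,
    chao_to_t,
    identity_confusion,
    imitation_day_schedule,
    planned_imitation_ledger,
    planned_naming_ledger,
)
from tonetrace.tone_metrics import DurationStats, dct_features, dct_shape, duration_stats


def _analyze(traj, rng, dur):
    return dct_features(t_normalize(truncate_edges(traj), rng), dur)


def _model(**kw):
    defaults = dict(
        speaker_id="s01", group=Group.ENGLISH, f0_floor=100.0, f0_ceiling=250.0, seed=0
    )
    defaults.update(kw)
    return SpeakerModel(**defaults)


class TestChaoMapping:
    @pytest.mark.parametrize("digit,expected", [(1, 0.0), (2, 1.25), (3, 2.5), (5, 5.0)])
    def test_values(self, digit, expected):
        assert chao_to_t(digit) == expected

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            chao_to_t(6)

    def test_level_spec_requires_equal_digits(self):
        with pytest.raises(ValidationError):
            ToneSpec(Tone.MID, 2, 3)


class TestMakeTargetStimuli:
    def test_crossing_yields_16(self, targets):
        assert len(targets) == 16
        assert len({t.item for t in targets}) == 16
        assert {t.tone for t in targets} == set(TONE_ORDER)

    def test_level_spec_constant_contour(self, targets, target_range):
        mid = next(t for t in targets if t.item == "nɔn22")
        dur = DurationStats(400.0, 50.0)
        feats = _analyze(mid, target_range, dur)
        assert feats.dct1 == pytest.approx(1.25, abs=1e-9)
        assert feats.dct2 == pytest.approx(0.0, abs=1e-9)
        assert feats.dct3 == pytest.approx(0.0, abs=1e-9)

    def test_linear_rise_roundtrip_through_inverse(self, target_range):
        specs = (ToneSpec(Tone.RISE, 1, 5, curvature_gain=0.0),
                 *DEFAULT_TONE_SPECS[1:])
        targets = make_target_stimuli(specs=specs)
        rise = next(t for t in targets if t.tone is Tone.RISE)
        tvals = np.array(t_normalize(rise, target_range).tvals)
        np.testing.assert_allclose(tvals, np.linspace(0, 5, 20), atol=1e-9)
        hz_again = t_denormalize(tvals, target_range)
        np.testing.assert_allclose(hz_again, rise.values(), rtol=1e-9)

    def test_rise_fall_dct2_signs(self, targets, target_range):
        dur = DurationStats(400.0, 50.0)
        for t in targets:
            f = _analyze(t, target_range, dur)
            if t.tone is Tone.RISE:
                assert f.dct2 < 0
            elif t.tone is Tone.FALL:
                assert f.dct2 > 0
            else:
                assert abs(f.dct2) < 1e-9


class TestSimulateImitations:
    def test_noiseless_identity(self, targets, target_range):
        model = _model(f0_floor=90.0, f0_ceiling=320.0)
        ims = simulate_imitations(targets, model, reps=1, days=(1,),
                                  target_range=target_range)
        assert len(ims) == 16
        dur = duration_stats([t.duration_ms for t in targets])
        tf = [dct_features(t_normalize(truncate_edges(t), target_range), dur) for t in targets]
        cents = tone_centroids(tf)
        for im in ims:
            f = dct_features(t_normalize(truncate_edges(im), model.range), dur)
            assert tonal_distance(f, cents[im.tone]) == pytest.approx(0.0, abs=1e-9)

    def test_slope_gain_scales_dct2(self, targets, target_range):
        model = _model(slope_gain=0.6)
        ims = simulate_imitations(targets, model, reps=1, days=(1,),
                                  target_range=target_range)
        rise_t = next(t for t in targets if t.item == "nɔn15")
        rise_i = next(t for t in ims if t.item == "nɔn15" and t.day == 1)
        d2_target = dct_shape(t_normalize(truncate_edges(rise_t), target_range).values())[1]
        d2_imit = dct_shape(t_normalize(truncate_edges(rise_i), model.range).values())[1]
        assert d2_imit / d2_target == pytest.approx(0.6, abs=1e-9)

    def test_height_offset_raises_level_dct1(self, targets, target_range):
        raised = _model(height_offset=0.8)
        flat = _model(height_offset=0.0)
        dur = duration_stats([t.duration_ms for t in targets])
        tf = [dct_features(t_normalize(truncate_edges(t), target_range), dur) for t in targets]
        cents = tone_centroids(tf)
        for tone in LEVEL_TONES:
            target = next(t for t in targets if t.tone is tone)
            d1_target = dct_shape(
                t_normalize(truncate_edges(target), target_range).values()
            )[0]
            for model, offset in ((raised, 0.8), (flat, 0.0)):
                im = simulate_imitations([target], model, reps=1, days=(1,),
                                         target_range=target_range)[0]
                f = dct_features(t_normalize(truncate_edges(im), model.range), dur)
                assert f.dct1 - d1_target == pytest.approx(offset, abs=1e-9)
                if offset > 0:
                    assert tonal_distance(f, cents[tone]) > 0.5

    def test_deterministic_given_seed(self, targets, target_range):
        model = _model(noise_sd=0.3, duration_jitter_sd=0.05, seed=42)
        a = simulate_imitations(targets, model, target_range=target_range)
        b = simulate_imitations(targets, model, target_range=target_range)
        assert a == b

    def test_different_seed_differs(self, targets, target_range):
        m1 = _model(noise_sd=0.3, seed=1)
        m2 = _model(noise_sd=0.3, seed=2)
        assert simulate_imitations(targets, m1, target_range=target_range) != \
            simulate_imitations(targets, m2, target_range=target_range)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValidationError):
            _model(slope_gain=1.5)
        with pytest.raises(ValidationError):
            _model(f0_floor=300.0, f0_ceiling=200.0)
        with pytest.raises(ValidationError):
            _model(confusion_matrix=((0.5, 0.5, 0.5, 0.5),) * 4)


class TestSimulateNamingLedger:
    def test_identity_confusion_all_correct(self, targets):
        model = _model()
        labels = simulate_naming_ledger(model, targets, p_segment_correct=1.0)
        outcomes = score_ledger(labels)
        assert len(outcomes) == 32
        assert all(o.category is OutcomeCategory.CORRECT for o in outcomes)

    def test_low_to_mid_dominates_low_errors(self, targets):
        cm = (
            (1.0, 0.0, 0.0, 0.0),
            (0.0, 1.0, 0.0, 0.0),
            (0.0, 0.0, 1.0, 0.0),
            (0.0, 0.0, 0.9, 0.1),
        )
        counts = {Tone.MID: 0, Tone.RISE: 0, Tone.FALL: 0, Tone.LOW: 0}
        for seed in range(60):
            model = _model(confusion_matrix=cm, seed=seed)
            labels = simulate_naming_ledger(model, targets, p_segment_correct=1.0)
            for o in score_ledger(labels):
                if o.target_tone is Tone.LOW:
                    produced = o.error_type[1] if o.error_type else Tone.LOW
                    counts[produced] += 1
        total = sum(counts.values())
        errors = total - counts[Tone.LOW]
        assert counts[Tone.MID] == errors  # the only configured error route
        assert counts[Tone.MID] / total == pytest.approx(0.9, abs=0.05)

    def test_no_segment_correct_no_tone_only_errors(self, targets):
        model = _model(confusion_matrix=identity_confusion())
        labels = simulate_naming_ledger(model, targets, p_segment_correct=0.0)
        outcomes = score_ledger(labels)
        assert not any(
            o.category is OutcomeCategory.TONE_ONLY_ERROR for o in outcomes
        )

    def test_deterministic(self, targets):
        model = _model(seed=9)
        assert simulate_naming_ledger(model, targets, p_segment_correct=0.5) == \
            simulate_naming_ledger(model, targets, p_segment_correct=0.5)


class TestSchedules:
    def test_day_schedule_counts(self, targets, rng):
        trials = imitation_day_schedule(targets, presentations=4, rng=rng)
        assert len(trials) == 64
        items = [t.item for t in targets]
        for item in items:
            assert trials.count(item) == 4

    def test_paired_block_structure_and_constraint(self, targets, rng):
        trials = imitation_day_schedule(targets, presentations=4, rng=rng)
        block = trials[:32]
        stimuli = block[0::2]
        assert block[1::2] == stimuli  # each stimulus twice in a row
        by_item = {t.item: t for t in targets}
        for a, b in zip(stimuli, stimuli[1:]):
            ta, tb = by_item[a], by_item[b]
            assert ta.item[:-2] != tb.item[:-2]
            assert ta.tone != tb.tone


class TestPlannedLedgers:
    def test_imitation_design_product(self):
        ledger = planned_imitation_ledger()
        assert ledger.planned_count == 2 * 16 * 41 * 2 == 2624

    def test_naming_design_product(self):
        ledger = planned_naming_ledger()
        assert ledger.planned_count == 16 * 41 * 2 == 1312

    def test_random_exclusions(self, rng):
        ledger = planned_imitation_ledger()
        apply_random_exclusions(ledger, 21, rng)
        assert ledger.retained_count == 2603
        ledger.check()


class TestDefaultCohort:
    @pytest.fixture(scope="class")
    def cohort(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return default_cohort(CohortConfig(seed=5))

    def test_bookkeeping(self, cohort):
        assert len(cohort.speaker_models) == 41
        groups = [m.group for m in cohort.speaker_models.values()]
        assert groups.count(Group.ENGLISH) == 21
        assert groups.count(Group.MANDARIN) == 20
        assert cohort.imitation_ledger.planned_count == 2624
        assert cohort.imitation_ledger.retained_count == 2603
        assert len(cohort.imitations) == 2603
        assert cohort.naming_ledger.planned_count == 1312
        assert cohort.naming_ledger.retained_count == 1308
        assert len(cohort.naming_labels) == 1312
        assert sum(lb.quality_flag for lb in cohort.naming_labels) == 4

    def test_ground_truth_sidecar_is_jsonable_and_complete(self, cohort):
        gt = json.loads(json.dumps(cohort.ground_truth()))
        assert set(gt["speakers"]) == set(cohort.speaker_models)
        one = gt["speakers"][next(iter(gt["speakers"]))]
        assert {"slope_gain", "height_offset", "confusion_matrix"} <= set(one)

    def test_determinism_byte_identical(self, cohort):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = default_cohort(CohortConfig(seed=5))
        assert again.imitations == cohort.imitations
        assert again.naming_labels == cohort.naming_labels
        assert json.dumps(again.ground_truth()) == json.dumps(cohort.ground_truth())

    def test_group_contrast_reflects_generating_offsets(self, cohort):
        # mandarin height offsets are drawn well above english ones
        betas = {
            g: [m.height_offset for m in cohort.speaker_models.values() if m.group is g]
            for g in (Group.ENGLISH, Group.MANDARIN)
        }
        assert np.mean(betas[Group.MANDARIN]) - np.mean(betas[Group.ENGLISH]) > 0.2


class TestCohortConfigIO:
    def test_from_yaml(self, tmp_path):
        cfg_yaml = """
seed: 7
n_imitation_exclusions: 3
n_naming_exclusions: 1
groups:
  english:
    n_speakers: 2
    slope_gain_mean: 0.8
  mandarin:
    n_speakers: 2
    height_offset_mean: 0.6
p_segment_correct:
  1: 0.4
  2: 0.9
"""
        path = tmp_path / "cohort.yaml"
        path.write_text(cfg_yaml)
        cfg = CohortConfig.from_yaml(path)
        assert cfg.seed == 7
        assert cfg.groups["english"].n_speakers == 2
        assert cfg.p_segment_correct[2] == 0.9
        cohort = default_cohort(cfg)
        assert len(cohort.speaker_models) == 4
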